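"""Seed-reproducible mock cohorts with the funnel structure of the workflow.

Real production data cannot be shipped, so this module simulates the
selection funnel end-to-end: single B-cells sorted onto 96-well plates, per
-chain PCR band sizes, V/J allele calls drawn from the packaged primer
registry (so every call is resolvable), cloning/colony/sequencing outcomes,
heavy-light pairing and final antibody concentrations.  Identical seeds give
byte-identical output files; every emitted file is parseable by the
corresponding ingest function, and thresholding the emitted band sizes
reproduces the simulated pass/fail outcomes exactly.

The per-stage success probabilities are illustrative defaults (production
rates are proprietary to a given lab); they are configuration, not claims
about any real cohort.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .batching import StoreEntry, StoreList
from .errors import InputValidationError
from .lineage import LineageStore, RecordID
from .plates import PlateFormat, ScanOrder, format_barcode, index_to_well_label
from .primers import AlleleCall, PrimerRegistry, default_registry
from .readouts import (
    ChainReadout,
    ConcentrationReading,
    WellAddress,
    write_electrophoresis,
    write_quantification,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FunnelConfig",
    "ChainSim",
    "CellSim",
    "Cohort",
    "generate_cohort",
    "funnel_counts",
    "expected_pair_probability",
    "FUNNEL_STAGES",
    "ALLELE_CALL_COLUMNS",
]

ALLELE_CALL_COLUMNS = [
    "sample_id", "chain", "v_allele", "j_allele", "evaluation", "plate_barcode", "well",
]

# ordered workflow stages counted by funnel_counts; a cell is counted at a
# stage while BOTH of its chains are still alive there
FUNNEL_STAGES = (
    "sorted_cells",
    "cdna",
    "cele1_passed",
    "seq1_functional",
    "cele2_passed",
    "cloned",
    "colonies_picked",
    "seq2_passed",
    "transfection_pairs",
)

_CHAIN_SUFFIX = {"Heavy": "H", "Kappa": "K", "Lambda": "L"}
_BASE_TIME = datetime(2025, 1, 1, tzinfo=timezone.utc)


@dataclass(frozen=True)
class FunnelConfig:
    """Study conditions for one mock cohort.

    Probabilities apply per chain at each quality gate; a cell survives a
    stage only while both of its chains do.  Band-size distributions are
    two-component mixtures: a chain-specific amplicon peak for successes and
    no-band/short-product for failures.
    """

    n_cells: int = 384
    p_pcr_band: float = 0.8        # band at either electrophoresis check
    p_seq1_functional: float = 0.85
    p_clone: float = 0.9
    p_colony: float = 0.95
    p_seq2: float = 0.9
    p_kappa: float = 0.6           # light-chain type of a cell, else lambda
    p_novel_allele: float = 0.0    # emits registry-unresolvable alleles
    band_mean_bp: dict = field(
        default_factory=lambda: {"Heavy": 480.0, "Kappa": 420.0, "Lambda": 440.0}
    )
    band_sd_bp: float = 15.0
    fail_band_mean_bp: float = 120.0
    fail_band_sd_bp: float = 30.0
    p_fail_no_band: float = 0.7    # failures with no band at all (0 bp)
    band_threshold_bp: float = 300.0
    concentration_mean_ng_ul: float = 100.0
    concentration_sigma: float = 0.3  # lognormal shape
    seed: int = 0

    def __post_init__(self):
        for name in ("p_pcr_band", "p_seq1_functional", "p_clone", "p_colony",
                     "p_seq2", "p_kappa", "p_novel_allele", "p_fail_no_band"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputValidationError(f"{name} must be in [0, 1], got {v}")
        if self.n_cells < 1:
            raise InputValidationError("n_cells must be >= 1")


@dataclass(frozen=True)
class ChainSim:
    """Simulated trajectory of one antibody chain of one cell."""

    chain: str
    v_allele: str
    j_allele: str
    cele1_band_bp: float
    cele1_passed: bool
    seq1_functional: bool
    cele2_band_bp: float
    cele2_passed: bool
    cloned: bool
    colony_picked: bool
    seq2_passed: bool
    concentration_ng_ul: float

    def alive_through(self) -> tuple[bool, ...]:
        """Cumulative survival at each post-cDNA gate, in funnel order."""
        gates = (
            self.cele1_passed,
            self.seq1_functional,
            self.cele2_passed,
            self.cloned,
            self.colony_picked,
            self.seq2_passed,
        )
        out, alive = [], True
        for g in gates:
            alive = alive and g
            out.append(alive)
        return tuple(out)


@dataclass(frozen=True)
class CellSim:
    cell_id: str
    plate_barcode: str
    well: str
    heavy: ChainSim
    light: ChainSim

    def pair_survives(self) -> bool:
        return self.heavy.alive_through()[-1] and self.light.alive_through()[-1]


@dataclass(frozen=True)
class Cohort:
    config: FunnelConfig
    cells: tuple[CellSim, ...]

    def chain_samples(self):
        for cell in self.cells:
            for sim in (cell.heavy, cell.light):
                yield cell, sim, f"{cell.cell_id}_{_CHAIN_SUFFIX[sim.chain]}"


def expected_pair_probability(config: FunnelConfig) -> float:
    """Analytic probability that a cell yields a transfection pair: both
    chains must pass two band checks, sequence evaluation, cloning, colony
    growth and final sequencing independently."""
    s = (
        config.p_pcr_band ** 2
        * config.p_seq1_functional
        * config.p_clone
        * config.p_colony
        * config.p_seq2
    )
    return s * s


def _draw_band(rng: np.random.Generator, cfg: FunnelConfig, chain: str, passed: bool) -> float:
    """Band size consistent with the pass/fail outcome at the configured
    threshold, so re-thresholding the emitted file reproduces the outcome."""
    if passed:
        band = rng.normal(cfg.band_mean_bp[chain], cfg.band_sd_bp)
        band = max(band, cfg.band_threshold_bp)
    elif rng.random() < cfg.p_fail_no_band:
        band = 0.0
    else:
        band = rng.normal(cfg.fail_band_mean_bp, cfg.fail_band_sd_bp)
        band = min(max(band, 0.0), cfg.band_threshold_bp - 1.0)
    return float(round(band))


def _simulate_chain(
    rng: np.random.Generator,
    cfg: FunnelConfig,
    chain: str,
    v_keys: list[str],
    j_keys: list[str],
) -> ChainSim:
    cele1 = rng.random() < cfg.p_pcr_band
    seq1 = rng.random() < cfg.p_seq1_functional
    cele2 = rng.random() < cfg.p_pcr_band
    cloned = rng.random() < cfg.p_clone
    colony = rng.random() < cfg.p_colony
    seq2 = rng.random() < cfg.p_seq2
    if rng.random() < cfg.p_novel_allele:
        v_allele = {"Heavy": "IGHV9-99*01", "Kappa": "IGKV9-99*01", "Lambda": "IGLV9-99*01"}[chain]
    else:
        v_allele = v_keys[int(rng.integers(len(v_keys)))] + "*01"
    j_allele = j_keys[int(rng.integers(len(j_keys)))] + "*01"
    conc = float(round(rng.lognormal(np.log(cfg.concentration_mean_ng_ul), cfg.concentration_sigma), 1))
    return ChainSim(
        chain=chain,
        v_allele=v_allele,
        j_allele=j_allele,
        cele1_band_bp=_draw_band(rng, cfg, chain, cele1),
        cele1_passed=cele1,
        seq1_functional=seq1,
        cele2_band_bp=_draw_band(rng, cfg, chain, cele2),
        cele2_passed=cele2,
        cloned=cloned,
        colony_picked=colony,
        seq2_passed=seq2,
        concentration_ng_ul=conc,
    )


def generate_cohort(config: FunnelConfig, registry: PrimerRegistry | None = None) -> Cohort:
    """Simulate one cohort of sorted single B-cells through the full funnel.

    Allele calls are sampled from the packaged registry's keys so every
    functional call resolves to a specific primer pair (unless
    ``p_novel_allele`` deliberately injects unresolvable ones).
    """
    registry = registry or default_registry()
    rng = np.random.default_rng(config.seed)
    fmt = PlateFormat.plate_96()
    keys = {
        chain: (sorted(registry.allele_keys(chain, "forward")),
                sorted(registry.allele_keys(chain, "reverse")))
        for chain in ("Heavy", "Kappa", "Lambda")
    }
    cells = []
    for i in range(config.n_cells):
        plate_i, well_i = divmod(i, fmt.n_wells)
        light_type = "Kappa" if rng.random() < config.p_kappa else "Lambda"
        heavy = _simulate_chain(rng, config, "Heavy", *keys["Heavy"])
        light = _simulate_chain(rng, config, light_type, *keys[light_type])
        cells.append(
            CellSim(
                cell_id=f"C{i + 1:04d}",
                plate_barcode=format_barcode("FACS_", plate_i + 1),
                well=index_to_well_label(well_i, fmt),
                heavy=heavy,
                light=light,
            )
        )
    return Cohort(config=config, cells=tuple(cells))


def funnel_counts(cohort: Cohort) -> dict[str, int]:
    """Cells surviving each workflow stage (both chains alive), in order.

    Monotonically non-increasing by construction; with all probabilities at
    1.0 every stage equals ``n_cells``.
    """
    counts = {stage: 0 for stage in FUNNEL_STAGES}
    counts["sorted_cells"] = len(cohort.cells)
    counts["cdna"] = len(cohort.cells)  # reverse transcription is not a gate here
    for cell in cohort.cells:
        h, l = cell.heavy.alive_through(), cell.light.alive_through()
        for gate_i, stage in enumerate(FUNNEL_STAGES[2:8]):
            if h[gate_i] and l[gate_i]:
                counts[stage] += 1
        if cell.pair_survives():
            counts["transfection_pairs"] += 1
    return counts


# ---------------------------------------------------------------------------
# file emission — the same dialects the ingest functions consume


def write_cohort_files(cohort: Cohort, directory: str | Path) -> dict[str, Path]:
    """Emit the cohort as the pipeline's intermediate files.

    Returns a name -> path map: FACS layout, first/final electrophoresis
    readouts, allele-call table, plasmid concentrations, final-sequencing
    outcomes and harvested-antibody quantification.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    facs = pd.DataFrame(
        [{"cell_id": c.cell_id, "plate_barcode": c.plate_barcode, "well": c.well}
         for c in cohort.cells],
        columns=["cell_id", "plate_barcode", "well"],
    )
    paths["facs_layout"] = directory / "facs_layout.csv"
    facs.to_csv(paths["facs_layout"], index=False)

    cele1 = [
        ChainReadout(
            sample_id=sid,
            plate_barcode=f"{cell.plate_barcode}_{_CHAIN_SUFFIX[sim.chain]}",
            well=WellAddress.parse(cell.well),
            chain=sim.chain,
            band_size_bp=sim.cele1_band_bp,
        )
        for cell, sim, sid in cohort.chain_samples()
    ]
    paths["cele1"] = directory / "cele1_readout.csv"
    write_electrophoresis(cele1, paths["cele1"])

    calls = pd.DataFrame(
        [
            {
                "sample_id": sid,
                "chain": sim.chain,
                "v_allele": sim.v_allele,
                "j_allele": sim.j_allele,
                "evaluation": "functional" if sim.seq1_functional else "failed",
                "plate_barcode": f"{cell.plate_barcode}_{_CHAIN_SUFFIX[sim.chain]}",
                "well": cell.well,
            }
            for cell, sim, sid in cohort.chain_samples()
            if sim.cele1_passed
        ],
        columns=ALLELE_CALL_COLUMNS,
    )
    paths["allele_calls"] = directory / "allele_calls.csv"
    calls.to_csv(paths["allele_calls"], index=False)

    fmt = PlateFormat.plate_96()
    cele2_rows = []
    i = 0
    for cell, sim, sid in cohort.chain_samples():
        if not (sim.cele1_passed and sim.seq1_functional):
            continue
        plate_i, well_i = divmod(i, fmt.n_wells)
        cele2_rows.append(
            ChainReadout(
                sample_id=sid,
                plate_barcode=format_barcode("PCR3_", plate_i + 1),
                well=WellAddress.parse(index_to_well_label(well_i, fmt)),
                chain=sim.chain,
                band_size_bp=sim.cele2_band_bp,
            )
        )
        i += 1
    paths["cele2"] = directory / "cele2_readout.csv"
    write_electrophoresis(cele2_rows, paths["cele2"])

    minipreps = [
        ConcentrationReading(
            sample_id=sid,
            concentration_ng_ul=sim.concentration_ng_ul,
            plate_barcode="MINI_001",
            well=None,
        )
        for cell, sim, sid in cohort.chain_samples()
        if all(sim.alive_through()[:5])  # reached plasmid isolation
    ]
    paths["plasmid_concentrations"] = directory / "plasmid_concentrations.csv"
    _write_concentrations_no_well(minipreps, paths["plasmid_concentrations"])

    seq2 = pd.DataFrame(
        [
            {"sample_id": sid, "status": "passed" if sim.seq2_passed else "failed"}
            for cell, sim, sid in cohort.chain_samples()
            if all(sim.alive_through()[:5])
        ],
        columns=["sample_id", "status"],
    )
    paths["seq2_results"] = directory / "seq2_results.csv"
    seq2.to_csv(paths["seq2_results"], index=False)

    quant_rows = []
    j = 0
    rng = np.random.default_rng(cohort.config.seed + 1)
    for cell in cohort.cells:
        if not cell.pair_survives():
            continue
        plate_i, well_i = divmod(j, fmt.n_wells)
        quant_rows.append(
            ConcentrationReading(
                sample_id=cell.cell_id,
                concentration_ng_ul=float(round(rng.lognormal(np.log(50.0), 0.4), 1)),
                plate_barcode=format_barcode("TRAF_", plate_i + 1),
                well=WellAddress.parse(index_to_well_label(well_i, fmt)),
            )
        )
        j += 1
    paths["quantification"] = directory / "mab_quantification.csv"
    write_quantification(quant_rows, paths["quantification"])

    logger.info("cohort of %d cells written to %s (%d files)", len(cohort.cells), directory, len(paths))
    return paths


def _write_concentrations_no_well(readings, path):
    pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "plate_barcode": r.plate_barcode,
                "well": r.well.label if r.well else "",
                "concentration_ng_ul": (
                    str(int(r.concentration_ng_ul))
                    if float(r.concentration_ng_ul).is_integer()
                    else repr(float(r.concentration_ng_ul))
                ),
            }
            for r in readings
        ],
        columns=["sample_id", "plate_barcode", "well", "concentration_ng_ul"],
    ).to_csv(path, index=False)


def allele_calls(cohort: Cohort, passed_only: bool = True) -> list[AlleleCall]:
    """The cohort's allele calls as typed records (functional calls of
    band-passed chains by default)."""
    out = []
    for cell, sim, sid in cohort.chain_samples():
        if passed_only and not (sim.cele1_passed and sim.seq1_functional):
            continue
        out.append(
            AlleleCall(
                sample_id=sid,
                chain=sim.chain,
                v_allele=sim.v_allele,
                j_allele=sim.j_allele,
                evaluation="functional" if sim.seq1_functional else "failed",
                plate_barcode=f"{cell.plate_barcode}_{_CHAIN_SUFFIX[sim.chain]}",
                well=WellAddress.parse(cell.well),
            )
        )
    return out


def pcr3_store_list(cohort: Cohort, step: str = "PCR3") -> StoreList:
    """Queue of chain samples awaiting the final PCR, with strictly
    increasing synthetic enqueue timestamps (deterministic FIFO order)."""
    entries = []
    t = _BASE_TIME
    for cell, sim, sid in cohort.chain_samples():
        if not (sim.cele1_passed and sim.seq1_functional):
            continue
        t += timedelta(seconds=1)
        entries.append(
            StoreEntry(
                sample_id=sid,
                plate_barcode=f"{cell.plate_barcode}_{_CHAIN_SUFFIX[sim.chain]}",
                well=WellAddress.parse(cell.well),
                enqueued_at=t,
            )
        )
    return StoreList(step=step, entries=tuple(entries))


def populate_store(cohort: Cohort, store: LineageStore | None = None) -> LineageStore:
    """Register the cohort's full lineage chains in a store.

    Builds FACS -> cDNA roots per cell, per-chain chains as far as each
    chain survived, and transfection/antibody/quantification records for
    surviving pairs.  Record IDs are seeded from the cohort config, so the
    store contents are reproducible.
    """
    if store is None:
        store = LineageStore(
            id_rng=random.Random(cohort.config.seed),
            clock=_ticking_clock(),
        )
    for cell in cohort.cells:
        facs = store.register(
            "FACS",
            {"donor_id": "D001", "plate_barcode": cell.plate_barcode, "well": cell.well},
        )
        cdna = store.register(
            "cDNA", {"plate_barcode": cell.plate_barcode, "well": cell.well},
            {"FK_FACS_ID": facs},
        )
        stock_ids: dict[str, RecordID] = {}
        for sim in (cell.heavy, cell.light):
            stock = _register_chain_records(store, cell, sim, cdna)
            if stock is not None:
                stock_ids[sim.chain] = stock
        if cell.pair_survives():
            heavy_stock = stock_ids["Heavy"]
            light_stock = stock_ids[cell.light.chain]
            traf = store.register(
                "Transfection",
                {"plate_barcode": "TRAF_001", "well": cell.well},
                {"FK_Heavy_Working_Stock_ID": heavy_stock,
                 "FK_Light_Working_Stock_ID": light_stock},
            )
            ab = store.register("AB", {"harvest_date": "2025-02-01"}, {"FK_Transfection_ID": traf})
            store.register("quant", {"concentration_ug_ml": 50.0}, {"FK_AB_ID": ab})
    return store


def _register_chain_records(store, cell, sim: ChainSim, cdna) -> RecordID | None:
    suffix = _CHAIN_SUFFIX[sim.chain]
    pcr1 = store.register(
        "PCR1",
        {"chain": sim.chain, "plate_barcode": f"{cell.plate_barcode}_{suffix}", "well": cell.well},
        {"FK_cDNA_ID": cdna},
    )
    pcr2 = store.register(
        "PCR2", {"plate_barcode": f"PCR2_{suffix}", "well": cell.well}, {"FK_PCR1_ID": pcr1}
    )
    cele1 = store.register(
        "cELE1",
        {"band_size_bp": sim.cele1_band_bp, "status": "passed" if sim.cele1_passed else "failed"},
        {"FK_PCR2_ID": pcr2},
    )
    if not sim.cele1_passed:
        return None
    seq1 = store.register(
        "SEQ1",
        {"v_allele": sim.v_allele, "j_allele": sim.j_allele,
         "evaluation": "functional" if sim.seq1_functional else "failed"},
        {"FK_cELE1_ID": cele1},
    )
    if not sim.seq1_functional:
        return None
    pcr3 = store.register(
        "PCR3", {"plate_barcode": "PCR3_001", "well": cell.well}, {"FK_SEQ1_ID": seq1}
    )
    cele2 = store.register(
        "cELE2",
        {"band_size_bp": sim.cele2_band_bp, "status": "passed" if sim.cele2_passed else "failed"},
        {"FK_PCR3_ID": pcr3},
    )
    if not sim.cele2_passed:
        return None
    gias = store.register("GiAs", {"plate_barcode": "GIAS_001", "well": cell.well}, {"FK_cELE2_ID": cele2})
    if not sim.cloned:
        return None
    trfo = store.register("TRFO", {"plate_barcode": "TRFO_001", "well": cell.well}, {"FK_GiAs_ID": gias})
    plating = store.register(
        "Plating", {"plate_barcode": f"PLATE_{cell.cell_id}_{suffix}"}, {"FK_TRFO_ID": trfo}
    )
    if not sim.colony_picked:
        return None
    picking = store.register("Picking", {"colony_number": 1}, {"FK_Plating_ID": plating})
    stock = store.register(
        "Working_Stock",
        {"chain": sim.chain, "concentration_ng_ul": sim.concentration_ng_ul,
         "seq2_status": "passed" if sim.seq2_passed else "failed"},
        {"FK_Picking_ID": picking},
    )
    return stock if sim.seq2_passed else None


def _ticking_clock():
    """Strictly increasing deterministic timestamps for reproducible stores."""
    state = {"t": _BASE_TIME}

    def clock() -> str:
        state["t"] += timedelta(seconds=1)
        return state["t"].isoformat()

    return clock
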
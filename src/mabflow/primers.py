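"""Three-step PCR strategy: mix scheduling and allele-specific primer lookup.

Antibody heavy and light chains are amplified in three successive PCRs.  The
first two use per-chain forward/reverse primer *mixes* (the V(D)J segment
used by a given B-cell is unknown at that point); after the second-PCR
amplicon is sequenced and its V and J alleles are called, the final PCR uses
a *specific* primer pair selected from a registry of 69 individual primers
keyed by V- and J-allele patterns.

The packaged default registry mirrors that structure — 69 final-PCR primers
spanning the heavy, kappa and lambda chains, keyed by standard human
immunoglobulin gene names — with synthetic placeholder sequences (the
registry's structure and counts drive the pipeline; oligo sequences do not).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import InputValidationError, PrimerLookupError, RegistryError
from .plates import PlateFormat, ScanOrder, WellAddress, index_to_well_label
from .readouts import CHAINS

logger = logging.getLogger(__name__)

__all__ = [
    "PrimerRecord",
    "PrimerRegistry",
    "AlleleCall",
    "PCRReaction",
    "LookupRow",
    "load_registry",
    "default_registry",
    "chain_type_of",
    "schedule_pcr1",
    "select_pcr3_pair",
    "build_pcr3_lookup",
]

REGISTRY_COLUMNS = ["name", "pcr_stage", "chain", "direction", "allele_keys", "sequence"]

_LOCUS_TO_CHAIN = {"IGH": "Heavy", "IGK": "Kappa", "IGL": "Lambda"}


@dataclass(frozen=True)
class PrimerRecord:
    """One primer: stage, chain, direction, and (for the final PCR) the
    V-/J-allele patterns it amplifies."""

    name: str
    pcr_stage: str  # PCR1 | PCR2 | PCR3
    chain: str
    direction: str  # forward | reverse
    allele_keys: tuple[str, ...] = ()
    sequence: str = ""

    def __post_init__(self):
        if self.pcr_stage not in ("PCR1", "PCR2", "PCR3"):
            raise RegistryError(f"primer {self.name!r}: unknown stage {self.pcr_stage!r}")
        if self.chain not in CHAINS:
            raise RegistryError(f"primer {self.name!r}: unknown chain {self.chain!r}")
        if self.direction not in ("forward", "reverse"):
            raise RegistryError(f"primer {self.name!r}: direction must be forward/reverse")
        if self.pcr_stage == "PCR3" and not self.allele_keys:
            raise RegistryError(f"final-PCR primer {self.name!r} lacks an allele key")


@dataclass(frozen=True)
class AlleleCall:
    """Per-sample V/J allele call from sequence evaluation."""

    sample_id: str
    chain: str
    v_allele: str
    j_allele: str
    evaluation: str = "functional"  # functional | failed
    plate_barcode: str = ""
    well: WellAddress | None = None


@dataclass(frozen=True)
class PCRReaction:
    """One scheduled first-PCR reaction (one chain of one cDNA sample)."""

    sample_id: str
    chain: str
    plate_barcode: str
    well: WellAddress
    forward_mix: str
    reverse_mix: str


@dataclass(frozen=True)
class LookupRow:
    """One line of the final-PCR lookup table / liquid-handler worklist."""

    sample_id: str
    source_plate: str
    source_well: str
    dest_plate: str
    dest_well: str
    forward_primer: str
    reverse_primer: str


class PrimerRegistry:
    """Primer set indexed by (stage, chain, direction).

    Records are canonically sorted at construction (stage, chain, direction,
    name), so lookups are deterministic regardless of file row order.
    """

    def __init__(self, records: Iterable[PrimerRecord]):
        self.records: list[PrimerRecord] = sorted(
            records, key=lambda r: (r.pcr_stage, r.chain, r.direction, r.name)
        )
        names = [r.name for r in self.records]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise RegistryError(f"duplicate primer names in registry: {sorted(dupes)}")
        self._index: dict[tuple[str, str, str], list[PrimerRecord]] = {}
        for r in self.records:
            self._index.setdefault((r.pcr_stage, r.chain, r.direction), []).append(r)

    def __len__(self) -> int:
        return len(self.records)

    def pcr3_records(self) -> list[PrimerRecord]:
        return [r for r in self.records if r.pcr_stage == "PCR3"]

    def candidates(self, stage: str, chain: str, direction: str) -> list[PrimerRecord]:
        return self._index.get((stage, chain, direction), [])

    def mix_name(self, stage: str, chain: str, direction: str) -> str:
        cands = self.candidates(stage, chain, direction)
        if not cands:
            raise PrimerLookupError(f"no {stage} {direction} mix for {chain} chain in registry")
        return cands[0].name

    def lookup(self, stage: str, chain: str, direction: str, allele: str) -> PrimerRecord:
        """Deterministic allele-keyed lookup for final-PCR primers.

        A key matches when it is a prefix of the allele call ending at a
        gene-name boundary (so the gene-level key IGHV1-2 matches IGHV1-2*02
        but not IGHV1-24*01).  Among matches the longest key wins; ties are
        broken by registry order.
        """
        cands = self.candidates(stage, chain, direction)
        if not cands:
            raise PrimerLookupError(
                f"registry has no {stage} {direction} primers for {chain} chain",
                allele=allele,
            )
        best: PrimerRecord | None = None
        best_len = -1
        for rec in cands:
            for key in rec.allele_keys:
                if _key_matches(key, allele) and len(key) > best_len:
                    best, best_len = rec, len(key)
        if best is None:
            raise PrimerLookupError(
                f"no {direction} primer for allele {allele!r} ({chain} chain)", allele=allele
            )
        return best

    def allele_keys(self, chain: str, direction: str) -> list[str]:
        """All final-PCR allele keys for a chain/direction (used to sample
        registry-resolvable synthetic calls)."""
        out: list[str] = []
        for rec in self.candidates("PCR3", chain, direction):
            out.extend(rec.allele_keys)
        return out


def _key_matches(key: str, allele: str) -> bool:
    if not allele.startswith(key):
        return False
    rest = allele[len(key):]
    return rest == "" or not rest[0].isdigit()


def load_registry(path: str | Path) -> PrimerRegistry:
    """Load a primer registry from a delimited-text file (or .xlsx sheet)."""
    p = Path(path)
    if p.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(p, dtype=str).fillna("")
    else:
        df = pd.read_csv(p, dtype=str, keep_default_na=False)
    missing = [c for c in REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise RegistryError(f"{p.name}: registry file lacks columns {missing}")
    records = [
        PrimerRecord(
            name=row["name"],
            pcr_stage=row["pcr_stage"],
            chain=row["chain"],
            direction=row["direction"],
            allele_keys=tuple(k for k in row["allele_keys"].split(";") if k),
            sequence=row["sequence"],
        )
        for _, row in df.iterrows()
    ]
    reg = PrimerRegistry(records)
    logger.info("%s: loaded %d primers (%d final-PCR)", p.name, len(reg), len(reg.pcr3_records()))
    return reg


def default_registry() -> PrimerRegistry:
    """The packaged registry: PCR1/PCR2 mixes plus 69 allele-keyed final-PCR primers."""
    with resources.as_file(resources.files("mabflow") / "data" / "primer_registry.csv") as p:
        return load_registry(p)


def chain_type_of(allele: str) -> str:
    """Chain type implied by an immunoglobulin allele name's locus prefix."""
    prefix = allele[:3].upper()
    chain = _LOCUS_TO_CHAIN.get(prefix)
    if chain is None:
        raise InputValidationError(
            f"allele {allele!r} does not start with an immunoglobulin locus (IGH/IGK/IGL)"
        )
    return chain


def schedule_pcr1(
    cdna_samples: Sequence,
    registry: PrimerRegistry | None = None,
) -> list[PCRReaction]:
    """Plan the first PCR: three parallel per-chain reactions per cDNA sample.

    Each sample is amplified once with the heavy, kappa and lambda primer
    mixes on per-chain plates that mirror the source layout (same well, the
    chain name appended to the plate barcode).
    """
    if not cdna_samples:
        raise InputValidationError("no cDNA samples to schedule")
    if registry is None:
        registry = default_registry()
    reactions: list[PCRReaction] = []
    for s in cdna_samples:
        well = s.well if isinstance(s.well, WellAddress) else WellAddress.parse(s.well)
        for chain in CHAINS:
            reactions.append(
                PCRReaction(
                    sample_id=s.sample_id,
                    chain=chain,
                    plate_barcode=f"{s.plate_barcode}_{chain}",
                    well=well,
                    forward_mix=registry.mix_name("PCR1", chain, "forward"),
                    reverse_mix=registry.mix_name("PCR1", chain, "reverse"),
                )
            )
    return reactions


def select_pcr3_pair(
    call: AlleleCall, registry: PrimerRegistry
) -> tuple[PrimerRecord, PrimerRecord]:
    """Pick the specific (forward, reverse) final-PCR pair for one allele call.

    The forward primer is keyed by the V allele, the reverse by the J
    allele, both within the call's chain.  Requires a functional sequence
    evaluation; selection is deterministic for a given registry.
    """
    if call.evaluation != "functional":
        raise InputValidationError(
            f"sample {call.sample_id}: cannot select primers for a call "
            f"with evaluation {call.evaluation!r}"
        )
    if chain_type_of(call.v_allele) != call.chain:
        raise InputValidationError(
            f"sample {call.sample_id}: V allele {call.v_allele!r} is not a "
            f"{call.chain}-chain locus"
        )
    fwd = registry.lookup("PCR3", call.chain, "forward", call.v_allele)
    rev = registry.lookup("PCR3", call.chain, "reverse", call.j_allele)
    return fwd, rev


def build_pcr3_lookup(
    calls: Sequence[AlleleCall],
    registry: PrimerRegistry,
    dest_barcodes: Sequence[str],
    plate_format: PlateFormat | None = None,
    order: ScanOrder = ScanOrder.ROW_MAJOR,
) -> tuple[list[LookupRow], list[tuple[AlleleCall, str]]]:
    """Build the final-PCR lookup table for a batch of passed allele calls.

    Destination wells are assigned in scan order on the freshly barcoded
    plates.  Calls with no matching primer are collected into a rejection
    report (second return value) rather than aborting the batch.
    """
    fmt = plate_format or PlateFormat.plate_96()
    rows: list[LookupRow] = []
    rejections: list[tuple[AlleleCall, str]] = []
    resolved: list[tuple[AlleleCall, PrimerRecord, PrimerRecord]] = []
    for call in calls:
        try:
            fwd, rev = select_pcr3_pair(call, registry)
            resolved.append((call, fwd, rev))
        except (PrimerLookupError, InputValidationError) as exc:
            rejections.append((call, str(exc)))
    n_plates_needed = -(-len(resolved) // fmt.n_wells) if resolved else 0
    if n_plates_needed > len(dest_barcodes):
        raise InputValidationError(
            f"{len(resolved)} samples need {n_plates_needed} destination plates, "
            f"only {len(dest_barcodes)} barcodes supplied"
        )
    for i, (call, fwd, rev) in enumerate(resolved):
        plate_i, well_i = divmod(i, fmt.n_wells)
        rows.append(
            LookupRow(
                sample_id=call.sample_id,
                source_plate=call.plate_barcode,
                source_well=call.well.label if call.well else "",
                dest_plate=dest_barcodes[plate_i],
                dest_well=index_to_well_label(well_i, fmt, order),
                forward_primer=fwd.name,
                reverse_primer=rev.name,
            )
        )
    if not rows:
        logger.warning("final-PCR lookup table is empty (no resolvable calls)")
    if rejections:
        logger.warning("%d calls had no matching primer and were rejected", len(rejections))
    return rows, rejections


def read_allele_calls(path: str | Path, expected_header: Sequence[str] | None = None) -> list[AlleleCall]:
    """Load a sequence-evaluation result table (one V/J call per sample).

    The file emulates the third-party sequence-analysis output consumed by
    the pipeline: sample, chain, V and J alleles and a functional/failed
    evaluation, plus the sample's plate position.
    """
    from .errors import HeaderValidationError

    expected = list(expected_header) if expected_header else [
        "sample_id", "chain", "v_allele", "j_allele", "evaluation", "plate_barcode", "well",
    ]
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != expected:
        missing = [c for c in expected if c not in df.columns]
        extra = [c for c in df.columns if c not in expected]
        raise HeaderValidationError(
            f"{Path(path).name}: allele-call header mismatch — missing {missing}, "
            f"unexpected {extra}",
            missing=missing,
            extra=extra,
        )
    return [
        AlleleCall(
            sample_id=row["sample_id"],
            chain=row["chain"],
            v_allele=row["v_allele"],
            j_allele=row["j_allele"],
            evaluation=row["evaluation"],
            plate_barcode=row["plate_barcode"],
            well=WellAddress.parse(row["well"]) if row["well"] else None,
        )
        for _, row in df.iterrows()
    ]


def write_lookup_table(rows: Iterable[LookupRow], path: str | Path) -> None:
    """Write a lookup table as a liquid-handler-consumable CSV worklist."""
    pd.DataFrame([r.__dict__ for r in rows], columns=list(LookupRow.__dataclass_fields__)).to_csv(
        path, index=False
    )
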
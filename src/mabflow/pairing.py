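"""Heavy/light plasmid pairing, transfection planning and repicking.

An antibody needs one heavy-chain and one light-chain plasmid cloned from
the same originating single-cell cDNA, and both must have passed sequence
quality control.  This module matches passed plasmids into transfection
pairs, lays matched pairs out on transfection plates (refusing to lay out
anything when the heavy and light input tables disagree in size), and turns
failed plasmids into colony repick candidates that reuse the already
registered bacteria-plate record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .errors import CountMismatchError, InputValidationError, LineageError
from .lineage import LineageStore, RecordID
from .plates import PlateFormat, ScanOrder, index_to_well_label

logger = logging.getLogger(__name__)

__all__ = [
    "PlasmidRecord",
    "TransfectionPair",
    "PairingResult",
    "RepickCandidate",
    "match_pairs",
    "plan_transfection",
    "repick_candidates",
    "DEFAULT_MAX_PICKS",
]

LIGHT_CHAINS = ("Kappa", "Lambda")
DEFAULT_MAX_PICKS = 3


@dataclass(frozen=True)
class PlasmidRecord:
    """A sequenced expression plasmid carrying one antibody chain."""

    plasmid_id: str
    cdna_id: str
    chain: str  # Heavy | Kappa | Lambda
    qc: str = "pending"  # pending | passed | failed

    def __post_init__(self):
        if self.chain not in ("Heavy", *LIGHT_CHAINS):
            raise InputValidationError(f"unknown chain {self.chain!r}")
        if self.qc not in ("pending", "passed", "failed"):
            raise InputValidationError(f"unknown QC state {self.qc!r}")


@dataclass(frozen=True)
class TransfectionPair:
    heavy: PlasmidRecord
    light: PlasmidRecord
    well: str = ""
    plate: str = ""

    def __post_init__(self):
        if self.heavy.chain != "Heavy":
            raise InputValidationError("heavy slot must hold a heavy-chain plasmid")
        if self.light.chain not in LIGHT_CHAINS:
            raise InputValidationError("light slot must hold a kappa or lambda plasmid")
        if self.heavy.cdna_id != self.light.cdna_id:
            raise InputValidationError(
                f"pair crosses cDNAs: {self.heavy.cdna_id} vs {self.light.cdna_id}"
            )
        if self.heavy.qc != "passed" or self.light.qc != "passed":
            raise InputValidationError("both plasmids of a pair must have passed QC")


@dataclass(frozen=True)
class PairingResult:
    """Disjoint partition of the passed plasmids.

    ``pairs`` holds matched heavy+light plasmids; ``unmatched_heavy`` /
    ``unmatched_light`` are passed plasmids whose partner chain is missing
    (these drive repetition of the partner chain's workflow steps);
    ``ambiguous`` holds plasmids from cDNAs with both a passed kappa and a
    passed lambda, set aside for manual review.
    """

    pairs: tuple[TransfectionPair, ...]
    unmatched_heavy: tuple[PlasmidRecord, ...]
    unmatched_light: tuple[PlasmidRecord, ...]
    ambiguous: tuple[PlasmidRecord, ...] = ()


def match_pairs(plasmids: Sequence[PlasmidRecord]) -> PairingResult:
    """Match passed heavy and light plasmids cloned from the same cDNA.

    Pairing is strictly one-to-one per cDNA, first-registered plasmid first;
    surplus passed plasmids of a chain stay unmatched.  A cDNA with both a
    passed kappa and a passed lambda is flagged ambiguous and excluded from
    pairing.  Every passed plasmid lands in exactly one output bucket.
    """
    by_cdna: dict[str, list[PlasmidRecord]] = {}
    for p in plasmids:
        if p.qc == "passed":
            by_cdna.setdefault(p.cdna_id, []).append(p)

    pairs: list[TransfectionPair] = []
    unmatched_h: list[PlasmidRecord] = []
    unmatched_l: list[PlasmidRecord] = []
    ambiguous: list[PlasmidRecord] = []
    for cdna_id in by_cdna:  # insertion order = registration age
        group = by_cdna[cdna_id]
        heavies = [p for p in group if p.chain == "Heavy"]
        kappas = [p for p in group if p.chain == "Kappa"]
        lambdas = [p for p in group if p.chain == "Lambda"]
        if kappas and lambdas:
            ambiguous.extend(group)
            logger.warning(
                "cDNA %s has passed plasmids of both light-chain types "
                "(%d kappa, %d lambda); flagged for manual review",
                cdna_id, len(kappas), len(lambdas),
            )
            continue
        lights = kappas or lambdas
        if heavies and lights:
            pairs.append(TransfectionPair(heavy=heavies[0], light=lights[0]))
            unmatched_h.extend(heavies[1:])
            unmatched_l.extend(lights[1:])
        else:
            unmatched_h.extend(heavies)
            unmatched_l.extend(lights)
    logger.info(
        "pair matching: %d pairs, %d unmatched heavy, %d unmatched light, %d ambiguous",
        len(pairs), len(unmatched_h), len(unmatched_l), len(ambiguous),
    )
    return PairingResult(
        pairs=tuple(pairs),
        unmatched_heavy=tuple(unmatched_h),
        unmatched_light=tuple(unmatched_l),
        ambiguous=tuple(ambiguous),
    )


def plan_transfection(
    heavy: Sequence[PlasmidRecord],
    light: Sequence[PlasmidRecord],
    plate_format: PlateFormat | None = None,
    plate_barcode: str = "TRAF_001",
    order: ScanOrder = ScanOrder.ROW_MAJOR,
) -> list[TransfectionPair]:
    """Lay matched pairs out on a transfection plate.

    The heavy and light input tables must hold the same number of rows —
    split samples pivot unevenly often enough that this is checked *before*
    any layout is produced — and must pair up one-to-one by cDNA.  Pairs are
    placed in scan order.
    """
    if len(heavy) != len(light):
        raise CountMismatchError(
            f"uneven plasmid tables parsed for transfection: "
            f"{len(heavy)} heavy vs {len(light)} light rows"
        )
    if not heavy:
        logger.warning("transfection layout is empty (no pairs)")
        return []
    fmt = plate_format or PlateFormat.plate_96()
    if len(heavy) > fmt.n_wells:
        raise InputValidationError(
            f"{len(heavy)} pairs exceed one {fmt} transfection plate"
        )
    light_by_cdna = {p.cdna_id: p for p in light}
    if len(light_by_cdna) != len(light):
        raise InputValidationError("light table contains repeated cDNA IDs")
    layout: list[TransfectionPair] = []
    for i, h in enumerate(heavy):
        partner = light_by_cdna.get(h.cdna_id)
        if partner is None:
            raise InputValidationError(
                f"heavy plasmid {h.plasmid_id} (cDNA {h.cdna_id}) has no light partner row"
            )
        layout.append(
            TransfectionPair(
                heavy=h,
                light=partner,
                well=index_to_well_label(i, fmt, order),
                plate=plate_barcode,
            )
        )
    return layout


def transfection_import_rows(
    layout: Sequence[TransfectionPair], store: LineageStore
) -> list[RecordID]:
    """Register each laid-out pair as a transfection record linked to its two
    plasmid working-stock ancestors; returns the new record IDs."""
    out = []
    for pair in layout:
        rid = store.register(
            "Transfection",
            payload={"plate_barcode": pair.plate, "well": pair.well},
            parents={
                "FK_Heavy_Working_Stock_ID": pair.heavy.plasmid_id,
                "FK_Light_Working_Stock_ID": pair.light.plasmid_id,
            },
        )
        out.append(rid)
    return out


def write_transfection_layout(layout: Sequence[TransfectionPair], path) -> None:
    pd.DataFrame(
        [
            {
                "plate_barcode": p.plate,
                "well": p.well,
                "heavy_plasmid_id": p.heavy.plasmid_id,
                "light_plasmid_id": p.light.plasmid_id,
            }
            for p in layout
        ],
        columns=["plate_barcode", "well", "heavy_plasmid_id", "light_plasmid_id"],
    ).to_csv(path, index=False)


@dataclass(frozen=True)
class RepickCandidate:
    """A colony slot to re-pick for a failed plasmid.

    References the *existing* bacteria-plate record (no re-registration);
    ``replate`` marks plates whose pick capacity is exhausted.
    """

    plasmid_id: str
    plating_id: str
    plate_barcode: str
    replate: bool = False


def repick_candidates(
    seq2_results: Mapping[str, str],
    store: LineageStore,
    max_picks: int = DEFAULT_MAX_PICKS,
) -> list[RepickCandidate]:
    """Compute colonies to re-pick after failed plasmid sequencing.

    ``seq2_results`` maps plasmid working-stock record IDs to "passed" /
    "failed".  Each failed plasmid is traced to its bacteria-plate (plating)
    record; if the plate still has pick capacity (fewer than ``max_picks``
    pickings registered against it) a candidate reusing the original plating
    ID is emitted, otherwise the plate is flagged for replating.
    """
    candidates: list[RepickCandidate] = []
    picks_planned: dict[str, int] = {}
    for plasmid_id, status in seq2_results.items():
        if status != "failed":
            continue
        platings = [
            r for r in store.trace_lineage(plasmid_id) if r.table == "Plating"
        ]
        if not platings:
            raise LineageError(
                f"failed plasmid {plasmid_id} has no bacteria-plating ancestor"
            )
        plating = platings[0]
        key = str(plating.id)
        used = len(store.children_of(plating.id, "Picking")) + picks_planned.get(key, 0)
        if used >= max_picks:
            candidates.append(
                RepickCandidate(
                    plasmid_id=str(plasmid_id),
                    plating_id=key,
                    plate_barcode=str(plating.payload.get("plate_barcode") or ""),
                    replate=True,
                )
            )
        else:
            picks_planned[key] = picks_planned.get(key, 0) + 1
            candidates.append(
                RepickCandidate(
                    plasmid_id=str(plasmid_id),
                    plating_id=key,
                    plate_barcode=str(plating.payload.get("plate_barcode") or ""),
                )
            )
    return candidates


def write_repick_list(candidates: Sequence[RepickCandidate], path) -> None:
    pd.DataFrame(
        [c.__dict__ for c in candidates],
        columns=list(RepickCandidate.__dataclass_fields__),
    ).to_csv(path, index=False)
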
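"""Instrument-readout ingestion and the band-size selection funnel.

Capillary-electrophoresis exports are consumed as delimited text tables, one
row per (plate, well, chain) with a band size in base pairs; a missing band
is encoded as 0 bp.  Quantification exports carry antibody or plasmid
concentrations instead.  Headers are validated against the configured
expectation so silent instrument-software changes fail loudly, and the
band-size threshold filter partitions readouts into passed and failed sets
for the next workflow step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import HeaderValidationError, InputValidationError, RowValidationError
from .plates import PlateFormat, WellAddress

logger = logging.getLogger(__name__)

__all__ = [
    "Chain",
    "ChainReadout",
    "ConcentrationReading",
    "DilutionPlan",
    "ELECTROPHORESIS_COLUMNS",
    "QUANTIFICATION_COLUMNS",
    "parse_electrophoresis",
    "write_electrophoresis",
    "select_by_band_size",
    "concentration_adjustment",
    "parse_quantification",
    "write_quantification",
]

# canonical intermediate-file headers (override per instrument in the config)
ELECTROPHORESIS_COLUMNS = ["sample_id", "plate_barcode", "well", "chain", "band_size_bp"]
QUANTIFICATION_COLUMNS = ["sample_id", "plate_barcode", "well", "concentration_ng_ul"]

CHAINS = ("Heavy", "Kappa", "Lambda")


class Chain:
    """Antibody chain names (heavy chain, and the two light-chain types)."""

    HEAVY = "Heavy"
    KAPPA = "Kappa"
    LAMBDA = "Lambda"
    ALL = CHAINS


@dataclass(frozen=True)
class ChainReadout:
    """One sample's per-chain electrophoresis measurement at a workflow step."""

    sample_id: str
    plate_barcode: str
    well: WellAddress
    chain: str
    band_size_bp: float  # 0 means no band detected
    status: str = "pending"  # pending | passed | failed

    def __post_init__(self):
        if self.chain not in CHAINS:
            raise InputValidationError(f"unknown chain {self.chain!r} (expected one of {CHAINS})")
        if self.band_size_bp < 0:
            raise InputValidationError(f"band size must be >= 0 bp, got {self.band_size_bp}")


@dataclass(frozen=True)
class ConcentrationReading:
    """A measured concentration against its target, with available volume."""

    sample_id: str
    concentration_ng_ul: float
    target_ng_ul: float = 0.0
    volume_available_ul: float = 0.0
    plate_barcode: str = ""
    well: WellAddress | None = None

    def __post_init__(self):
        for name in ("concentration_ng_ul", "target_ng_ul", "volume_available_ul"):
            if getattr(self, name) < 0:
                raise InputValidationError(f"{name} must be non-negative")


@dataclass(frozen=True)
class DilutionPlan:
    """Volumes solving C1*V1 = C2*V2 for one sample."""

    stock_volume_ul: float
    diluent_volume_ul: float
    below_target: bool = False
    insufficient_volume: bool = False


def _check_header(df: pd.DataFrame, expected: Sequence[str], path) -> None:
    header = list(df.columns)
    if header != list(expected):
        missing = [c for c in expected if c not in header]
        extra = [c for c in header if c not in expected]
        raise HeaderValidationError(
            f"{Path(path).name}: unexpected header — missing columns {missing}, "
            f"unexpected columns {extra}",
            missing=missing,
            extra=extra,
        )


def parse_electrophoresis(
    path: str | Path,
    expected_header: Sequence[str] = ELECTROPHORESIS_COLUMNS,
    plate_format: PlateFormat | None = None,
    delimiter: str = ",",
) -> list[ChainReadout]:
    """Load a capillary-electrophoresis readout file.

    Returns one :class:`ChainReadout` per data row; well labels are
    validated (against ``plate_format`` when given).  A renamed or missing
    column raises :class:`HeaderValidationError`; unparseable band sizes are
    collected into a per-row :class:`RowValidationError`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, sep=delimiter)
    _check_header(df, expected_header, path)
    readouts: list[ChainReadout] = []
    row_errors: list[str] = []
    for i, row in df.iterrows():
        line = i + 2
        try:
            band = float(row["band_size_bp"])
            if band < 0:
                raise ValueError("negative band size")
            well = WellAddress.parse(row["well"])
            if plate_format is not None:
                well.check_on(plate_format)
            readouts.append(
                ChainReadout(
                    sample_id=row["sample_id"],
                    plate_barcode=row["plate_barcode"],
                    well=well,
                    chain=row["chain"],
                    band_size_bp=band,
                )
            )
        except (ValueError, InputValidationError) as exc:
            row_errors.append(f"line {line}: {exc}")
        except Exception as exc:  # addressing errors carry their own message
            row_errors.append(f"line {line}: {exc}")
    if row_errors:
        raise RowValidationError(
            f"{Path(path).name}: {len(row_errors)} unparseable rows", row_errors=row_errors
        )
    if not readouts:
        logger.warning("%s: readout file has an empty data section", Path(path).name)
    logger.info("%s: parsed %d readout rows", Path(path).name, len(readouts))
    return readouts


def write_electrophoresis(readouts: Iterable[ChainReadout], path: str | Path) -> None:
    """Canonical writer for electrophoresis readouts (round-trips with the parser)."""
    df = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "plate_barcode": r.plate_barcode,
                "well": r.well.label,
                "chain": r.chain,
                "band_size_bp": _fmt_number(r.band_size_bp),
            }
            for r in readouts
        ],
        columns=ELECTROPHORESIS_COLUMNS,
    )
    df.to_csv(path, index=False)


def select_by_band_size(
    readouts: Sequence[ChainReadout],
    min_bp: float,
    max_bp: float | None = None,
) -> tuple[list[ChainReadout], list[ChainReadout]]:
    """Partition readouts by an amplicon-size window.

    A sample passes when ``min_bp <= band_size_bp`` (and ``<= max_bp`` when a
    maximum is set).  Returns ``(passed, failed)`` with statuses updated;
    the two lists always partition the input.
    """
    if min_bp < 0 or (max_bp is not None and max_bp < 0):
        raise InputValidationError("band-size thresholds must be >= 0 bp")
    if max_bp is not None and min_bp > max_bp:
        raise InputValidationError(f"min_bp ({min_bp}) exceeds max_bp ({max_bp})")
    passed, failed = [], []
    for r in readouts:
        ok = r.band_size_bp >= min_bp and (max_bp is None or r.band_size_bp <= max_bp)
        (passed if ok else failed).append(replace(r, status="passed" if ok else "failed"))
    logger.info(
        "band-size filter [%s, %s] bp: %d passed, %d failed of %d",
        min_bp, "inf" if max_bp is None else max_bp, len(passed), len(failed), len(readouts),
    )
    if readouts and not passed:
        logger.warning("no samples passed the band-size filter")
    return passed, failed


def concentration_adjustment(
    reading: ConcentrationReading,
    final_volume_ul: float,
    target_ng_ul: float | None = None,
) -> DilutionPlan:
    """Dilution volumes bringing a stock to its target concentration.

    Solves C1*V1 = C2*V2: stock volume = target x final / measured, diluent
    makes up the remainder.  A stock already below target cannot be
    concentrated by dilution, so it is flagged ``below_target`` and used
    neat; a stock volume exceeding what is available sets
    ``insufficient_volume``.
    """
    target = reading.target_ng_ul if target_ng_ul is None else target_ng_ul
    if reading.concentration_ng_ul <= 0:
        raise InputValidationError("measured concentration must be > 0 ng/uL")
    if final_volume_ul <= 0:
        raise InputValidationError("final volume must be > 0 uL")
    if reading.concentration_ng_ul < target:
        return DilutionPlan(
            stock_volume_ul=final_volume_ul,
            diluent_volume_ul=0.0,
            below_target=True,
            insufficient_volume=(
                reading.volume_available_ul > 0
                and final_volume_ul > reading.volume_available_ul
            ),
        )
    stock = min(target * final_volume_ul / reading.concentration_ng_ul, final_volume_ul)
    return DilutionPlan(
        stock_volume_ul=stock,
        diluent_volume_ul=max(final_volume_ul - stock, 0.0),
        insufficient_volume=(
            reading.volume_available_ul > 0 and stock > reading.volume_available_ul
        ),
    )


def parse_quantification(
    path: str | Path,
    expected_header: Sequence[str] = QUANTIFICATION_COLUMNS,
    delimiter: str = ",",
) -> list[ConcentrationReading]:
    """Load a concentration/quantification export (harvested antibodies or plasmids)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False, sep=delimiter)
    _check_header(df, expected_header, path)
    readings: list[ConcentrationReading] = []
    row_errors: list[str] = []
    for i, row in df.iterrows():
        line = i + 2
        try:
            conc = float(row["concentration_ng_ul"])
            if conc < 0:
                raise ValueError(f"negative concentration {conc}")
            readings.append(
                ConcentrationReading(
                    sample_id=row["sample_id"],
                    concentration_ng_ul=conc,
                    plate_barcode=row["plate_barcode"],
                    well=WellAddress.parse(row["well"]) if row["well"] else None,
                )
            )
        except (ValueError, InputValidationError) as exc:
            row_errors.append(f"line {line}: {exc}")
    if row_errors:
        raise RowValidationError(
            f"{Path(path).name}: {len(row_errors)} unparseable rows", row_errors=row_errors
        )
    logger.info("%s: parsed %d concentration rows", Path(path).name, len(readings))
    return readings


def write_quantification(readings: Iterable[ConcentrationReading], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "plate_barcode": r.plate_barcode,
                "well": r.well.label if r.well else "",
                "concentration_ng_ul": _fmt_number(r.concentration_ng_ul),
            }
            for r in readings
        ],
        columns=QUANTIFICATION_COLUMNS,
    )
    df.to_csv(path, index=False)


def _fmt_number(x: float) -> str:
    # integers print without a trailing .0 so files are stable and tidy
    return str(int(x)) if float(x).is_integer() else repr(float(x))
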
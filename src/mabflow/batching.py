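"""Store lists and batch formation.

Samples that pass a quality step accumulate faster or slower than full
plates; a *store list* is the ordered queue of samples waiting for the next
wet-lab step.  Batches are formed oldest-first (the samples that have waited
longest are processed first), the number of full batches is computed
automatically from the queue length, and the leftover is persisted as a new
timestamped store-list file.  Transfer worklists translate a batch into
source-to-destination pipetting rows for a liquid handler.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd

from .errors import DuplicateSampleError, HeaderValidationError, InputValidationError
from .plates import (
    PlateFormat,
    ScanOrder,
    WellAddress,
    index_to_well_label,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StoreEntry",
    "StoreList",
    "Batch",
    "WorklistRow",
    "form_batches",
    "enqueue",
    "persist_store_list",
    "load_store_list",
    "build_transfer_worklist",
    "write_worklist",
]

STORE_LIST_COLUMNS = ["sample_id", "plate_barcode", "well", "enqueued_at"]

DEFAULT_BATCH_SIZE = 96


@dataclass(frozen=True)
class StoreEntry:
    sample_id: str
    plate_barcode: str
    well: WellAddress
    enqueued_at: datetime


@dataclass(frozen=True)
class StoreList:
    """An ordered (oldest-first) queue of pending samples for one workflow step."""

    step: str
    entries: tuple[StoreEntry, ...] = ()

    def __post_init__(self):
        ids = [e.sample_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DuplicateSampleError(f"duplicate sample IDs in store list: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class Batch:
    """Up to ``batch_size`` samples destined for one plate."""

    samples: tuple[StoreEntry, ...]
    dest_barcode: str = ""


@dataclass(frozen=True)
class WorklistRow:
    source_barcode: str
    source_well: str
    dest_barcode: str
    dest_well: str
    volume_ul: float


def form_batches(
    store: StoreList, batch_size: int = DEFAULT_BATCH_SIZE
) -> tuple[list[Batch], StoreList]:
    """Split a store list into full batches plus the leftover queue.

    The number of batches is ``len(store) // batch_size``, filled
    oldest-first; the leftover store list preserves the remaining entries in
    order, so ``n_batches * batch_size + len(leftover) == len(store)``.
    """
    if not isinstance(batch_size, int) or isinstance(batch_size, bool) or batch_size < 1:
        raise InputValidationError(f"batch size must be a positive integer, got {batch_size!r}")
    n_full = len(store) // batch_size
    batches = [
        Batch(samples=store.entries[i * batch_size:(i + 1) * batch_size])
        for i in range(n_full)
    ]
    leftover = StoreList(step=store.step, entries=store.entries[n_full * batch_size:])
    logger.info(
        "%s: %d samples -> %d full batches of %d, %d leftover",
        store.step, len(store), n_full, batch_size, len(leftover),
    )
    return batches, leftover


def enqueue(
    store: StoreList,
    new_samples: Sequence,
    clock: Callable[[], datetime] | None = None,
) -> StoreList:
    """Append newly advanced samples behind every existing entry.

    ``new_samples`` may be StoreEntry-like objects or (sample_id, barcode,
    well) tuples; fresh enqueue timestamps are assigned (injectable clock).
    Duplicate sample IDs against the queue raise an error naming the sample.
    """
    now = clock or (lambda: datetime.now(timezone.utc))
    existing = {e.sample_id for e in store.entries}
    added: list[StoreEntry] = []
    for s in new_samples:
        if isinstance(s, StoreEntry):
            sid, barcode, well = s.sample_id, s.plate_barcode, s.well
        elif isinstance(s, tuple):
            sid, barcode, well = s
        else:
            sid, barcode, well = s.sample_id, s.plate_barcode, s.well
        if sid in existing:
            raise DuplicateSampleError(f"sample {sid!r} is already on the {store.step} store list")
        existing.add(sid)
        added.append(
            StoreEntry(
                sample_id=sid,
                plate_barcode=barcode,
                well=well if isinstance(well, WellAddress) else WellAddress.parse(well),
                enqueued_at=now(),
            )
        )
    return StoreList(step=store.step, entries=(*store.entries, *added))


def persist_store_list(
    store: StoreList,
    directory: str | Path,
    clock: Callable[[], datetime] | None = None,
) -> Path:
    """Save a store list as ``<step>_<timestamp>.csv``; never overwrites.

    Two persists within the same second get distinct counter-suffixed names.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    now = (clock or (lambda: datetime.now(timezone.utc)))()
    stamp = now.strftime("%Y%m%dT%H%M%S")
    path = directory / f"{store.step}_{stamp}.csv"
    counter = 1
    while path.exists():
        path = directory / f"{store.step}_{stamp}_{counter}.csv"
        counter += 1
    df = pd.DataFrame(
        [
            {
                "sample_id": e.sample_id,
                "plate_barcode": e.plate_barcode,
                "well": e.well.label,
                "enqueued_at": e.enqueued_at.isoformat(),
            }
            for e in store.entries
        ],
        columns=STORE_LIST_COLUMNS,
    )
    df.to_csv(path, index=False)
    logger.info("%s: saved %d leftover samples to %s", store.step, len(store), path)
    return path


def load_store_list(path: str | Path, step: str | None = None) -> StoreList:
    """Load a persisted store list, validating header and entry order."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != STORE_LIST_COLUMNS:
        missing = [c for c in STORE_LIST_COLUMNS if c not in df.columns]
        extra = [c for c in df.columns if c not in STORE_LIST_COLUMNS]
        raise HeaderValidationError(
            f"{path.name}: store-list header mismatch — missing {missing}, unexpected {extra}",
            missing=missing,
            extra=extra,
        )
    if step is None:
        # filename convention <step>_<YYYYMMDDTHHMMSS>[_<counter>].csv
        tokens = path.stem.split("_")
        while tokens and tokens[-1].isdigit():
            tokens.pop()
        if tokens and re.fullmatch(r"\d{8}T\d{6}", tokens[-1]):
            tokens.pop()
        step = "_".join(tokens) or path.stem
    entries = tuple(
        StoreEntry(
            sample_id=row["sample_id"],
            plate_barcode=row["plate_barcode"],
            well=WellAddress.parse(row["well"]),
            enqueued_at=datetime.fromisoformat(row["enqueued_at"]),
        )
        for _, row in df.iterrows()
    )
    return StoreList(step=step, entries=entries)


def build_transfer_worklist(
    batch: Batch,
    dest_barcode: str,
    plate_format: PlateFormat | None = None,
    order: ScanOrder = ScanOrder.ROW_MAJOR,
    volume_ul: float = 10.0,
    source_format: PlateFormat | None = None,
) -> list[WorklistRow]:
    """Plate-to-plate pipetting rows for one batch.

    Destination wells are assigned in the configured scan order; a full
    batch covers the destination plate exactly.  Source addresses are
    validated against ``source_format`` (defaults to the destination format).
    """
    fmt = plate_format or PlateFormat.plate_96()
    src_fmt = source_format or fmt
    if len(batch.samples) > fmt.n_wells:
        raise InputValidationError(
            f"batch of {len(batch.samples)} does not fit a {fmt} destination plate"
        )
    rows = []
    for i, entry in enumerate(batch.samples):
        entry.well.check_on(src_fmt)
        rows.append(
            WorklistRow(
                source_barcode=entry.plate_barcode,
                source_well=entry.well.label,
                dest_barcode=dest_barcode,
                dest_well=index_to_well_label(i, fmt, order),
                volume_ul=volume_ul,
            )
        )
    return rows


def write_worklist(rows: Iterable[WorklistRow], path: str | Path) -> None:
    pd.DataFrame(
        [r.__dict__ for r in rows], columns=list(WorklistRow.__dataclass_fields__)
    ).to_csv(path, index=False)
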
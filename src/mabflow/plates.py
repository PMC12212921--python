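"""Coordinate algebra for microplate layouts.

Laboratory instruments address the same physical plate in different ways:
row-wise or column-wise scan orders, 96- or 384-well formats, and stamped
quadrants when four 96-well plates are condensed onto one 384-well plate.
This module is the single source of truth for converting between well labels
("A1" ... "P24"), 0-based linear indices, and 96-to-384 quadrant positions,
plus sequential plate-barcode assignment.

Conventions
-----------
* Internal row/column indices are 0-based; printed labels use the universal
  letter-row + 1-based-column style ("A1").
* Row-major ("A1, A2, ...") is the default scan order.
* Quadrant stamping defaults to the interleaved convention used by
  plate-stamping liquid handlers: 96-well (r, c) in quadrant q maps to
  384-well (2r + q//2, 2c + q%2).  A block convention (four contiguous
  8x12 rectangles) is available for instruments that tile instead.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum

from .errors import AddressingError, InputValidationError

__all__ = [
    "PlateFormat",
    "ScanOrder",
    "WellAddress",
    "well_label_to_index",
    "index_to_well_label",
    "quadrant_map_96_to_384",
    "format_barcode",
    "next_barcodes",
]

_ROW_LETTERS = "ABCDEFGHIJKLMNOP"
_LABEL_RE = re.compile(r"^([A-P])([0-9]{1,2})$")


class ScanOrder(str, Enum):
    """Traversal order of a plate: along rows or down columns."""

    ROW_MAJOR = "row-major"
    COLUMN_MAJOR = "column-major"


@dataclass(frozen=True)
class PlateFormat:
    """Rectangular plate geometry.

    The two standard formats are 96-well (8x12) and 384-well (16x24); build
    them with :meth:`plate_96` / :meth:`plate_384`.  Other rectangles (e.g.
    a 1xN strip standing in for a tube rack) go through :meth:`custom`.
    """

    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise InputValidationError(
                f"plate format needs at least one row and one column, "
                f"got {self.n_rows}x{self.n_cols}"
            )
        if self.n_rows > len(_ROW_LETTERS):
            raise InputValidationError(
                f"at most {len(_ROW_LETTERS)} rows supported (A-P), got {self.n_rows}"
            )

    @property
    def n_wells(self) -> int:
        return self.n_rows * self.n_cols

    @classmethod
    def plate_96(cls) -> "PlateFormat":
        return cls(8, 12)

    @classmethod
    def plate_384(cls) -> "PlateFormat":
        return cls(16, 24)

    @classmethod
    def custom(cls, n_rows: int, n_cols: int) -> "PlateFormat":
        return cls(n_rows, n_cols)

    def __str__(self) -> str:  # "96-well" / "384-well" / "3x5"
        if (self.n_rows, self.n_cols) in ((8, 12), (16, 24)):
            return f"{self.n_wells}-well"
        return f"{self.n_rows}x{self.n_cols}"


@dataclass(frozen=True, order=True)
class WellAddress:
    """A well position: 0-based row and column."""

    row: int
    col: int

    @property
    def label(self) -> str:
        return f"{_ROW_LETTERS[self.row]}{self.col + 1}"

    @classmethod
    def parse(cls, label: str) -> "WellAddress":
        m = _LABEL_RE.match(label.strip().upper() if isinstance(label, str) else "")
        if not m:
            raise AddressingError(f"malformed well label {label!r} (expected e.g. 'A1')")
        row = _ROW_LETTERS.index(m.group(1))
        col = int(m.group(2)) - 1
        if col < 0:
            raise AddressingError(f"column must be >= 1 in well label {label!r}")
        return cls(row, col)

    def check_on(self, fmt: PlateFormat) -> "WellAddress":
        """Validate this address against a plate format; returns self."""
        if self.row >= fmt.n_rows or self.col >= fmt.n_cols:
            raise AddressingError(
                f"well {self.label!r} does not exist on a {fmt} plate"
            )
        return self

    def __str__(self) -> str:
        return self.label


def well_label_to_index(
    label: str | WellAddress,
    fmt: PlateFormat,
    order: ScanOrder = ScanOrder.ROW_MAJOR,
) -> int:
    """Convert a well label to its 0-based linear index under a scan order.

    For a fixed (format, order) this is a bijection onto 0 .. n_wells-1.
    """
    well = label if isinstance(label, WellAddress) else WellAddress.parse(label)
    well.check_on(fmt)
    if order == ScanOrder.ROW_MAJOR:
        return well.row * fmt.n_cols + well.col
    return well.col * fmt.n_rows + well.row


def index_to_well_label(
    index: int,
    fmt: PlateFormat,
    order: ScanOrder = ScanOrder.ROW_MAJOR,
) -> str:
    """Inverse of :func:`well_label_to_index`."""
    if not isinstance(index, int) or isinstance(index, bool):
        raise AddressingError(f"linear index must be an integer, got {index!r}")
    if not 0 <= index < fmt.n_wells:
        raise AddressingError(
            f"linear index {index} out of range for a {fmt} plate (0..{fmt.n_wells - 1})"
        )
    if order == ScanOrder.ROW_MAJOR:
        row, col = divmod(index, fmt.n_cols)
    else:
        col, row = divmod(index, fmt.n_rows)
    return WellAddress(row, col).label


def quadrant_map_96_to_384(
    quadrant: int,
    well: str | WellAddress,
    convention: str = "interleaved",
) -> WellAddress:
    """Map a 96-well position into one quadrant of a 384-well plate.

    ``interleaved`` (default): quadrant q places 96-well (r, c) at
    384-well (2r + q//2, 2c + q%2), the every-other-well pattern produced
    by a four-stamp liquid-handler head.  ``block`` tiles the four 96-well
    plates as contiguous 8x12 rectangles instead.  Either way the four
    quadrants together cover the 384 plate exactly once.
    """
    if quadrant not in (0, 1, 2, 3):
        raise AddressingError(f"quadrant must be 0-3, got {quadrant!r}")
    w = well if isinstance(well, WellAddress) else WellAddress.parse(well)
    w.check_on(PlateFormat.plate_96())
    if convention == "interleaved":
        return WellAddress(2 * w.row + quadrant // 2, 2 * w.col + quadrant % 2)
    if convention == "block":
        return WellAddress(w.row + 8 * (quadrant // 2), w.col + 12 * (quadrant % 2))
    raise InputValidationError(
        f"unknown quadrant convention {convention!r} (interleaved or block)"
    )


def format_barcode(prefix: str, number: int, width: int = 3) -> str:
    """Render a plate barcode as prefix + zero-padded number."""
    if not isinstance(number, int) or isinstance(number, bool) or number < 0:
        raise InputValidationError(
            f"barcode number must be a non-negative integer, got {number!r}"
        )
    return f"{prefix}{number:0{width}d}"


def next_barcodes(prefix: str, last_number: int, n_new: int, width: int = 3) -> list[str]:
    """Assign the next ``n_new`` consecutive barcodes after ``last_number``.

    The caller supplies the latest plate number already used on a workflow
    step (typically from the command line); new plates continue the sequence,
    so barcodes are strictly increasing and collision-free within a step.
    """
    if not isinstance(last_number, int) or isinstance(last_number, bool) or last_number < 0:
        raise InputValidationError(
            f"--last-barcode must be a non-negative integer (the highest plate "
            f"number already used), got {last_number!r}"
        )
    if not isinstance(n_new, int) or isinstance(n_new, bool) or n_new < 0:
        raise InputValidationError(f"number of new barcodes must be >= 0, got {n_new!r}")
    return [format_barcode(prefix, last_number + i, width) for i in range(1, n_new + 1)]


def iter_wells(fmt: PlateFormat, order: ScanOrder = ScanOrder.ROW_MAJOR):
    """Yield every WellAddress of a plate in scan order."""
    for i in range(fmt.n_wells):
        yield WellAddress.parse(index_to_well_label(i, fmt, order))
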
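"""Core domain model for BAC-library quality control.

A BAC (bacterial artificial chromosome) library stores ~100-250 kb genomic
inserts in 384-well plates (rows A-P, columns 1-24).  Each clone ideally
yields two Sanger end-reads, one from the SP6 vector primer and one from T7.
When both end-reads of an intact clone are mapped to a reference genome they
land on the same chromosome, on opposite strands, facing inward ("tail-to-
tail"), with an implied span consistent with the insert size.  Any other
geometry is discordant and indicates rearrangement, chimerism or clone
identity confusion.

This module holds the clone-address / mapping / read types, the clone-name
parser, 384-well plate geometry, and the paired-end concordance classifier
that every downstream analysis shares.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional

PLATE_ROWS = "ABCDEFGHIJKLMNOP"  # 16 rows
PLATE_COLUMNS = 24
WELLS_PER_PLATE = len(PLATE_ROWS) * PLATE_COLUMNS  # 384

SP6 = "SP6"
T7 = "T7"
PRIMERS = (SP6, T7)


class CloneNameError(ValueError):
    """Raised for a clone name that does not parse or leaves the plate grid."""


class PlateGeometryError(ValueError):
    """Raised for well coordinates outside the 16 x 24 grid."""


@dataclass(frozen=True, order=True, slots=True)
class CloneAddress:
    """Plate/well address of a clone, e.g. CH243-341E5 = plate 341, row E, col 5."""

    library_prefix: str
    plate: int
    row: str
    column: int

    def __post_init__(self) -> None:
        if self.plate < 1:
            raise PlateGeometryError(f"plate must be >= 1, got {self.plate}")
        if self.row not in PLATE_ROWS:
            raise PlateGeometryError(
                f"row {self.row!r} outside {PLATE_ROWS[0]}-{PLATE_ROWS[-1]}"
            )
        if not 1 <= self.column <= PLATE_COLUMNS:
            raise PlateGeometryError(
                f"column {self.column} outside 1-{PLATE_COLUMNS}"
            )

    @property
    def row_index(self) -> int:
        """0-based row index (A = 0 ... P = 15)."""
        return PLATE_ROWS.index(self.row)

    @property
    def well(self) -> tuple[str, int]:
        return (self.row, self.column)

    @property
    def name(self) -> str:
        return f"{self.library_prefix}-{self.plate}{self.row}{self.column}"

    def __str__(self) -> str:
        return self.name


_CLONE_NAME_RE = re.compile(
    r"^(?P<prefix>[A-Za-z][A-Za-z0-9]*)-(?P<plate>\d+)(?P<row>[A-Za-z])(?P<column>\d+)$"
)


def parse_clone_name(name: str) -> CloneAddress:
    """Parse a clone name like ``"CH243-341E5"`` into a :class:`CloneAddress`.

    Raises :class:`CloneNameError` on malformed names and
    :class:`PlateGeometryError` when the well leaves the A-P x 1-24 grid.
    ``format`` of the result reproduces the input canonically.
    """
    m = _CLONE_NAME_RE.match(name.strip())
    if m is None:
        raise CloneNameError(f"unparseable clone name: {name!r}")
    row = m.group("row").upper()
    try:
        return CloneAddress(
            library_prefix=m.group("prefix"),
            plate=int(m.group("plate")),
            row=row,
            column=int(m.group("column")),
        )
    except PlateGeometryError as exc:
        raise PlateGeometryError(f"{name!r}: {exc}") from exc


def format_clone_name(address: CloneAddress) -> str:
    """Canonical clone name; inverse of :func:`parse_clone_name`."""
    return address.name


@dataclass(frozen=True, slots=True)
class GenomeInterval:
    """A mapped location: 0-based half-open [start, end) on a strand."""

    chromosome: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chromosome}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def intersection_length(self, other: "GenomeInterval") -> int:
        if self.chromosome != other.chromosome:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True, slots=True)
class BesRecord:
    """One BAC-end sequence read: its clone, primer and (optional) mapping."""

    clone: CloneAddress
    primer: str
    mapping: Optional[GenomeInterval] = None
    read_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.primer not in PRIMERS:
            raise ValueError(f"primer must be SP6 or T7, got {self.primer!r}")

    @property
    def mapped(self) -> bool:
        return self.mapping is not None


class ConcordanceClass(Enum):
    """Geometry class of a clone's two end-read mappings."""

    TAIL_TO_TAIL = "tail_to_tail"
    TAIL_TO_TAIL_OUTSIZE = "tail_to_tail_outsize"
    TAIL_TO_HEAD = "tail_to_head"
    HEAD_TO_HEAD = "head_to_head"
    DIFFERENT_CHROMOSOME = "different_chromosome"
    ONE_END_ONLY = "one_end_only"
    NO_END_POSITIONED = "no_end_positioned"


@dataclass(frozen=True, slots=True)
class InsertSizeBounds:
    """Acceptable implied-span window for a concordant (tail-to-tail) clone.

    CHORI-style BAC inserts run ~150-250 kb; the default window is generous
    on both sides so only clearly aberrant spans are called outsize.
    """

    min_bp: int = 50_000
    max_bp: int = 350_000

    def __post_init__(self) -> None:
        if not 0 < self.min_bp < self.max_bp:
            raise ValueError(
                f"need 0 < min_bp < max_bp, got [{self.min_bp}, {self.max_bp}]"
            )


DEFAULT_INSERT_BOUNDS = InsertSizeBounds()


@dataclass(frozen=True, slots=True)
class BacPair:
    """A clone's two end-reads joined, with concordance class once classified."""

    clone: CloneAddress
    sp6: Optional[BesRecord] = None
    t7: Optional[BesRecord] = None
    cls: Optional[ConcordanceClass] = None
    implied_span: Optional[GenomeInterval] = None


def classify_mappings(
    a: Optional[GenomeInterval],
    b: Optional[GenomeInterval],
    bounds: InsertSizeBounds = DEFAULT_INSERT_BOUNDS,
) -> ConcordanceClass:
    """Classify the geometry of two (possibly absent) end-read mappings.

    Orientation is decided from strand and coordinate order: the two reads
    face inward (tail-to-tail) when the leftmost-mapped read is on '+' and
    the rightmost on '-'; both on one strand is tail-to-head; the reverse
    arrangement is head-to-head.  A tail-to-tail pair whose implied span
    falls outside ``bounds`` is tail-to-tail outsize.  Degenerate geometry
    (non-positive span) is classified outsize rather than raising.
    """
    if a is None and b is None:
        return ConcordanceClass.NO_END_POSITIONED
    if a is None or b is None:
        return ConcordanceClass.ONE_END_ONLY
    if a.chromosome != b.chromosome:
        return ConcordanceClass.DIFFERENT_CHROMOSOME
    left, right = sorted((a, b), key=lambda iv: (iv.start, iv.end))
    if left.strand == right.strand:
        return ConcordanceClass.TAIL_TO_HEAD
    if left.strand == "-":
        return ConcordanceClass.HEAD_TO_HEAD
    span = right.end - left.start
    if span <= 0 or not bounds.min_bp <= span <= bounds.max_bp:
        return ConcordanceClass.TAIL_TO_TAIL_OUTSIZE
    return ConcordanceClass.TAIL_TO_TAIL


def classify_pair(
    sp6: Optional[BesRecord],
    t7: Optional[BesRecord],
    bounds: InsertSizeBounds = DEFAULT_INSERT_BOUNDS,
) -> ConcordanceClass:
    """Classify a clone from its SP6 and T7 records (either may be absent)."""
    return classify_mappings(
        sp6.mapping if sp6 is not None else None,
        t7.mapping if t7 is not None else None,
        bounds,
    )


def implied_span(
    sp6: Optional[BesRecord], t7: Optional[BesRecord]
) -> Optional[GenomeInterval]:
    """Outermost coordinates of the two mappings when both lie on one chromosome."""
    a = sp6.mapping if sp6 is not None else None
    b = t7.mapping if t7 is not None else None
    if a is None or b is None or a.chromosome != b.chromosome:
        return None
    return GenomeInterval(
        chromosome=a.chromosome,
        start=min(a.start, b.start),
        end=max(a.end, b.end),
        strand="+",
    )


def classify(pair: BacPair, bounds: InsertSizeBounds = DEFAULT_INSERT_BOUNDS) -> BacPair:
    """Return a copy of *pair* with ``cls`` and ``implied_span`` filled in."""
    return replace(
        pair,
        cls=classify_pair(pair.sp6, pair.t7, bounds),
        implied_span=implied_span(pair.sp6, pair.t7),
    )


def classify_pairs(
    pairs: Iterable[BacPair], bounds: InsertSizeBounds = DEFAULT_INSERT_BOUNDS
) -> list[BacPair]:
    return [classify(p, bounds) for p in pairs]


SAME_WELL = "same_well"
SAME_ROW = "same_row"
SAME_COLUMN = "same_column"
NEITHER = "neither"


@dataclass(frozen=True, slots=True)
class WellDistance:
    """Relation of two wells on one plate.

    ``gap`` is the number of intervening wells: adjacent wells on the same
    row or column have gap 0, one well between them gives gap 1, and so on.
    Diagonal relations are ``neither`` and carry no gap.
    """

    axis: str  # same_well | same_row | same_column | neither
    gap: Optional[int] = None


def well_distance(a: CloneAddress, b: CloneAddress) -> WellDistance:
    """Row/column relation of two clones on the same plate (Fig.-3-style strata)."""
    if a.plate != b.plate:
        raise PlateGeometryError(
            f"well_distance requires one plate, got {a.plate} and {b.plate}"
        )
    if a.well == b.well:
        return WellDistance(SAME_WELL, None)
    if a.row == b.row:
        return WellDistance(SAME_ROW, abs(a.column - b.column) - 1)
    if a.column == b.column:
        return WellDistance(SAME_COLUMN, abs(a.row_index - b.row_index) - 1)
    return WellDistance(NEITHER, None)
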
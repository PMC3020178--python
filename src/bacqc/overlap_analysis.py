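"""Clone-overlap redundancy and well-adjacency analysis.

Genome assembly treats each BAC as an independent linkage between the loci
its two ends touch, so non-independent (duplicated) clones inflate
confidence.  Two signatures expose them:

* the distribution of percent overlap between tail-to-tail clones' implied
  spans — re-picked identical clones on the *same* plate peak at 100%
  overlap, while overlaps between *different* plates peak lower;
* pairs of clones on the same plate with overlapping end-read mappings that
  sit 0, 1 or 2 wells apart on the same row or column — the footprint of
  localised cross-contamination during plate handling.

Overlapping span pairs are found by a sweep over start-sorted intervals per
chromosome, never an all-pairs scan.  Percent overlap is normalised by the
shorter span, so a duplicate whose end-reads differ slightly in length
still scores (essentially) 100%.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    BacPair,
    BesRecord,
    CloneAddress,
    SAME_COLUMN,
    SAME_ROW,
    WellDistance,
    well_distance,
)

ADJACENCY_AXES = (SAME_ROW, SAME_COLUMN)
ADJACENCY_GAPS = (0, 1, 2)


@dataclass(frozen=True, slots=True)
class OverlapPair:
    """One unordered pair of clones with intersecting implied spans."""

    clone_a: CloneAddress  # canonical order: lower (plate, row, column) first
    clone_b: CloneAddress
    percent_overlap: float  # 100 * intersection / min(span lengths)
    same_plate: bool
    adjacency: Optional[WellDistance] = None  # set when same_plate


def _canonical(a: CloneAddress, b: CloneAddress) -> tuple[CloneAddress, CloneAddress]:
    ka = (a.plate, a.row_index, a.column)
    kb = (b.plate, b.row_index, b.column)
    return (a, b) if ka <= kb else (b, a)


def bac_overlap_pairs(tt_pairs: Iterable[BacPair]) -> list[OverlapPair]:
    """All clone pairs whose implied spans intersect, via a per-chromosome sweep.

    Input pairs must carry ``implied_span`` (i.e. be tail-to-tail clones, or
    at least same-chromosome both-end clones).  Each unordered pair appears
    exactly once, in canonical clone order.
    """
    by_chrom: dict[str, list[tuple[int, int, CloneAddress]]] = defaultdict(list)
    for p in tt_pairs:
        if p.implied_span is None:
            raise ValueError(f"pair {p.clone.name} has no implied span")
        s = p.implied_span
        by_chrom[s.chromosome].append((s.start, s.end, p.clone))

    out: list[OverlapPair] = []
    for chrom in sorted(by_chrom):
        spans = sorted(by_chrom[chrom], key=lambda t: (t[0], t[1], t[2]))
        active: list[tuple[int, int, CloneAddress]] = []
        for start, end, clone in spans:
            active = [a for a in active if a[1] > start]
            for a_start, a_end, a_clone in active:
                inter = min(end, a_end) - start  # start >= a_start in sweep order
                if inter <= 0:
                    continue
                pct = 100.0 * inter / min(end - start, a_end - a_start)
                ca, cb = _canonical(a_clone, clone)
                same_plate = ca.plate == cb.plate
                out.append(
                    OverlapPair(
                        clone_a=ca,
                        clone_b=cb,
                        percent_overlap=pct,
                        same_plate=same_plate,
                        adjacency=well_distance(ca, cb) if same_plate else None,
                    )
                )
            active.append((start, end, clone))
    return out


@dataclass(frozen=True, slots=True)
class Histogram:
    """Right-closed percent-overlap histogram over (0, 100]."""

    bin_width: float
    counts: tuple[int, ...]

    @property
    def bins(self) -> list[tuple[float, float]]:
        return [
            (i * self.bin_width, (i + 1) * self.bin_width)
            for i in range(len(self.counts))
        ]

    @property
    def modal_bin(self) -> Optional[tuple[float, float]]:
        """Highest-count bin; ties resolve to the higher bin; None when empty."""
        if not self.counts or sum(self.counts) == 0:
            return None
        best = max(range(len(self.counts)), key=lambda i: (self.counts[i], i))
        return self.bins[best]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"bin_low": lo, "bin_high": hi, "count": c}
                for (lo, hi), c in zip(self.bins, self.counts)
            ],
            columns=["bin_low", "bin_high", "count"],
        )


def overlap_histogram(
    overlaps: Iterable[OverlapPair],
    same_plate: bool,
    bin_width: float = 2.0,
) -> Histogram:
    """Histogram of percent overlaps restricted to same- or different-plate pairs.

    Bins are right-closed and cover (0, 100]; *bin_width* must divide 100.
    """
    n_bins = 100.0 / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(f"bin_width {bin_width} does not divide 100")
    n_bins = int(round(n_bins))
    pct = np.array(
        [o.percent_overlap for o in overlaps if o.same_plate == same_plate], dtype=float
    )
    if pct.size == 0:
        return Histogram(bin_width=bin_width, counts=(0,) * n_bins)
    idx = np.clip(np.ceil(pct / bin_width).astype(int) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return Histogram(bin_width=bin_width, counts=tuple(int(c) for c in counts))


@dataclass(frozen=True, slots=True)
class AdjacencyCount:
    """Count of BES-overlapping clone pairs in one (plate, axis, gap) stratum."""

    plate: int
    axis: str  # same_row | same_column
    gap: int  # 0, 1 or 2 intervening wells
    count: int


def _intersecting_same_plate_clone_pairs(
    records: Iterable[BesRecord],
) -> set[tuple[CloneAddress, CloneAddress]]:
    """Unordered same-plate clone pairs with >= 1 bp BES-interval intersection."""
    by_chrom: dict[str, list[tuple[int, int, CloneAddress]]] = defaultdict(list)
    for r in records:
        if r.mapping is None:
            continue
        m = r.mapping
        by_chrom[m.chromosome].append((m.start, m.end, r.clone))
    found: set[tuple[CloneAddress, CloneAddress]] = set()
    for chrom, items in by_chrom.items():
        items.sort(key=lambda t: (t[0], t[1], t[2]))
        active: list[tuple[int, int, CloneAddress]] = []
        for start, end, clone in items:
            active = [a for a in active if a[1] > start]
            for _, _, other in active:
                if other.plate == clone.plate and other != clone:
                    found.add(_canonical(other, clone))
            active.append((start, end, clone))
    return found


def bes_adjacency_counts(records: Iterable[BesRecord]) -> list[AdjacencyCount]:
    """Count same-plate clone pairs with overlapping BES mappings 0-2 wells apart.

    A pair counts once per stratum (it has a single well relation) when its
    wells share a row or column with at most 2 intervening wells; diagonal or
    farther pairs contribute nothing.  Returned sorted by (plate, axis, gap),
    zero strata omitted.
    """
    tally: dict[tuple[int, str, int], int] = defaultdict(int)
    for a, b in _intersecting_same_plate_clone_pairs(records):
        wd = well_distance(a, b)
        if wd.axis in ADJACENCY_AXES and wd.gap in ADJACENCY_GAPS:
            tally[(a.plate, wd.axis, wd.gap)] += 1
    return [
        AdjacencyCount(plate=p, axis=ax, gap=g, count=c)
        for (p, ax, g), c in sorted(tally.items())
    ]


def same_plate_overlapping_clone_pairs(records: Iterable[BesRecord]) -> dict[int, int]:
    """Per plate, the number of clone pairs with any BES-mapping intersection.

    On a contaminated plate (many reads piled into one tiny region) this
    count can exceed the number of clones on the plate — the hallmark of a
    hotspot rather than genuine clone redundancy.
    """
    counts: dict[int, int] = defaultdict(int)
    for a, _ in _intersecting_same_plate_clone_pairs(records):
        counts[a.plate] += 1
    return dict(sorted(counts.items()))


def overlaps_to_frame(overlaps: Sequence[OverlapPair]) -> pd.DataFrame:
    rows = [
        {
            "clone_a": o.clone_a.name,
            "clone_b": o.clone_b.name,
            "percent_overlap": o.percent_overlap,
            "same_plate": o.same_plate,
            "adjacency_axis": o.adjacency.axis if o.adjacency else "",
            "adjacency_gap": o.adjacency.gap if o.adjacency and o.adjacency.gap is not None else "",
        }
        for o in overlaps
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "clone_a", "clone_b", "percent_overlap", "same_plate",
            "adjacency_axis", "adjacency_gap",
        ],
    )


def adjacency_to_frame(counts: Sequence[AdjacencyCount]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"plate": c.plate, "axis": c.axis, "gap": c.gap, "count": c.count} for c in counts],
        columns=["plate", "axis", "gap", "count"],
    )
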
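"""Detection and resolution of SP6/T7 plate swaps.

A plate swap is a handling error in which one primer's sequencing reactions
for a whole plate (or part of one) are attributed to another plate: plate
A's SP6 reads actually came from plate B's clones in the same wells, and
vice versa.  The signature is a pair of plates with almost no tail-to-tail
clones whose concordance is restored by exchanging the suspect primer's
mappings well-for-well (E5 <-> E5) between the two plates.

``test_plate_swap`` evaluates that what-if for one (plate, plate, primer)
triple, including a per-well diagnosis for partial swaps; ``scan_swap_
candidates`` ranks all candidate pairs by the tail-to-tail count gained.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .core import (
    BacPair,
    BesRecord,
    ConcordanceClass,
    DEFAULT_INSERT_BOUNDS,
    InsertSizeBounds,
    PLATE_ROWS,
    PRIMERS,
    SP6,
    classify_mappings,
)

TT = ConcordanceClass.TAIL_TO_TAIL

ORIGINAL = "original"
SWAPPED = "swapped"
NEITHER_ASSIGNMENT = "neither"


class PlateLookupError(KeyError):
    """Raised when a requested plate has no pairs."""


def pairs_by_plate(pairs: Iterable[BacPair]) -> dict[int, dict[tuple[str, int], BacPair]]:
    """Index classified pairs as plate -> well -> pair."""
    out: dict[int, dict[tuple[str, int], BacPair]] = {}
    for p in pairs:
        out.setdefault(p.clone.plate, {})[p.clone.well] = p
    return out


@dataclass(frozen=True, slots=True)
class WellAssignment:
    well: tuple[str, int]
    assignment: str  # original | swapped | neither
    cls_a_orig: ConcordanceClass
    cls_b_orig: ConcordanceClass
    cls_a_swapped: ConcordanceClass
    cls_b_swapped: ConcordanceClass


@dataclass(frozen=True, slots=True)
class SwapTestResult:
    plate_a: int
    plate_b: int
    primer: str
    tt_a_orig: int
    tt_b_orig: int
    tt_a_swapped: int
    tt_b_swapped: int
    per_well: tuple[WellAssignment, ...]

    @property
    def gain(self) -> int:
        return (self.tt_a_swapped + self.tt_b_swapped) - (self.tt_a_orig + self.tt_b_orig)

    @property
    def n_swapped_wells(self) -> int:
        return sum(1 for w in self.per_well if w.assignment == SWAPPED)

    @property
    def n_original_wells(self) -> int:
        return sum(1 for w in self.per_well if w.assignment == ORIGINAL)

    @property
    def n_evaluated_wells(self) -> int:
        return len(self.per_well)


def _mappings(pair: Optional[BacPair]):
    sp6 = pair.sp6.mapping if pair is not None and pair.sp6 is not None else None
    t7 = pair.t7.mapping if pair is not None and pair.t7 is not None else None
    return sp6, t7


def test_plate_swap(
    by_plate: Mapping[int, Mapping[tuple[str, int], BacPair]],
    plate_a: int,
    plate_b: int,
    primer: str,
    bounds: InsertSizeBounds = DEFAULT_INSERT_BOUNDS,
) -> SwapTestResult:
    """What-if analysis of swapping *primer*'s mappings between two plates.

    For every well address present on both plates the pair is classified
    as-is and with the primer's mappings exchanged; the input is never
    modified.  Each well is assigned ``swapped`` when the exchanged
    configuration yields strictly more tail-to-tail clones than the
    original, ``original`` when the original configuration wins or ties
    with at least one tail-to-tail, and ``neither`` when no configuration
    produces one (such wells carry no evidence either way).
    """
    for plate in (plate_a, plate_b):
        if plate not in by_plate:
            raise PlateLookupError(f"plate {plate} not present in the dataset")
    wells_a, wells_b = by_plate[plate_a], by_plate[plate_b]
    shared = sorted(
        set(wells_a) & set(wells_b), key=lambda w: (PLATE_ROWS.index(w[0]), w[1])
    )
    tt_a_orig = tt_b_orig = tt_a_sw = tt_b_sw = 0
    per_well = []
    for well in shared:
        pa, pb = wells_a[well], wells_b[well]
        a_sp6, a_t7 = _mappings(pa)
        b_sp6, b_t7 = _mappings(pb)
        cls_a = classify_mappings(a_sp6, a_t7, bounds)
        cls_b = classify_mappings(b_sp6, b_t7, bounds)
        if primer == SP6:
            cls_a_sw = classify_mappings(b_sp6, a_t7, bounds)
            cls_b_sw = classify_mappings(a_sp6, b_t7, bounds)
        else:
            cls_a_sw = classify_mappings(a_sp6, b_t7, bounds)
            cls_b_sw = classify_mappings(b_sp6, a_t7, bounds)
        tt_a_orig += cls_a is TT
        tt_b_orig += cls_b is TT
        tt_a_sw += cls_a_sw is TT
        tt_b_sw += cls_b_sw is TT
        orig_tt = (cls_a is TT) + (cls_b is TT)
        sw_tt = (cls_a_sw is TT) + (cls_b_sw is TT)
        if sw_tt > orig_tt:
            assignment = SWAPPED
        elif orig_tt > 0:
            assignment = ORIGINAL
        else:
            assignment = NEITHER_ASSIGNMENT
        per_well.append(
            WellAssignment(well, assignment, cls_a, cls_b, cls_a_sw, cls_b_sw)
        )
    return SwapTestResult(
        plate_a=plate_a,
        plate_b=plate_b,
        primer=primer,
        tt_a_orig=tt_a_orig,
        tt_b_orig=tt_b_orig,
        tt_a_swapped=tt_a_sw,
        tt_b_swapped=tt_b_sw,
        per_well=tuple(per_well),
    )


DEFAULT_MIN_GAIN = 10  # tail-to-tail clones gained; suppresses coincidental gains


def scan_swap_candidates(
    by_plate: Mapping[int, Mapping[tuple[str, int], BacPair]],
    candidate_plates: Sequence[int],
    bounds: InsertSizeBounds = DEFAULT_INSERT_BOUNDS,
    min_gain: int = DEFAULT_MIN_GAIN,
) -> list[SwapTestResult]:
    """Test every unordered candidate-plate pair x primer; rank by gain.

    Candidates are typically the deficit-flagged plates from the per-plate
    statistics.  Results with gain >= *min_gain* are returned sorted by
    gain descending (ties: plate_a, plate_b, primer).
    """
    results = []
    for a, b in combinations(sorted(set(candidate_plates)), 2):
        for primer in PRIMERS:
            r = test_plate_swap(by_plate, a, b, primer, bounds)
            if r.gain >= min_gain:
                results.append(r)
    results.sort(key=lambda r: (-r.gain, r.plate_a, r.plate_b, r.primer))
    return results


def apply_plate_swap(
    records: Iterable[BesRecord], plate_a: int, plate_b: int, primer: str
) -> list[BesRecord]:
    """Return records with *primer*'s mappings exchanged between the two plates.

    Every well address carrying the primer's record on both plates is
    exchanged (the full "straight swap"); other records are untouched.
    """
    records = list(records)
    pos: dict[tuple[int, tuple[str, int]], int] = {}
    for i, r in enumerate(records):
        if r.primer == primer and r.clone.plate in (plate_a, plate_b):
            pos[(r.clone.plate, r.clone.well)] = i
    out = records[:]
    for (plate, well), ia in pos.items():
        if plate != plate_a:
            continue
        ib = pos.get((plate_b, well))
        if ib is None:
            continue
        ra, rb = records[ia], records[ib]
        out[ia] = replace(ra, mapping=rb.mapping)
        out[ib] = replace(rb, mapping=ra.mapping)
    return out


def results_to_frame(results: Sequence[SwapTestResult]) -> pd.DataFrame:
    cols = [
        "plate_a", "plate_b", "primer", "gain", "tt_a_orig", "tt_b_orig",
        "tt_a_swapped", "tt_b_swapped", "n_swapped_wells", "n_original_wells",
        "n_evaluated_wells",
    ]
    return pd.DataFrame(
        [{c: getattr(r, c) for c in cols} for r in results], columns=cols
    )


def per_well_frame(result: SwapTestResult) -> pd.DataFrame:
    rows = [
        {
            "row": w.well[0],
            "column": w.well[1],
            "assignment": w.assignment,
            "cls_a_orig": w.cls_a_orig.value,
            "cls_b_orig": w.cls_b_orig.value,
            "cls_a_swapped": w.cls_a_swapped.value,
            "cls_b_swapped": w.cls_b_swapped.value,
        }
        for w in result.per_well
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "row", "column", "assignment", "cls_a_orig", "cls_b_orig",
            "cls_a_swapped", "cls_b_swapped",
        ],
    )
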
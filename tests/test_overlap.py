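"""Overlap sweep vs brute force, histograms, and well-adjacency counts."""

from __future__ import annotations

from itertools import combinations

import pytest
from hypothesis import given, strategies as st

from bacqc.core import (
    BacPair,
    BesRecord,
    CloneAddress,
    GenomeInterval,
    classify_pairs,
)
from bacqc.io_formats import pair_records
from bacqc.overlap_analysis import (
    bac_overlap_pairs,
    bes_adjacency_counts,
    overlap_histogram,
    same_plate_overlapping_clone_pairs,
)
from bacqc.synthetic import (
    AdjacentDuplicate,
    Contamination,
    CrossPlateDuplicate,
    SimulationConfig,
    simulate_library,
)
from conftest import SPARSE_GENOME


def _span_pair(plate, row, col, start, end):
    clone = CloneAddress("CH243", plate, row, col)
    return BacPair(
        clone=clone,
        implied_span=GenomeInterval("chr1", start, end, "+"),
    )


class TestOverlapPairs:
    def test_identical_spans_give_100_percent(self):
        pairs = [_span_pair(1, "A", 1, 0, 100_000), _span_pair(2, "A", 1, 0, 100_000)]
        (o,) = bac_overlap_pairs(pairs)
        assert o.percent_overlap == 100.0
        assert not o.same_plate

    def test_half_overlap_arithmetic(self):
        pairs = [_span_pair(1, "A", 1, 0, 100_000), _span_pair(1, "B", 1, 50_000, 150_000)]
        (o,) = bac_overlap_pairs(pairs)
        assert o.percent_overlap == 50.0
        assert o.same_plate
        assert o.adjacency.axis == "same_column"

    def test_touching_spans_do_not_overlap(self):
        pairs = [_span_pair(1, "A", 1, 0, 100_000), _span_pair(1, "A", 2, 100_000, 200_000)]
        assert bac_overlap_pairs(pairs) == []

    def test_missing_span_rejected(self):
        with pytest.raises(ValueError):
            bac_overlap_pairs([BacPair(clone=CloneAddress("CH243", 1, "A", 1))])

    def test_sweep_matches_brute_force_on_simulated_clones(self):
        cfg = SimulationConfig(seed=19, n_plates=1, p_end_unmapped=0.0, p_discordant=0.0)
        records, _ = simulate_library(cfg)
        pairs = classify_pairs(pair_records(records))[:200]
        swept = {
            (o.clone_a.name, o.clone_b.name): o.percent_overlap
            for o in bac_overlap_pairs(pairs)
        }
        brute = {}
        for pa, pb in combinations(pairs, 2):
            a, b = pa.implied_span, pb.implied_span
            inter = a.intersection_length(b)
            if inter > 0:
                ca, cb = sorted([pa.clone, pb.clone])
                brute[(ca.name, cb.name)] = 100.0 * inter / min(a.length, b.length)
        assert swept == brute

    def test_each_pair_appears_once_in_canonical_order(self, clean_fully_mapped):
        _, records, _ = clean_fully_mapped
        pairs = classify_pairs(pair_records(records))
        overlaps = bac_overlap_pairs(pairs)
        keys = [(o.clone_a.name, o.clone_b.name) for o in overlaps]
        assert len(keys) == len(set(keys))
        for o in overlaps:
            assert (o.clone_a.plate, o.clone_a.row_index, o.clone_a.column) <= (
                o.clone_b.plate, o.clone_b.row_index, o.clone_b.column,
            )


@given(shift=st.integers(min_value=0, max_value=10_000_000))
def test_overlap_invariant_under_coordinate_shift(shift):
    base = [
        _span_pair(1, "A", 1, 0, 100_000),
        _span_pair(1, "B", 2, 40_000, 150_000),
        _span_pair(2, "C", 3, 90_000, 260_000),
    ]
    shifted = [
        BacPair(
            clone=p.clone,
            implied_span=GenomeInterval(
                "chr1", p.implied_span.start + shift, p.implied_span.end + shift, "+"
            ),
        )
        for p in base
    ]
    pct0 = sorted(o.percent_overlap for o in bac_overlap_pairs(base))
    pct1 = sorted(o.percent_overlap for o in bac_overlap_pairs(shifted))
    assert pct0 == pct1


class TestHistogram:
    def test_single_pair_lands_in_one_bin(self):
        pairs = [_span_pair(1, "A", 1, 0, 100_000), _span_pair(1, "B", 1, 50_000, 150_000)]
        hist = overlap_histogram(bac_overlap_pairs(pairs), same_plate=True)
        assert sum(hist.counts) == 1
        assert hist.modal_bin == (48.0, 50.0)  # right-closed: 50% -> (48, 50]

    def test_empty_input_has_no_modal_bin(self):
        hist = overlap_histogram([], same_plate=True)
        assert sum(hist.counts) == 0
        assert hist.modal_bin is None

    def test_bin_width_must_divide_100(self):
        with pytest.raises(ValueError):
            overlap_histogram([], same_plate=True, bin_width=3.0)

    def test_duplicate_injections_reproduce_plate_contrast(self):
        cfg = SimulationConfig(
            seed=31, n_plates=4, genome=SPARSE_GENOME,
            defects=[
                AdjacentDuplicate(plate=1, n_pairs=20, gap=0, axis="same_row"),
                AdjacentDuplicate(plate=2, n_pairs=15, gap=1, axis="same_column"),
                # mid-bin redundancy target: a peak exactly on a bin edge
                # would split between the two neighbouring bins
                CrossPlateDuplicate(n_pairs=120, overlap_fraction=0.87),
            ],
        )
        records, _ = simulate_library(cfg)
        pairs = classify_pairs(pair_records(records))
        overlaps = bac_overlap_pairs([p for p in pairs if p.implied_span is not None])
        same = overlap_histogram(overlaps, same_plate=True)
        diff = overlap_histogram(overlaps, same_plate=False)
        assert same.modal_bin == (98.0, 100.0)  # re-picked clones: ~100% overlap
        assert diff.modal_bin == (86.0, 88.0)  # redundancy peak well below 100%


class TestAdjacency:
    def test_injected_strata_counted_exactly(self):
        cfg = SimulationConfig(
            seed=41, n_plates=6, genome=SPARSE_GENOME,
            defects=[
                AdjacentDuplicate(plate=1, n_pairs=5, gap=1, axis="same_row"),
                AdjacentDuplicate(plate=2, n_pairs=4, gap=0, axis="same_column"),
                AdjacentDuplicate(plate=3, n_pairs=3, gap=2, axis="same_row"),
            ],
        )
        records, _ = simulate_library(cfg)
        counts = {(c.plate, c.axis, c.gap): c.count for c in bes_adjacency_counts(records)}
        assert counts == {
            (1, "same_row", 1): 5,
            (2, "same_column", 0): 4,
            (3, "same_row", 2): 3,
        }

    def test_clean_sparse_library_counts_nothing(self, clean_sparse_library):
        _, records, _ = clean_sparse_library
        assert bes_adjacency_counts(records) == []

    def test_far_apart_wells_do_not_count(self):
        iv = GenomeInterval("chr1", 0, 600, "+")
        records = [
            BesRecord(CloneAddress("CH243", 1, "E", 1), "SP6", iv),
            BesRecord(CloneAddress("CH243", 1, "E", 5), "SP6", iv),  # gap 3
        ]
        assert bes_adjacency_counts(records) == []

    def test_contaminated_plate_pair_count_exceeds_clone_count(self):
        cfg = SimulationConfig(
            seed=43, n_plates=3, genome=SPARSE_GENOME,
            defects=[Contamination(3, "SP6", 59, 33, "chr2", 5_000_000)],
        )
        records, _ = simulate_library(cfg)
        per_plate = same_plate_overlapping_clone_pairs(records)
        assert per_plate[3] >= 59 * 58 // 2  # 1711 pairs from 59 piled reads
        assert per_plate[3] > 384  # exceeds the clone count of the plate
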
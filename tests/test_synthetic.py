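"""Simulator correctness: geometry, determinism, defect injection and labels."""

from __future__ import annotations

import math
from collections import Counter

import pytest

from bacqc.core import ConcordanceClass, classify_pairs
from bacqc.io_formats import pair_records
from bacqc.synthetic import (
    AdjacentDuplicate,
    Contamination,
    CrossPlateDuplicate,
    DefectError,
    PrimerSwap,
    SimulationConfig,
    SimulationConfigError,
    TruthLabels,
    inject_defects,
    simulate_library,
)
from conftest import SPARSE_GENOME

CC = ConcordanceClass


def test_defect_free_fully_mapped_library_is_all_tail_to_tail(clean_fully_mapped):
    _, records, labels = clean_fully_mapped
    assert len(records) == 2 * 768  # 2 plates x 384 wells x 2 ends
    pairs = classify_pairs(pair_records(records))
    assert len(pairs) == 768
    assert all(p.cls is CC.TAIL_TO_TAIL for p in pairs)
    assert labels.read_tags == {}


def test_same_seed_reproduces_identical_records(clean_fully_mapped):
    cfg, records, _ = clean_fully_mapped
    again, _ = simulate_library(cfg)
    assert again == records


def test_unmapped_end_rate_matches_binomial_expectation():
    p = 0.1
    cfg = SimulationConfig(seed=13, n_plates=4, p_end_unmapped=p, p_discordant=0.0)
    records, _ = simulate_library(cfg)
    n = len(records)
    observed = sum(1 for r in records if r.mapping is None) / n
    se = math.sqrt(p * (1 - p) / n)
    assert abs(observed - p) <= 3 * se


def test_discordant_fraction_produces_non_tt_classes():
    cfg = SimulationConfig(seed=17, n_plates=4, p_end_unmapped=0.0, p_discordant=0.2)
    records, _ = simulate_library(cfg)
    counts = Counter(p.cls for p in classify_pairs(pair_records(records)))
    n = 4 * 384
    assert counts[CC.TAIL_TO_TAIL] < n
    discordant = n - counts[CC.TAIL_TO_TAIL]
    se = math.sqrt(0.2 * 0.8 / n)
    assert abs(discordant / n - 0.2) <= 3 * se
    # every discordant flavour should appear at this sample size
    for cls in (CC.TAIL_TO_HEAD, CC.HEAD_TO_HEAD, CC.DIFFERENT_CHROMOSOME,
                CC.TAIL_TO_TAIL_OUTSIZE):
        assert counts[cls] > 0


def test_genome_too_small_for_inserts_rejected():
    with pytest.raises(SimulationConfigError):
        SimulationConfig(genome=(("chr1", 100_000),))


class TestInjection:
    def test_empty_defect_list_is_identity(self, clean_fully_mapped):
        _, records, _ = clean_fully_mapped
        out, labels = inject_defects(list(records), TruthLabels(), [], seed=1)
        assert out == list(records)
        assert labels.read_tags == {}

    def test_record_count_conserved_under_every_defect_kind(self):
        cfg = SimulationConfig(
            seed=23, n_plates=4, genome=SPARSE_GENOME,
            defects=[
                PrimerSwap(1, 2, "SP6", 0.5),
                Contamination(3, "T7", 20, 33, "chr1", 1_000_000),
                AdjacentDuplicate(4, 5, 1, "same_row"),
                CrossPlateDuplicate(5, 0.9),
            ],
        )
        records, labels = simulate_library(cfg)
        assert len(records) == 4 * 384 * 2
        assert set(labels.plate_defects) == {1, 2, 3, 4}

    def test_full_swap_destroys_concordance_on_both_plates(self):
        cfg = SimulationConfig(
            seed=29, n_plates=3, p_end_unmapped=0.0, p_discordant=0.0,
            defects=[PrimerSwap(1, 2, "SP6", 1.0)],
        )
        records, labels = simulate_library(cfg)
        pairs = classify_pairs(pair_records(records))
        swapped = [p for p in pairs if p.clone.plate in (1, 2)]
        untouched = [p for p in pairs if p.clone.plate == 3]
        # a swapped-in SP6 read lands at a random other locus: tail-to-tail
        # only by coincidence.  P(coincidence) ~= window/(genome) * 1/2 for
        # the strand: the read must fall in the ~300 kb span window on the
        # correct side of the clone's T7 read with the correct orientation.
        bounds = cfg.insert_bounds
        genome_bp = sum(l for _, l in cfg.genome)
        p_coinc = (bounds.max_bp - bounds.min_bp) / genome_bp * 0.5
        expected = len(swapped) * p_coinc
        n_tt_swapped = sum(p.cls is CC.TAIL_TO_TAIL for p in swapped)
        assert n_tt_swapped <= expected + 4 * math.sqrt(expected) + 1
        assert all(p.cls is CC.TAIL_TO_TAIL for p in untouched)
        assert len(labels.swapped_wells[(1, 2, "SP6")]) == 384

    def test_contamination_labels_exactly_n_reads_in_region(self):
        d = Contamination(plate=3, primer="SP6", n_reads=59, region_span=33,
                          chromosome="chr2", region_start=5_000_000)
        cfg = SimulationConfig(seed=31, n_plates=3, genome=SPARSE_GENOME, defects=[d])
        records, labels = simulate_library(cfg)
        tagged = [r for r in records if labels.read_tags.get(r.read_id) == "contamination"]
        assert len(tagged) == 59
        for r in tagged:
            assert r.clone.plate == 3 and r.primer == "SP6"
            assert r.mapping.chromosome == "chr2"
            assert r.mapping.start >= 5_000_000
            assert r.mapping.end <= 5_000_033
        assert len({r.clone for r in tagged}) == 59

    def test_adjacent_duplicate_geometry_and_links(self):
        d = AdjacentDuplicate(plate=2, n_pairs=6, gap=2, axis="same_column")
        cfg = SimulationConfig(seed=37, n_plates=2, genome=SPARSE_GENOME, defects=[d])
        records, labels = simulate_library(cfg)
        assert len(labels.duplicate_links) == 6
        by_name = {}
        for r in records:
            by_name.setdefault(r.clone.name, {})[r.primer] = r
        from bacqc.core import parse_clone_name, well_distance

        for src_name, tgt_name in labels.duplicate_links:
            src, tgt = parse_clone_name(src_name), parse_clone_name(tgt_name)
            wd = well_distance(src, tgt)
            assert (wd.axis, wd.gap) == ("same_column", 2)
            for primer in ("SP6", "T7"):
                sm = by_name[src_name][primer].mapping
                tm = by_name[tgt_name][primer].mapping
                assert tm is not None and tm.chromosome == sm.chromosome
                assert abs(tm.start - sm.start) <= 1000  # jitter bound
                assert tm.length == sm.length

    def test_cross_plate_duplicate_hits_target_overlap(self):
        d = CrossPlateDuplicate(n_pairs=10, overlap_fraction=0.88)
        cfg = SimulationConfig(seed=41, n_plates=3, genome=SPARSE_GENOME, defects=[d])
        records, labels = simulate_library(cfg)
        spans = {}
        for r in records:
            if r.mapping is None:
                continue
            s = spans.setdefault(r.clone.name, [None, None])
            s[0] = min(x for x in (s[0], r.mapping.start) if x is not None)
            s[1] = max(x for x in (s[1], r.mapping.end) if x is not None)
        for src_name, tgt_name in labels.duplicate_links:
            (s1, e1), (s2, e2) = spans[src_name], spans[tgt_name]
            inter = min(e1, e2) - max(s1, s2)
            pct = inter / min(e1 - s1, e2 - s2)
            assert pct == pytest.approx(0.88, abs=0.005)

    def test_unsatisfiable_defect_raises(self):
        with pytest.raises(DefectError):
            simulate_library(
                SimulationConfig(
                    seed=43, n_plates=2,
                    defects=[Contamination(1, "SP6", 999, 33, "chr1", 0)],
                )
            )
        with pytest.raises(DefectError):
            simulate_library(
                SimulationConfig(seed=43, n_plates=1, defects=[CrossPlateDuplicate(1, 0.9)])
            )
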
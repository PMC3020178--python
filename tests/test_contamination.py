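"""Hotspot clustering and the k-mer contaminant/chimera screen."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from bacqc.core import BesRecord, CloneAddress, GenomeInterval
from bacqc.contamination import (
    detect_hotspots,
    screen_contaminant,
    summarize_contamination,
)
from bacqc.synthetic import Contamination, SimulationConfig, simulate_library
from conftest import SPARSE_GENOME


@pytest.fixture(scope="module")
def contaminated_library():
    cfg = SimulationConfig(
        seed=21, n_plates=5, genome=SPARSE_GENOME,
        defects=[Contamination(plate=3, primer="SP6", n_reads=59, region_span=33,
                               chromosome="chr2", region_start=5_000_000)],
    )
    return simulate_library(cfg)


class TestHotspots:
    def test_injected_pileup_recovered_exactly(self, contaminated_library):
        records, labels = contaminated_library
        clusters = detect_hotspots(records, max_span=500, min_clones=5)
        assert len(clusters) == 1
        c = clusters[0]
        assert c.n_members == 59
        assert c.n_distinct_clones == 59
        assert c.region.length == 33
        assert c.dominant_plate == 3 and c.dominant_plate_fraction == 1.0
        assert c.dominant_primer == "SP6" and c.dominant_primer_fraction == 1.0
        truth = {r for r, t in labels.read_tags.items() if t == "contamination"}
        assert set(c.member_read_ids) == truth  # recall and precision both 1.0

    def test_clean_library_has_no_clusters(self, clean_sparse_library):
        _, records, _ = clean_sparse_library
        assert detect_hotspots(records, max_span=500, min_clones=5) == []

    def test_small_pileups_below_min_clones_ignored(self):
        records = [
            BesRecord(CloneAddress("CH243", 1, "A", i), "SP6",
                      GenomeInterval("chr1", 1000, 1600, "+"))
            for i in (1, 2)
        ]
        assert detect_hotspots(records, max_span=500, min_clones=5) == []

    def test_result_invariant_to_input_order(self, contaminated_library):
        records, _ = contaminated_library
        rng = np.random.default_rng(0)
        shuffled = [records[i] for i in rng.permutation(len(records))]
        assert detect_hotspots(records) == detect_hotspots(shuffled)

    def test_parameter_validation(self, contaminated_library):
        records, _ = contaminated_library
        with pytest.raises(ValueError):
            detect_hotspots(records, max_span=0)
        with pytest.raises(ValueError):
            detect_hotspots(records, min_clones=1)


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="module")
def reference_fixture():
    rng = np.random.default_rng(1234)
    ref = _random_seq(rng, 1500)
    return rng, ref


class TestScreen:
    def test_verbatim_reference_substring_is_contaminant(self, reference_fixture):
        _, ref = reference_fixture
        reads = [SeqRecord(Seq(ref[200:800]), id="read1")]
        (hit,) = screen_contaminant(reads, [SeqRecord(Seq(ref), id="ref")])
        assert hit.kmer_fraction == 1.0
        assert hit.verdict == "contaminant"

    def test_reverse_complement_also_detected(self, reference_fixture):
        _, ref = reference_fixture
        rc = str(Seq(ref[200:800]).reverse_complement())
        (hit,) = screen_contaminant(
            [SeqRecord(Seq(rc), id="rc")], [SeqRecord(Seq(ref), id="ref")]
        )
        assert hit.kmer_fraction == 1.0

    def test_half_contaminant_read_gives_exact_chimera_fraction(self, reference_fixture):
        rng, ref = reference_fixture
        k = 21
        read = _random_seq(rng, 300) + ref[100:400]  # 300 random + 300 reference
        (hit,) = screen_contaminant(
            [SeqRecord(Seq(read), id="chimera1")], [SeqRecord(Seq(ref), id="ref")], k=k
        )
        # reference-derived k-mers fully inside the reference half over all k-mers
        assert hit.kmer_fraction == (300 - k + 1) / (600 - k + 1)
        assert hit.verdict == "chimera"

    def test_random_read_is_clean(self, reference_fixture):
        rng, ref = reference_fixture
        read = _random_seq(rng, 600)
        (hit,) = screen_contaminant(
            [SeqRecord(Seq(read), id="rand")], [SeqRecord(Seq(ref), id="ref")]
        )
        assert hit.kmer_fraction < 0.05
        assert hit.verdict == "clean"

    def test_short_read_clean_with_warning(self, reference_fixture, caplog):
        _, ref = reference_fixture
        with caplog.at_level("WARNING"):
            (hit,) = screen_contaminant(
                [SeqRecord(Seq("ACGTACGT"), id="tiny")], [SeqRecord(Seq(ref), id="ref")]
            )
        assert hit.verdict == "clean"
        assert "shorter than k" in caplog.text

    def test_fasta_path_input(self, tmp_path, reference_fixture):
        _, ref = reference_fixture
        reads_fa = tmp_path / "reads.fasta"
        ref_fa = tmp_path / "ref.fasta"
        reads_fa.write_text(f">r1\n{ref[0:600]}\n")
        ref_fa.write_text(f">ref\n{ref}\n")
        (hit,) = screen_contaminant(reads_fa, ref_fa)
        assert hit.verdict == "contaminant"

    def test_parameter_validation(self, reference_fixture):
        _, ref = reference_fixture
        reads = [SeqRecord(Seq(ref[:100]), id="r")]
        refs = [SeqRecord(Seq(ref), id="ref")]
        with pytest.raises(ValueError):
            screen_contaminant(reads, refs, k=7)
        with pytest.raises(ValueError):
            screen_contaminant(reads, refs, low=0.9, high=0.2)
        with pytest.raises(ValueError):
            screen_contaminant([], refs)


def test_per_plate_summary_joins_hotspots_and_screen(contaminated_library):
    records, labels = contaminated_library
    clusters = detect_hotspots(records)
    tagged = {r for r, t in labels.read_tags.items() if t == "contamination"}
    # fabricate screen verdicts consistent with the hotspot: contaminated reads
    # flagged as contaminant, five arbitrary clean reads as chimera
    from bacqc.contamination import ContaminantHit

    hits = [ContaminantHit(rid, 0.95, "contaminant") for rid in sorted(tagged)]
    clean_ids = [r.read_id for r in records if r.read_id not in tagged][:5]
    hits += [ContaminantHit(rid, 0.5, "chimera") for rid in clean_ids]
    frame = summarize_contamination(clusters, hits, records)
    assert list(frame["plate"]) == [1, 2, 3, 4, 5]
    row3 = frame[frame["plate"] == 3].iloc[0]
    assert row3["n_hotspot_reads"] == 59
    assert row3["n_contaminant_reads"] == 59
    assert row3["n_hotspot_and_screen"] == 59
    assert frame["n_chimera_reads"].sum() == 5
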
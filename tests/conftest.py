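"""Shared fixtures and the independent concordance oracle.

The oracle classifies a pair of end-read mappings by reasoning about each
read's 3' direction from its interval midpoint — deliberately a different
formulation from the package classifier's leftmost-strand rule — so the two
can be checked against each other over an exhaustive geometry grid.
"""

from __future__ import annotations

import pytest
from hypothesis import settings

from bacqc.core import (
    ConcordanceClass,
    DEFAULT_INSERT_BOUNDS,
    GenomeInterval,
    InsertSizeBounds,
)
from bacqc.synthetic import SimulationConfig, simulate_library

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=100)
settings.load_profile("suite")

# Mapping density comparable to a real large-insert library on a mammalian
# reference; the simulator's compute-scale default genome is far denser.
SPARSE_GENOME = (
    ("chr1", 200_000_000),
    ("chr2", 200_000_000),
    ("chr3", 200_000_000),
)


def oracle_classify(
    a: GenomeInterval | None,
    b: GenomeInterval | None,
    bounds: InsertSizeBounds = DEFAULT_INSERT_BOUNDS,
) -> ConcordanceClass:
    """Independent concordance classifier (midpoint direction-vector logic)."""
    if a is None and b is None:
        return ConcordanceClass.NO_END_POSITIONED
    if (a is None) != (b is None):
        return ConcordanceClass.ONE_END_ONLY
    if a.chromosome != b.chromosome:
        return ConcordanceClass.DIFFERENT_CHROMOSOME

    mid_a = (a.start + a.end) / 2
    mid_b = (b.start + b.end) / 2

    def points_toward(mid_self: float, strand: str, mid_other: float) -> bool:
        # a read's 3' direction runs right on '+', left on '-'
        return mid_other > mid_self if strand == "+" else mid_other < mid_self

    a_in = points_toward(mid_a, a.strand, mid_b)
    b_in = points_toward(mid_b, b.strand, mid_a)
    if a_in and b_in:  # facing inward: tail-to-tail geometry
        span = max(a.end, b.end) - min(a.start, b.start)
        if bounds.min_bp <= span <= bounds.max_bp:
            return ConcordanceClass.TAIL_TO_TAIL
        return ConcordanceClass.TAIL_TO_TAIL_OUTSIZE
    if not a_in and not b_in:
        return ConcordanceClass.HEAD_TO_HEAD
    return ConcordanceClass.TAIL_TO_HEAD


def enumeration_grid(bounds: InsertSizeBounds = DEFAULT_INSERT_BOUNDS):
    """All strand x order x span-class x chromosome cases with separated intervals.

    Yields (sp6_interval, t7_interval, description).  Also includes the
    missing-end cases.  Intervals are well separated (no overlap), the
    regime in which the midpoint and leftmost-strand formulations of
    "facing inward" provably agree.
    """
    read_len = 700
    spans = {
        "below": bounds.min_bp - 10_000,
        "inside": (bounds.min_bp + bounds.max_bp) // 2,
        "above": bounds.max_bp + 100_000,
    }
    cases = []
    for strand_first in "+-":
        for strand_second in "+-":
            for span_name, span in spans.items():
                for sp6_first in (True, False):
                    for same_chrom in (True, False):
                        left = GenomeInterval("chr1", 1_000, 1_000 + read_len, strand_first)
                        right_chrom = "chr1" if same_chrom else "chr2"
                        right = GenomeInterval(
                            right_chrom, 1_000 + span - read_len, 1_000 + span, strand_second
                        )
                        sp6, t7 = (left, right) if sp6_first else (right, left)
                        desc = (
                            f"{strand_first}{strand_second} span={span_name} "
                            f"sp6_first={sp6_first} same_chrom={same_chrom}"
                        )
                        cases.append((sp6, t7, desc))
    some = GenomeInterval("chr1", 1_000, 1_700, "+")
    cases.append((some, None, "t7 missing"))
    cases.append((None, some, "sp6 missing"))
    cases.append((None, None, "both missing"))
    return cases


@pytest.fixture(scope="session")
def clean_fully_mapped():
    """2 plates, every end mapped, no discordant clones: 768 tail-to-tail BACs."""
    cfg = SimulationConfig(seed=7, n_plates=2, p_end_unmapped=0.0, p_discordant=0.0)
    records, labels = simulate_library(cfg)
    return cfg, records, labels


@pytest.fixture(scope="session")
def clean_sparse_library():
    """4 plates on a sparse genome with default noise levels."""
    cfg = SimulationConfig(seed=3, n_plates=4, genome=SPARSE_GENOME)
    records, labels = simulate_library(cfg)
    return cfg, records, labels
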
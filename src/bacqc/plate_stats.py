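"""Per-plate integrity metrics and outlier-plate flagging.

For each plate the module counts how many end-reads were positioned on the
reference, how many clones have both ends sequenced / both ends positioned /
only one end positioned, and how many classify tail-to-tail, and derives the
four per-plate proportions used to judge library integrity:

* ``prop_positioned`` — positioned reads / all reads of the plate;
* ``prop_tt_of_positioned_bacs`` — tail-to-tail clones / clones positioned
  at all (both-ends-positioned + one-end-only; optionally all clones);
* ``prop_one_end`` — one-end-only clones / clones positioned at all;
* ``prop_tt_of_both_ends`` — tail-to-tail clones / clones with both ends
  sequenced.

If read identity is maintained these proportions are roughly constant across
plates, so a plate whose proportion deviates from the pooled library rate is
flagged by an exact two-sided binomial test (leave-one-plate-out pooled
rate) with Benjamini-Hochberg correction across plates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from statistics import median
from typing import Iterable, Optional, Sequence

import pandas as pd
from scipy import stats as sps

from .core import BacPair, BesRecord, ConcordanceClass

logger = logging.getLogger(__name__)

METRICS = (
    "prop_positioned",
    "prop_tt_of_positioned_bacs",
    "prop_one_end",
    "prop_tt_of_both_ends",
)


@dataclass(frozen=True, slots=True)
class PlateStats:
    plate: int
    n_bes_total: int
    n_bes_positioned: int
    n_clones: int
    n_both_ends_sequenced: int
    n_both_ends_positioned: int
    n_one_end_only: int
    n_tt: int
    alt_tt_denominator: bool = False  # use all clones as the TT denominator

    @property
    def n_positioned_bacs(self) -> int:
        """Clones positioned at all: both ends or exactly one end mapped."""
        return self.n_both_ends_positioned + self.n_one_end_only

    @property
    def prop_positioned(self) -> Optional[float]:
        return _ratio(self.n_bes_positioned, self.n_bes_total)

    @property
    def prop_tt_of_positioned_bacs(self) -> Optional[float]:
        den = self.n_clones if self.alt_tt_denominator else self.n_positioned_bacs
        return _ratio(self.n_tt, den)

    @property
    def prop_one_end(self) -> Optional[float]:
        return _ratio(self.n_one_end_only, self.n_positioned_bacs)

    @property
    def prop_tt_of_both_ends(self) -> Optional[float]:
        return _ratio(self.n_tt, self.n_both_ends_sequenced)

    def metric_fraction(self, metric: str) -> tuple[int, int]:
        """(numerator, denominator) of a named proportion."""
        if metric == "prop_positioned":
            return self.n_bes_positioned, self.n_bes_total
        if metric == "prop_tt_of_positioned_bacs":
            den = self.n_clones if self.alt_tt_denominator else self.n_positioned_bacs
            return self.n_tt, den
        if metric == "prop_one_end":
            return self.n_one_end_only, self.n_positioned_bacs
        if metric == "prop_tt_of_both_ends":
            return self.n_tt, self.n_both_ends_sequenced
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den else None


@dataclass(frozen=True, slots=True)
class PlateFlag:
    plate: int
    metric: str
    observed: float
    library_rate: float  # leave-one-plate-out median of plate proportions
    p_value: float
    adjusted_p: float
    direction: str  # deficit | excess
    numerator: int
    denominator: int


def compute_plate_stats(
    pairs: Iterable[BacPair],
    records: Iterable[BesRecord],
    alt_tt_denominator: bool = False,
) -> list[PlateStats]:
    """Per-plate counts and proportions from classified pairs plus raw records.

    One :class:`PlateStats` per plate present, sorted by plate number.
    Counts are conservative: summed over plates they equal the library-wide
    totals.  Proportions with a zero denominator are reported as absent
    (``None``), never as 0.
    """
    acc: dict[int, dict[str, int]] = {}

    def row(plate: int) -> dict[str, int]:
        return acc.setdefault(
            plate,
            dict(total=0, positioned=0, clones=0, both_seq=0, both_pos=0, one_end=0, tt=0),
        )

    for r in records:
        a = row(r.clone.plate)
        a["total"] += 1
        if r.mapping is not None:
            a["positioned"] += 1
    for p in pairs:
        if p.cls is None:
            raise ValueError(f"pair {p.clone.name} is unclassified; classify first")
        a = row(p.clone.plate)
        a["clones"] += 1
        if p.sp6 is not None and p.t7 is not None:
            a["both_seq"] += 1
            if p.sp6.mapped and p.t7.mapped:
                a["both_pos"] += 1
        if p.cls is ConcordanceClass.ONE_END_ONLY:
            a["one_end"] += 1
        elif p.cls is ConcordanceClass.TAIL_TO_TAIL:
            a["tt"] += 1
    return [
        PlateStats(
            plate=plate,
            n_bes_total=a["total"],
            n_bes_positioned=a["positioned"],
            n_clones=a["clones"],
            n_both_ends_sequenced=a["both_seq"],
            n_both_ends_positioned=a["both_pos"],
            n_one_end_only=a["one_end"],
            n_tt=a["tt"],
            alt_tt_denominator=alt_tt_denominator,
        )
        for plate, a in sorted(acc.items())
    ]


def flag_outlier_plates(
    stats: Sequence[PlateStats],
    metric: str = "prop_tt_of_both_ends",
    alpha: float = 0.05,
) -> list[PlateFlag]:
    """Flag plates whose *metric* deviates from the library-wide rate.

    Each plate's numerator is tested with an exact two-sided binomial test
    against a robust library rate: the leave-one-plate-out *median* of the
    other plates' proportions.  The median (rather than a count-weighted
    pooled mean) keeps one or two grossly defective plates — e.g. a swapped
    pair with zero tail-to-tail clones — from dragging the reference rate
    down and flagging every healthy plate as an excess.  P-values are
    Benjamini-Hochberg adjusted across plates and plates with adjusted
    p < *alpha* are returned, sorted by adjusted p.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")

    usable: list[tuple[PlateStats, int, int]] = []
    for s in stats:
        num, den = s.metric_fraction(metric)
        if den == 0:
            logger.warning("plate %d skipped: zero denominator for %s", s.plate, metric)
            continue
        usable.append((s, num, den))
    if len(usable) < 2:
        return []

    props = [num / den for _, num, den in usable]
    rows = []
    for i, (s, num, den) in enumerate(usable):
        others = props[:i] + props[i + 1 :]
        rate = float(median(others))
        p = sps.binomtest(num, den, rate, alternative="two-sided").pvalue
        rows.append((s, num, den, rate, p))
    adjusted = sps.false_discovery_control([r[4] for r in rows], method="bh")
    flags = [
        PlateFlag(
            plate=s.plate,
            metric=metric,
            observed=num / den,
            library_rate=rate,
            p_value=p,
            adjusted_p=float(q),
            direction="deficit" if num / den < rate else "excess",
            numerator=num,
            denominator=den,
        )
        for (s, num, den, rate, p), q in zip(rows, adjusted)
        if q < alpha
    ]
    flags.sort(key=lambda f: (f.adjusted_p, f.plate))
    return flags


def stats_to_frame(stats: Sequence[PlateStats]) -> pd.DataFrame:
    """Flat per-plate table (counts + proportions), one row per plate."""
    rows = []
    for s in stats:
        rows.append(
            {
                "plate": s.plate,
                "n_bes_total": s.n_bes_total,
                "n_bes_positioned": s.n_bes_positioned,
                "n_clones": s.n_clones,
                "n_both_ends_sequenced": s.n_both_ends_sequenced,
                "n_both_ends_positioned": s.n_both_ends_positioned,
                "n_one_end_only": s.n_one_end_only,
                "n_tt": s.n_tt,
                "prop_positioned": s.prop_positioned,
                "prop_tt_of_positioned_bacs": s.prop_tt_of_positioned_bacs,
                "prop_one_end": s.prop_one_end,
                "prop_tt_of_both_ends": s.prop_tt_of_both_ends,
            }
        )
    return pd.DataFrame(rows)


def flags_to_frame(flags: Sequence[PlateFlag]) -> pd.DataFrame:
    cols = [
        "plate", "metric", "observed", "library_rate", "p_value",
        "adjusted_p", "direction", "numerator", "denominator",
    ]
    return pd.DataFrame([{c: getattr(f, c) for c in cols} for f in flags], columns=cols)
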
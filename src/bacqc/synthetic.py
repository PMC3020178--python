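"""Synthetic BAC-library simulator with defect injection and truth labels.

The simulator emulates the data a BAC-end-sequencing project produces after
the alignment step: one mapped (or unmapped) interval per end-read, for every
well of every 384-well plate.  A clean clone gets an insert length drawn from
a truncated normal, a uniform random genomic placement, one end-read per
vector primer (SP6/T7, terminus assignment randomised per clone) facing
inward on opposite strands, and each end is independently unmapped with a
configurable probability.  A configurable fraction of clones is given a
random discordant geometry, emulating chimeric or rearranged clones.

On top of the clean library, :func:`inject_defects` reproduces the failure
modes documented for real libraries, each with exact truth labels so
detectors can be scored by recovery:

* ``primer_swap`` — one primer's reads exchanged well-for-well between two
  plates (fully or for a random fraction of wells), the plate-swap
  phenomenon;
* ``contamination`` — a batch of same-primer reads on one plate overwritten
  with mappings piled into one tiny genomic region, the 16S-style
  contamination hotspot signature;
* ``adjacent_duplicate`` — a clone's mappings copied (with <= 1 kb jitter)
  into a nearby well on the same row or column, modelling localised
  cross-contamination during plate handling;
* ``cross_plate_duplicate`` — a clone duplicated to a random well of another
  plate at a target span-overlap fraction, modelling re-picked clones.

Injection overwrites mappings in place (a contaminated well contains the
wrong DNA but its reads keep the well's name), so the record count is always
conserved.  Everything is driven by one seeded generator: the same seed and
config give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import yaml

from .core import (
    BacPair,
    BesRecord,
    CloneAddress,
    ConcordanceClass,
    DEFAULT_INSERT_BOUNDS,
    GenomeInterval,
    InsertSizeBounds,
    PLATE_COLUMNS,
    PLATE_ROWS,
    PRIMERS,
    SP6,
    T7,
)
from . import io_formats

DEFAULT_GENOME = (("chr1", 30_000_000), ("chr2", 30_000_000), ("chr3", 30_000_000))


class SimulationConfigError(ValueError):
    """Raised for an inconsistent simulation configuration."""


class DefectError(ValueError):
    """Raised when a defect spec cannot be applied (e.g. wells unavailable)."""


@dataclass(frozen=True, slots=True)
class PrimerSwap:
    """Exchange one primer's mappings well-for-well between two plates."""

    plate_a: int
    plate_b: int
    primer: str
    fraction: float = 1.0  # 1.0 = the "straight swap"

    kind = "primer_swap"


@dataclass(frozen=True, slots=True)
class Contamination:
    """Pile ``n_reads`` same-primer reads of one plate into one tiny region."""

    plate: int
    primer: str
    n_reads: int
    region_span: int
    chromosome: str
    region_start: int

    kind = "contamination"


@dataclass(frozen=True, slots=True)
class AdjacentDuplicate:
    """Copy clones into wells ``gap`` wells away on the same row or column."""

    plate: int
    n_pairs: int
    gap: int  # 0, 1 or 2 intervening wells
    axis: str  # same_row | same_column

    kind = "adjacent_duplicate"


@dataclass(frozen=True, slots=True)
class CrossPlateDuplicate:
    """Duplicate clones onto other plates at a target span-overlap fraction."""

    n_pairs: int
    overlap_fraction: float

    kind = "cross_plate_duplicate"


DefectSpec = Union[PrimerSwap, Contamination, AdjacentDuplicate, CrossPlateDuplicate]


@dataclass
class SimulationConfig:
    """Generative parameters of the synthetic library.

    Defaults emulate a CHORI-style large-insert library: ~184 kb mean insert
    (sd 30 kb), ~600 bp Sanger end-reads, a quarter of ends failing to map,
    and 5% of clones discordant.  The default toy genome (3 x 30 Mb) keeps
    small simulations dense enough to exercise the overlap machinery; pass a
    larger genome for realistic mapping density.
    """

    seed: int = 0
    n_plates: int = 2
    genome: Sequence[tuple[str, int]] = DEFAULT_GENOME
    insert_mean: int = 184_000
    insert_sd: int = 30_000
    read_length_mean: int = 600
    read_length_sd: int = 100
    p_end_unmapped: float = 0.25
    p_discordant: float = 0.05
    library_prefix: str = "CH243"
    insert_bounds: InsertSizeBounds = DEFAULT_INSERT_BOUNDS
    defects: list[DefectSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_plates < 1:
            raise SimulationConfigError("n_plates must be >= 1")
        for p in (self.p_end_unmapped, self.p_discordant):
            if not 0.0 <= p <= 1.0:
                raise SimulationConfigError(f"probability {p} outside [0, 1]")
        if not self.genome:
            raise SimulationConfigError("genome must list at least one chromosome")
        for name, length in self.genome:
            if length <= self.insert_bounds.max_bp:
                raise SimulationConfigError(
                    f"chromosome {name} ({length} bp) too small for inserts up to "
                    f"{self.insert_bounds.max_bp} bp"
                )


@dataclass
class TruthLabels:
    """Ground truth of every injected defect.

    ``read_tags`` maps read ids to their defect kind (clean reads are
    absent); ``plate_defects`` lists injected defect kinds per plate;
    ``duplicate_links`` records (source clone, copy clone) names;
    ``swapped_wells`` records, per (plate_a, plate_b, primer) swap, which
    well addresses were actually exchanged and which were eligible.
    """

    read_tags: dict[str, str] = field(default_factory=dict)
    plate_defects: dict[int, list[str]] = field(default_factory=dict)
    duplicate_links: list[tuple[str, str]] = field(default_factory=list)
    swapped_wells: dict[tuple[int, int, str], frozenset] = field(default_factory=dict)
    swap_eligible_wells: dict[tuple[int, int, str], frozenset] = field(default_factory=dict)

    def tag_plate(self, plate: int, kind: str) -> None:
        self.plate_defects.setdefault(plate, []).append(kind)


def _truncated_normal(rng, mean, sd, low, high, n) -> np.ndarray:
    """Normal draw truncated to [low, high] by rejection (exact, not clipped)."""
    out = rng.normal(mean, sd, n)
    bad = (out < low) | (out > high)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < low) | (out > high)
    return np.rint(out).astype(np.int64)


def _all_addresses(prefix: str, n_plates: int) -> list[CloneAddress]:
    return [
        CloneAddress(prefix, plate, row, col)
        for plate in range(1, n_plates + 1)
        for row in PLATE_ROWS
        for col in range(1, PLATE_COLUMNS + 1)
    ]


def simulate_library(config: SimulationConfig) -> tuple[list[BesRecord], TruthLabels]:
    """Simulate the library described by *config*, defects included.

    Returns the BES records (two per clone, SP6 then T7, plate/well order)
    and the truth labels of every injected defect.  Reproducible: identical
    configs give identical output.
    """
    rng = np.random.default_rng(config.seed)
    bounds = config.insert_bounds
    addresses = _all_addresses(config.library_prefix, config.n_plates)
    n = len(addresses)

    chrom_names = [c for c, _ in config.genome]
    chrom_lengths = np.array([l for _, l in config.genome], dtype=np.int64)
    chrom_p = chrom_lengths / chrom_lengths.sum()

    insert = _truncated_normal(
        rng, config.insert_mean, config.insert_sd, bounds.min_bp, bounds.max_bp, n
    )
    chrom_idx = rng.choice(len(chrom_names), size=n, p=chrom_p)
    start = np.floor(rng.random(n) * (chrom_lengths[chrom_idx] - insert)).astype(np.int64)
    read_len = np.empty((n, 2), dtype=np.int64)
    for side in (0, 1):
        rl = np.rint(rng.normal(config.read_length_mean, config.read_length_sd, n))
        read_len[:, side] = np.clip(rl, 50, insert // 2).astype(np.int64)
    sp6_on_left = rng.random(n) < 0.5
    unmapped = rng.random((n, 2)) < config.p_end_unmapped  # columns: SP6, T7
    discordant = rng.random(n) < config.p_discordant
    disc_kind = rng.integers(0, 4, size=n)  # consumed even for concordant clones

    records: list[BesRecord] = []
    read_seq = 0
    for i, clone in enumerate(addresses):
        chrom = chrom_names[chrom_idx[i]]
        s = int(start[i])
        e = s + int(insert[i])
        left = GenomeInterval(chrom, s, s + int(read_len[i, 0]), "+")
        right = GenomeInterval(chrom, e - int(read_len[i, 1]), e, "-")

        if discordant[i]:
            left, right = _discordant_geometry(
                rng, int(disc_kind[i]), left, right, chrom_names, chrom_lengths, bounds
            )

        sp6_iv, t7_iv = (left, right) if sp6_on_left[i] else (right, left)
        for primer, iv, um in ((SP6, sp6_iv, unmapped[i, 0]), (T7, t7_iv, unmapped[i, 1])):
            read_seq += 1
            records.append(
                BesRecord(
                    clone=clone,
                    primer=primer,
                    mapping=None if um else iv,
                    read_id=f"SIM{read_seq:07d}",
                )
            )

    labels = TruthLabels()
    if config.defects:
        records, labels = inject_defects(records, labels, config.defects, config.seed)
    return records, labels


def _discordant_geometry(rng, kind, left, right, chrom_names, chrom_lengths, bounds):
    """Replace a clean inward-facing geometry with a random discordant one."""
    if kind == 0:  # same strand -> tail-to-head
        return left, replace(right, strand="+")
    if kind == 1:  # outward facing -> head-to-head
        return replace(left, strand="-"), replace(right, strand="+")
    if kind == 2:  # outsize span
        delta = int(rng.integers(bounds.max_bp, 2 * bounds.max_bp))
        chrom_len = int(chrom_lengths[chrom_names.index(left.chromosome)])
        if right.end + delta <= chrom_len:
            return left, replace(right, start=right.start + delta, end=right.end + delta)
        if left.start - delta >= 0:
            return replace(left, start=left.start - delta, end=left.end - delta), right
        # chromosome too short to stretch: shrink the span below the window instead
        span = int(rng.integers(left.length + 1, bounds.min_bp))
        return left, replace(right, start=left.start + span - right.length, end=left.start + span)
    # kind 3: second end on a different chromosome
    j = int(rng.integers(0, len(chrom_names)))
    if chrom_names[j] == left.chromosome:
        j = (j + 1) % len(chrom_names)
    pos = int(rng.integers(0, chrom_lengths[j] - right.length))
    return left, GenomeInterval(chrom_names[j], pos, pos + right.length, right.strand)


# ---------------------------------------------------------------------------
# defect injection


def inject_defects(
    records: Sequence[BesRecord],
    labels: TruthLabels,
    defects: Iterable[DefectSpec],
    seed: int,
) -> tuple[list[BesRecord], TruthLabels]:
    """Apply *defects* to *records*, updating truth labels exactly.

    Mappings are overwritten in place (never inserted or removed), so the
    record count is conserved.  Deterministic for a given seed.  A clone
    touched by one defect is never re-targeted by a later one, so every
    truth label stays consistent with the final record set.
    """
    records = list(records)
    rng = np.random.default_rng(seed + 1)  # distinct stream from the clean simulation
    index: dict[tuple[int, str, int, str], int] = {
        (r.clone.plate, r.clone.row, r.clone.column, r.primer): i
        for i, r in enumerate(records)
    }
    plates = sorted({r.clone.plate for r in records})
    touched: set[CloneAddress] = set()
    for defect in defects:
        if isinstance(defect, PrimerSwap):
            _inject_primer_swap(records, labels, index, rng, defect, touched)
        elif isinstance(defect, Contamination):
            _inject_contamination(records, labels, rng, defect, touched)
        elif isinstance(defect, AdjacentDuplicate):
            _inject_adjacent_duplicate(records, labels, index, rng, defect, touched)
        elif isinstance(defect, CrossPlateDuplicate):
            _inject_cross_plate_duplicate(records, labels, index, rng, defect, plates, touched)
        else:
            raise DefectError(f"unknown defect spec: {defect!r}")
    return records, labels


def _wells_with_primer(index, plate: int, primer: str) -> list[tuple[str, int]]:
    return sorted(
        ((row, col) for (p, row, col, pr) in index if p == plate and pr == primer),
        key=lambda w: (PLATE_ROWS.index(w[0]), w[1]),
    )


def _inject_primer_swap(records, labels, index, rng, d: PrimerSwap, touched) -> None:
    if d.plate_a == d.plate_b:
        raise DefectError(f"primer_swap needs two distinct plates: {d}")
    if not 0.0 < d.fraction <= 1.0:
        raise DefectError(f"primer_swap fraction must be in (0, 1]: {d}")
    wells_a = set(_wells_with_primer(index, d.plate_a, d.primer))
    wells_b = set(_wells_with_primer(index, d.plate_b, d.primer))
    blocked = {
        c.well for c in touched if c.plate in (d.plate_a, d.plate_b)
    }
    shared = sorted(
        (wells_a & wells_b) - blocked, key=lambda w: (PLATE_ROWS.index(w[0]), w[1])
    )
    if not shared:
        raise DefectError(f"no shared wells with {d.primer} records: {d}")
    k = max(1, round(d.fraction * len(shared)))
    chosen_idx = sorted(rng.choice(len(shared), size=k, replace=False))
    chosen = [shared[i] for i in chosen_idx]
    for row, col in chosen:
        ia = index[(d.plate_a, row, col, d.primer)]
        ib = index[(d.plate_b, row, col, d.primer)]
        ra, rb = records[ia], records[ib]
        records[ia] = replace(ra, mapping=rb.mapping)
        records[ib] = replace(rb, mapping=ra.mapping)
        for r in (ra, rb):
            if r.read_id:
                labels.read_tags[r.read_id] = d.kind
    key = (d.plate_a, d.plate_b, d.primer)
    labels.swapped_wells[key] = frozenset(chosen)
    labels.swap_eligible_wells[key] = frozenset(shared)
    for plate in (d.plate_a, d.plate_b):
        touched.update(
            CloneAddress(records[0].clone.library_prefix, plate, row, col)
            for row, col in chosen
        )
    labels.tag_plate(d.plate_a, d.kind)
    labels.tag_plate(d.plate_b, d.kind)


def _inject_contamination(records, labels, rng, d: Contamination, touched) -> None:
    if d.n_reads < 1 or d.region_span < 1:
        raise DefectError(f"contamination needs n_reads >= 1 and span >= 1: {d}")
    positions = [
        i
        for i, r in enumerate(records)
        if r.clone.plate == d.plate and r.primer == d.primer
        and r.clone not in touched
    ]
    if len(positions) < d.n_reads:
        raise DefectError(
            f"plate {d.plate} has only {len(positions)} {d.primer} reads, "
            f"cannot contaminate {d.n_reads}: {d}"
        )
    chosen = sorted(rng.choice(len(positions), size=d.n_reads, replace=False))
    region = GenomeInterval(
        d.chromosome, d.region_start, d.region_start + d.region_span, "+"
    )
    for ci in chosen:
        i = positions[ci]
        records[i] = replace(records[i], mapping=region)
        if records[i].read_id:
            labels.read_tags[records[i].read_id] = d.kind
        touched.add(records[i].clone)
    labels.tag_plate(d.plate, d.kind)


def _both_ends_mapped_clones(records, index, plate=None) -> list[CloneAddress]:
    mapped: dict[CloneAddress, int] = {}
    for r in records:
        if r.mapping is not None and (plate is None or r.clone.plate == plate):
            mapped[r.clone] = mapped.get(r.clone, 0) + 1
    return sorted((c for c, k in mapped.items() if k == 2))


def _concordant_clones(records) -> list[CloneAddress]:
    """Clones whose two mappings form a tail-to-tail pair under default bounds.

    A re-picked (duplicated) clone is physically an ordinary clone, so only
    concordant clones are eligible duplication sources; a discordant source
    (e.g. ends on two chromosomes) has no meaningful single-span copy.
    """
    from .core import ConcordanceClass, classify_mappings

    by_clone: dict[CloneAddress, dict[str, GenomeInterval]] = {}
    for r in records:
        if r.mapping is not None:
            by_clone.setdefault(r.clone, {})[r.primer] = r.mapping
    return sorted(
        c
        for c, m in by_clone.items()
        if len(m) == 2
        and classify_mappings(m[SP6], m[T7]) is ConcordanceClass.TAIL_TO_TAIL
    )


def _copy_clone_mappings(records, labels, index, rng, source: CloneAddress,
                         target: CloneAddress, kind: str, jitter: int = 250) -> None:
    """Overwrite *target*'s mappings with jittered copies of *source*'s.

    The duplicate well contains the same physical clone, so its end-reads
    align at (nearly) the same positions; the jitter models read-length /
    trimming variation and is bounded by half the read length so the copy
    always shares mapped bases with its source.
    """
    for primer in PRIMERS:
        si = index[(source.plate, source.row, source.column, primer)]
        ti = index[(target.plate, target.row, target.column, primer)]
        src_map = records[si].mapping
        if src_map is None:
            continue
        bound = min(jitter, max(1, (src_map.length - 1) // 2))
        dlt = int(rng.integers(-bound, bound + 1))
        new_start = max(0, src_map.start + dlt)
        new_map = replace(src_map, start=new_start, end=new_start + src_map.length)
        records[ti] = replace(records[ti], mapping=new_map)
        if records[ti].read_id:
            labels.read_tags[records[ti].read_id] = kind
    labels.duplicate_links.append((source.name, target.name))


def _inject_adjacent_duplicate(records, labels, index, rng, d: AdjacentDuplicate,
                               touched) -> None:
    if d.gap not in (0, 1, 2):
        raise DefectError(f"adjacent_duplicate gap must be 0, 1 or 2: {d}")
    if d.axis not in ("same_row", "same_column"):
        raise DefectError(f"adjacent_duplicate axis must be same_row/same_column: {d}")
    step = d.gap + 1  # gap = number of intervening wells
    candidates = [
        c for c in _both_ends_mapped_clones(records, index, plate=d.plate)
        if c not in touched
    ]
    if not candidates:
        raise DefectError(f"plate {d.plate} has no both-ends-mapped clones: {d}")
    order = rng.permutation(len(candidates))
    used: set[tuple[str, int]] = set()
    injected = 0
    for oi in order:
        if injected == d.n_pairs:
            break
        src = candidates[oi]
        if src.well in used:
            continue
        directions = [1, -1] if rng.random() < 0.5 else [-1, 1]
        for sign in directions:
            if d.axis == "same_row":
                row, col = src.row, src.column + sign * step
                if not 1 <= col <= PLATE_COLUMNS:
                    continue
            else:
                ri = src.row_index + sign * step
                if not 0 <= ri < len(PLATE_ROWS):
                    continue
                row, col = PLATE_ROWS[ri], src.column
            if (row, col) in used:
                continue
            target = CloneAddress(src.library_prefix, src.plate, row, col)
            if target in touched:
                continue
            _copy_clone_mappings(records, labels, index, rng, src, target, d.kind)
            used.add(src.well)
            used.add((row, col))
            touched.add(src)
            touched.add(target)
            injected += 1
            break
    if injected < d.n_pairs:
        raise DefectError(
            f"could only place {injected}/{d.n_pairs} adjacent duplicates: {d}"
        )
    labels.tag_plate(d.plate, d.kind)


def _inject_cross_plate_duplicate(records, labels, index, rng, d: CrossPlateDuplicate,
                                  plates: list[int], touched) -> None:
    if not 0.0 < d.overlap_fraction <= 1.0:
        raise DefectError(f"overlap_fraction must be in (0, 1]: {d}")
    if len(plates) < 2:
        raise DefectError("cross_plate_duplicate needs at least two plates")
    candidates = [c for c in _concordant_clones(records) if c not in touched]
    order = rng.permutation(len(candidates))
    injected = 0
    for oi in order:
        if injected == d.n_pairs:
            break
        src = candidates[oi]
        if src in touched:
            continue
        other = [p for p in plates if p != src.plate]
        plate = other[int(rng.integers(0, len(other)))]
        row = PLATE_ROWS[int(rng.integers(0, len(PLATE_ROWS)))]
        col = int(rng.integers(1, PLATE_COLUMNS + 1))
        target = CloneAddress(src.library_prefix, plate, row, col)
        if target in touched:
            continue
        _duplicate_with_overlap(records, labels, index, rng, src, target, d)
        touched.add(src)
        touched.add(target)
        injected += 1
        labels.tag_plate(plate, d.kind)
    if injected < d.n_pairs:
        raise DefectError(
            f"could only place {injected}/{d.n_pairs} cross-plate duplicates: {d}"
        )


def _duplicate_with_overlap(records, labels, index, rng, source, target,
                            d: CrossPlateDuplicate) -> None:
    """Copy *source*'s span to *target*, shifted so span overlap = the target fraction."""
    sp6 = records[index[(source.plate, source.row, source.column, SP6)]].mapping
    t7 = records[index[(source.plate, source.row, source.column, T7)]].mapping
    left, right = sorted((sp6, t7), key=lambda iv: iv.start)
    span_start, span_end = left.start, right.end
    span_len = span_end - span_start
    shift = round((1.0 - d.overlap_fraction) * span_len)
    if span_start - shift >= 0 and rng.random() < 0.5:
        shift = -shift
    s, e = span_start + shift, span_end + shift
    new_left = GenomeInterval(left.chromosome, s, s + left.length, "+")
    new_right = GenomeInterval(left.chromosome, e - right.length, e, "-")
    sp6_iv, t7_iv = (new_left, new_right) if rng.random() < 0.5 else (new_right, new_left)
    for primer, iv in ((SP6, sp6_iv), (T7, t7_iv)):
        ti = index[(target.plate, target.row, target.column, primer)]
        records[ti] = replace(records[ti], mapping=iv)
        if records[ti].read_id:
            labels.read_tags[records[ti].read_id] = d.kind
    labels.duplicate_links.append((source.name, target.name))


# ---------------------------------------------------------------------------
# on-disk emission (same formats io_formats reads)


def write_simulation(
    records: Sequence[BesRecord],
    labels: TruthLabels,
    outdir: Union[str, Path],
    config: Optional[SimulationConfig] = None,
) -> dict[str, Path]:
    """Write the simulated library: BED6 + unmapped sidecar + truth TSVs + config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mappings": outdir / "mappings.bed",
        "unmapped": outdir / "unmapped.txt",
        "read_tags": outdir / "truth_read_tags.tsv",
        "plate_defects": outdir / "truth_plate_defects.tsv",
        "duplicate_links": outdir / "truth_duplicate_links.tsv",
    }
    io_formats.write_bes_mappings(records, paths["mappings"], paths["unmapped"])
    with open(paths["read_tags"], "w") as fh:
        fh.write("read_id\ttag\n")
        for rid in sorted(labels.read_tags):
            fh.write(f"{rid}\t{labels.read_tags[rid]}\n")
    with open(paths["plate_defects"], "w") as fh:
        fh.write("plate\tdefect\n")
        for plate in sorted(labels.plate_defects):
            for kind in labels.plate_defects[plate]:
                fh.write(f"{plate}\t{kind}\n")
    with open(paths["duplicate_links"], "w") as fh:
        fh.write("source\ttarget\n")
        for src, tgt in sorted(labels.duplicate_links):
            fh.write(f"{src}\t{tgt}\n")
    if config is not None:
        paths["config"] = outdir / "sim_config.yaml"
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)
    return paths


def config_to_dict(config: SimulationConfig) -> dict:
    return {
        "seed": config.seed,
        "n_plates": config.n_plates,
        "genome": [[c, int(l)] for c, l in config.genome],
        "insert_mean": config.insert_mean,
        "insert_sd": config.insert_sd,
        "read_length_mean": config.read_length_mean,
        "read_length_sd": config.read_length_sd,
        "p_end_unmapped": config.p_end_unmapped,
        "p_discordant": config.p_discordant,
        "library_prefix": config.library_prefix,
        "insert_bounds": [config.insert_bounds.min_bp, config.insert_bounds.max_bp],
        "defects": [
            {"kind": d.kind, **{f: getattr(d, f) for f in d.__dataclass_fields__}}
            for d in config.defects
        ],
    }


_DEFECT_CLASSES = {
    "primer_swap": PrimerSwap,
    "contamination": Contamination,
    "adjacent_duplicate": AdjacentDuplicate,
    "cross_plate_duplicate": CrossPlateDuplicate,
}


def config_from_dict(data: dict) -> SimulationConfig:
    data = dict(data)
    if "genome" in data:
        data["genome"] = tuple((c, int(l)) for c, l in data["genome"])
    if "insert_bounds" in data:
        lo, hi = data["insert_bounds"]
        data["insert_bounds"] = InsertSizeBounds(int(lo), int(hi))
    defects = []
    for d in data.get("defects", []):
        d = dict(d)
        cls = _DEFECT_CLASSES[d.pop("kind")]
        defects.append(cls(**d))
    data["defects"] = defects
    return SimulationConfig(**data)
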
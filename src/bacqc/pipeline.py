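"""End-to-end QC pipeline: read -> pair -> classify -> every detector -> reports.

``run_pipeline`` chains all stages over one mapping table, writes each
stage's TSV plus a machine-readable JSON summary, and reports whether any
plate failed QC so callers (and the CLI exit code) can gate downstream use
of the library.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from . import contamination, io_formats, overlap_analysis, plate_stats, swap_detector
from .core import DEFAULT_INSERT_BOUNDS, InsertSizeBounds, classify_pairs

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run needs; unset fields take documented defaults."""

    mappings: Union[str, Path] = "mappings.bed"
    unmapped_sidecar: Optional[Union[str, Path]] = None
    dialect: str = io_formats.BED6_DIALECT
    reads_fasta: Optional[Union[str, Path]] = None
    contaminant_fasta: Optional[Union[str, Path]] = None
    outdir: Union[str, Path] = "bacqc_out"
    insert_bounds: InsertSizeBounds = DEFAULT_INSERT_BOUNDS
    alpha: float = 0.05
    flag_metric: str = "prop_tt_of_both_ends"
    swap_min_gain: int = swap_detector.DEFAULT_MIN_GAIN
    hotspot_max_span: int = contamination.DEFAULT_MAX_SPAN
    hotspot_min_clones: int = contamination.DEFAULT_MIN_CLONES
    screen_k: int = contamination.DEFAULT_K
    screen_low: float = contamination.DEFAULT_LOW
    screen_high: float = contamination.DEFAULT_HIGH
    overlap_bin_width: float = 2.0
    write_pairs: bool = False  # full overlap-pair TSV can run to millions of rows

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "insert_bounds" in data:
            lo, hi = data["insert_bounds"]
            data["insert_bounds"] = InsertSizeBounds(int(lo), int(hi))
        return cls(**data)

    def to_dict(self) -> dict:
        out = {}
        for name in self.__dataclass_fields__:
            value = getattr(self, name)
            if isinstance(value, InsertSizeBounds):
                value = [value.min_bp, value.max_bp]
            elif isinstance(value, Path):
                value = str(value)
            out[name] = value
        return out


def run_pipeline(config: RunConfig) -> dict:
    """Run the full QC chain and write per-stage TSVs plus summary.json.

    Returns the summary dict.  ``summary["qc_fail"]`` is true when any
    plate was flagged; the CLI maps that to exit code 2.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info(
        "thresholds: alpha=%s metric=%s swap_min_gain=%s hotspot_max_span=%s "
        "hotspot_min_clones=%s screen_k=%s screen_low=%s screen_high=%s "
        "insert_bounds=[%d, %d]",
        config.alpha, config.flag_metric, config.swap_min_gain,
        config.hotspot_max_span, config.hotspot_min_clones, config.screen_k,
        config.screen_low, config.screen_high,
        config.insert_bounds.min_bp, config.insert_bounds.max_bp,
    )

    records = io_formats.read_bes_mappings(
        config.mappings, dialect=config.dialect, unmapped_sidecar=config.unmapped_sidecar
    )
    pairs = classify_pairs(io_formats.pair_records(records), config.insert_bounds)

    stats = plate_stats.compute_plate_stats(pairs, records)
    io_formats.write_report(plate_stats.stats_to_frame(stats), outdir / "plate_stats.tsv")

    flags = plate_stats.flag_outlier_plates(stats, config.flag_metric, config.alpha)
    io_formats.write_report(plate_stats.flags_to_frame(flags), outdir / "plate_flags.tsv")

    flagged_plates = sorted({f.plate for f in flags})
    by_plate = swap_detector.pairs_by_plate(pairs)
    swap_results = swap_detector.scan_swap_candidates(
        by_plate, flagged_plates, config.insert_bounds, config.swap_min_gain
    )
    io_formats.write_report(
        swap_detector.results_to_frame(swap_results), outdir / "swap_candidates.tsv"
    )

    tt_pairs = [p for p in pairs if p.implied_span is not None]
    overlaps = overlap_analysis.bac_overlap_pairs(tt_pairs)
    hist_same = overlap_analysis.overlap_histogram(overlaps, True, config.overlap_bin_width)
    hist_diff = overlap_analysis.overlap_histogram(overlaps, False, config.overlap_bin_width)
    io_formats.write_report(hist_same.to_frame(), outdir / "overlap_hist_same_plate.tsv")
    io_formats.write_report(hist_diff.to_frame(), outdir / "overlap_hist_diff_plate.tsv")
    if config.write_pairs:
        io_formats.write_report(
            overlap_analysis.overlaps_to_frame(overlaps), outdir / "overlap_pairs.tsv"
        )

    adjacency = overlap_analysis.bes_adjacency_counts(records)
    io_formats.write_report(
        overlap_analysis.adjacency_to_frame(adjacency), outdir / "adjacency_counts.tsv"
    )

    clusters = contamination.detect_hotspots(
        records, config.hotspot_max_span, config.hotspot_min_clones
    )
    io_formats.write_report(
        contamination.clusters_to_frame(clusters), outdir / "hotspot_clusters.tsv"
    )

    hits: list = []
    if config.reads_fasta and config.contaminant_fasta:
        hits = contamination.screen_contaminant(
            config.reads_fasta, config.contaminant_fasta,
            config.screen_k, config.screen_low, config.screen_high,
        )
        io_formats.write_report(
            contamination.hits_to_frame(hits), outdir / "contaminant_hits.tsv"
        )
    summary_frame = contamination.summarize_contamination(clusters, hits, records)
    io_formats.write_report(summary_frame, outdir / "contamination_by_plate.tsv")

    n_mapped = sum(1 for r in records if r.mapping is not None)
    class_counts = {}
    for p in pairs:
        class_counts[p.cls.value] = class_counts.get(p.cls.value, 0) + 1
    summary = {
        "n_records": len(records),
        "n_records_positioned": n_mapped,
        "n_clones": len(pairs),
        "n_plates": len(stats),
        "concordance_class_counts": dict(sorted(class_counts.items())),
        "flagged_plates": [
            {
                "plate": f.plate,
                "metric": f.metric,
                "observed": f.observed,
                "library_rate": f.library_rate,
                "adjusted_p": f.adjusted_p,
                "direction": f.direction,
            }
            for f in flags
        ],
        "swap_candidates": [
            {
                "plate_a": r.plate_a,
                "plate_b": r.plate_b,
                "primer": r.primer,
                "gain": r.gain,
                "n_swapped_wells": r.n_swapped_wells,
                "n_original_wells": r.n_original_wells,
            }
            for r in swap_results
        ],
        "n_overlap_pairs_same_plate": sum(1 for o in overlaps if o.same_plate),
        "n_overlap_pairs_diff_plate": sum(1 for o in overlaps if not o.same_plate),
        "modal_overlap_bin_same_plate": hist_same.modal_bin,
        "modal_overlap_bin_diff_plate": hist_diff.modal_bin,
        "n_adjacency_pairs": sum(c.count for c in adjacency),
        "n_hotspot_clusters": len(clusters),
        "n_contaminant_reads": sum(1 for h in hits if h.verdict == contamination.CONTAMINANT),
        "n_chimera_reads": sum(1 for h in hits if h.verdict == contamination.CHIMERA),
        "qc_fail": bool(flags),
        "thresholds": {
            "alpha": config.alpha,
            "flag_metric": config.flag_metric,
            "swap_min_gain": config.swap_min_gain,
            "hotspot_max_span": config.hotspot_max_span,
            "hotspot_min_clones": config.hotspot_min_clones,
            "screen_k": config.screen_k,
            "screen_low": config.screen_low,
            "screen_high": config.screen_high,
            "insert_bounds": [config.insert_bounds.min_bp, config.insert_bounds.max_bp],
        },
    }
    io_formats.write_report(summary, outdir / "summary.json", format="json")
    return summary
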
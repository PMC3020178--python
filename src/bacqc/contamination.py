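"""Contamination hotspot clustering and k-mer contaminant screening.

A contamination hotspot is many distinct clones' same-primer reads mapping
to one tiny genomic region — the signature of a foreign template (classically
eubacterial 16S rRNA DNA) that was sequenced instead of clone ends and
happens to align somewhere in the reference.  Hotspots are found by
single-linkage clustering of mapped read start coordinates per chromosome.

Independently, reads can be screened against a user-supplied contaminant
reference (e.g. a 16S rRNA sequence) by shared canonical k-mer fraction,
separating outright contaminant reads from chimeras (part genuine insert,
part contaminant) and clean reads.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .core import BesRecord, GenomeInterval

logger = logging.getLogger(__name__)

DEFAULT_MAX_SPAN = 500  # bp; documented hotspots span ~30-110 bp
DEFAULT_MIN_CLONES = 5
DEFAULT_K = 21
DEFAULT_LOW = 0.2
DEFAULT_HIGH = 0.8

CONTAMINANT = "contaminant"
CHIMERA = "chimera"
CLEAN = "clean"


@dataclass(frozen=True, slots=True)
class ContaminationCluster:
    """A tiny genomic region attracting reads from many distinct clones."""

    region: GenomeInterval  # envelope of member mappings
    n_members: int
    n_distinct_clones: int
    plate_histogram: tuple[tuple[int, int], ...]  # (plate, member count)
    primer_histogram: tuple[tuple[str, int], ...]
    member_read_ids: tuple[str, ...]

    @property
    def dominant_plate(self) -> int:
        return max(self.plate_histogram, key=lambda t: t[1])[0]

    @property
    def dominant_plate_fraction(self) -> float:
        return max(c for _, c in self.plate_histogram) / self.n_members

    @property
    def dominant_primer(self) -> str:
        return max(self.primer_histogram, key=lambda t: t[1])[0]

    @property
    def dominant_primer_fraction(self) -> float:
        return max(c for _, c in self.primer_histogram) / self.n_members


def detect_hotspots(
    records: Iterable[BesRecord],
    max_span: int = DEFAULT_MAX_SPAN,
    min_clones: int = DEFAULT_MIN_CLONES,
) -> list[ContaminationCluster]:
    """Cluster mapped reads into contamination hotspots.

    Per chromosome, mapped records are single-linkage clustered by start
    coordinate: consecutive (sorted) starts at most *max_span* apart join
    one cluster.  A cluster is reported when its mapping envelope is at most
    ``2 * max_span`` long (safety factor against chained pileups) and it
    contains reads from at least *min_clones* distinct clones.  Results are
    sorted by member count descending and are invariant to input order.
    """
    if max_span < 1:
        raise ValueError("max_span must be >= 1")
    if min_clones < 2:
        raise ValueError("min_clones must be >= 2")
    by_chrom: dict[str, list[BesRecord]] = defaultdict(list)
    for r in records:
        if r.mapping is not None:
            by_chrom[r.mapping.chromosome].append(r)

    clusters: list[ContaminationCluster] = []
    for chrom in sorted(by_chrom):
        members = sorted(
            by_chrom[chrom],
            key=lambda r: (r.mapping.start, r.mapping.end, r.clone, r.primer),
        )
        block: list[BesRecord] = []
        prev_start = None
        for r in members:
            if prev_start is not None and r.mapping.start - prev_start > max_span:
                clusters.extend(_finish_cluster(block, max_span, min_clones))
                block = []
            block.append(r)
            prev_start = r.mapping.start
        clusters.extend(_finish_cluster(block, max_span, min_clones))
    clusters.sort(
        key=lambda c: (-c.n_members, c.region.chromosome, c.region.start)
    )
    return clusters


def _finish_cluster(
    block: Sequence[BesRecord], max_span: int, min_clones: int
) -> list[ContaminationCluster]:
    if not block:
        return []
    clones = {r.clone for r in block}
    if len(clones) < min_clones:
        return []
    start = min(r.mapping.start for r in block)
    end = max(r.mapping.end for r in block)
    if end - start > 2 * max_span:
        return []
    plate_hist = Counter(r.clone.plate for r in block)
    primer_hist = Counter(r.primer for r in block)
    return [
        ContaminationCluster(
            region=GenomeInterval(block[0].mapping.chromosome, start, end, "+"),
            n_members=len(block),
            n_distinct_clones=len(clones),
            plate_histogram=tuple(sorted(plate_hist.items())),
            primer_histogram=tuple(sorted(primer_hist.items())),
            member_read_ids=tuple(
                sorted(r.read_id or f"{r.clone.name}.{r.primer}" for r in block)
            ),
        )
    ]


# ---------------------------------------------------------------------------
# k-mer contaminant screen


@dataclass(frozen=True, slots=True)
class ContaminantHit:
    read_id: str
    kmer_fraction: float  # shared canonical k-mers / read k-mers, in [0, 1]
    verdict: str  # contaminant | chimera | clean


def _canonical_kmers(seq: str, k: int) -> list[str]:
    seq = seq.upper()
    rc = str(Seq(seq).reverse_complement())
    n = len(seq)
    return [min(seq[i : i + k], rc[n - i - k : n - i]) for i in range(n - k + 1)]


def screen_contaminant(
    reads: Union[str, Path, Iterable],
    reference: Union[str, Path, Iterable],
    k: int = DEFAULT_K,
    low: float = DEFAULT_LOW,
    high: float = DEFAULT_HIGH,
) -> list[ContaminantHit]:
    """Screen reads against a contaminant reference by shared k-mer fraction.

    *reads* and *reference* are FASTA paths (or iterables of Bio.SeqRecord).
    Per read, the fraction of its canonical k-mers present in the
    reference's canonical k-mer set (both strands) decides the verdict:
    >= *high* -> contaminant; in [*low*, *high*) -> chimera; else clean.
    Reads shorter than *k* are clean with a warning.
    """
    if k < 11:
        raise ValueError("k must be >= 11 (shorter k-mers collide too often)")
    if not 0.0 <= low < high <= 1.0:
        raise ValueError(f"need 0 <= low < high <= 1, got low={low}, high={high}")
    ref_records = _as_seq_records(reference)
    read_records = _as_seq_records(reads)
    if not read_records:
        raise ValueError("no reads to screen")

    ref_kmers: set[str] = set()
    for rec in ref_records:
        ref_kmers.update(_canonical_kmers(str(rec.seq), k))

    hits = []
    for rec in read_records:
        seq = str(rec.seq)
        if len(seq) < k:
            logger.warning("read %s shorter than k=%d; verdict clean", rec.id, k)
            hits.append(ContaminantHit(rec.id, 0.0, CLEAN))
            continue
        kmers = _canonical_kmers(seq, k)
        frac = sum(km in ref_kmers for km in kmers) / len(kmers)
        if frac >= high:
            verdict = CONTAMINANT
        elif frac >= low:
            verdict = CHIMERA
        else:
            verdict = CLEAN
        hits.append(ContaminantHit(rec.id, frac, verdict))
    return hits


def _as_seq_records(source) -> list:
    if isinstance(source, (str, Path)):
        return list(SeqIO.parse(str(source), "fasta"))
    return list(source)


# ---------------------------------------------------------------------------
# per-plate roll-up


def summarize_contamination(
    clusters: Sequence[ContaminationCluster],
    hits: Sequence[ContaminantHit],
    records: Sequence[BesRecord],
) -> pd.DataFrame:
    """Per-plate contamination report joining hotspot membership and screen verdicts.

    Columns: reads in hotspot clusters, contaminant-verdict reads, chimera-
    verdict reads, and the overlap (reads both in a hotspot and flagged by
    the screen).  One row per plate present in *records*, plate ascending.
    """
    plate_of_read: dict[str, int] = {}
    plates: set[int] = set()
    for r in records:
        plates.add(r.clone.plate)
        rid = r.read_id or f"{r.clone.name}.{r.primer}"
        plate_of_read[rid] = r.clone.plate

    hotspot_reads: set[str] = set()
    for c in clusters:
        hotspot_reads.update(c.member_read_ids)
    flagged = {h.read_id for h in hits if h.verdict in (CONTAMINANT, CHIMERA)}
    contaminant_reads = {h.read_id for h in hits if h.verdict == CONTAMINANT}
    chimera_reads = {h.read_id for h in hits if h.verdict == CHIMERA}

    rows = []
    for plate in sorted(plates):
        in_hot = {rid for rid in hotspot_reads if plate_of_read.get(rid) == plate}
        in_cont = {rid for rid in contaminant_reads if plate_of_read.get(rid) == plate}
        in_chim = {rid for rid in chimera_reads if plate_of_read.get(rid) == plate}
        rows.append(
            {
                "plate": plate,
                "n_hotspot_reads": len(in_hot),
                "n_contaminant_reads": len(in_cont),
                "n_chimera_reads": len(in_chim),
                "n_hotspot_and_screen": len(in_hot & (in_cont | in_chim)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "plate", "n_hotspot_reads", "n_contaminant_reads",
            "n_chimera_reads", "n_hotspot_and_screen",
        ],
    )


def clusters_to_frame(clusters: Sequence[ContaminationCluster]) -> pd.DataFrame:
    rows = [
        {
            "chromosome": c.region.chromosome,
            "start": c.region.start,
            "end": c.region.end,
            "span": c.region.length,
            "n_members": c.n_members,
            "n_distinct_clones": c.n_distinct_clones,
            "dominant_plate": c.dominant_plate,
            "dominant_plate_fraction": c.dominant_plate_fraction,
            "dominant_primer": c.dominant_primer,
            "dominant_primer_fraction": c.dominant_primer_fraction,
        }
        for c in clusters
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chromosome", "start", "end", "span", "n_members",
            "n_distinct_clones", "dominant_plate", "dominant_plate_fraction",
            "dominant_primer", "dominant_primer_fraction",
        ],
    )


def hits_to_frame(hits: Sequence[ContaminantHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"read_id": h.read_id, "kmer_fraction": h.kmer_fraction, "verdict": h.verdict}
            for h in hits
        ],
        columns=["read_id", "kmer_fraction", "verdict"],
    )
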
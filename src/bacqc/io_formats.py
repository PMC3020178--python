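"""Reading and writing the tables the pipeline touches.

The central exchange format is BED6: one row per mapped BAC-end read, the
``name`` column encoding clone and primer as ``<clone>.<primer>`` (e.g.
``CH243-341E5.SP6``).  An optional 7th column carries the read id
(accession); the writer emits it whenever any record has one, so that
write -> read is an identity at the record level.  Unmapped reads cannot be
expressed in BED and live in a one-name-per-line sidecar file.

All writers are deterministic: fixed column order, rows sorted plate
ascending then well row-major, so identical inputs give byte-identical
files.
"""

from __future__ import annotations

import csv
import json
import logging
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .core import (
    BacPair,
    BesRecord,
    CloneAddress,
    CloneNameError,
    GenomeInterval,
    PlateGeometryError,
    PRIMERS,
    SP6,
    T7,
    parse_clone_name,
)

logger = logging.getLogger(__name__)

BED6_DIALECT = "bed6"
TSV1_DIALECT = "tsv1based"


class MappingTableError(ValueError):
    """Raised when a mapping table has more malformed rows than tolerated."""


def _split_name(name: str) -> tuple[CloneAddress, str]:
    clone_part, sep, primer = name.rpartition(".")
    if not sep or primer not in PRIMERS:
        raise CloneNameError(
            f"name {name!r} does not end in a .SP6/.T7 primer suffix"
        )
    return parse_clone_name(clone_part), primer


def read_bes_mappings(
    path: Union[str, Path],
    dialect: str = BED6_DIALECT,
    unmapped_sidecar: Optional[Union[str, Path]] = None,
    max_error_fraction: float = 0.01,
) -> list[BesRecord]:
    """Read BAC-end-sequence mappings from a BED-like TSV.

    Parameters
    ----------
    path
        Mapping table.  ``bed6`` dialect: chrom, start (0-based), end
        (exclusive), name, score, strand [, read_id].  ``tsv1based``: same
        columns but start is 1-based inclusive (converted on read).
    unmapped_sidecar
        Optional file listing unmapped read names (``clone.primer`` with an
        optional tab-separated read id), returned as records without a
        mapping.
    max_error_fraction
        Abort with :class:`MappingTableError` when more than this fraction
        of rows fail to parse; individual failures are otherwise collected
        and logged with their line numbers.

    Duplicate (clone, primer) rows are collapsed to the single best-scoring
    mapping (ties: leftmost start, then chromosome name), with a warning.
    """
    if dialect not in (BED6_DIALECT, TSV1_DIALECT):
        raise ValueError(f"unknown dialect {dialect!r}")
    offset = 0 if dialect == BED6_DIALECT else 1

    best: dict[tuple[CloneAddress, str], tuple[BesRecord, float]] = {}
    order: list[tuple[CloneAddress, str]] = []
    errors: list[str] = []
    n_rows = 0
    n_collapsed = 0

    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].startswith(("#", "track", "browser")):
                continue
            n_rows += 1
            try:
                if len(row) < 6:
                    raise ValueError(f"expected >= 6 columns, got {len(row)}")
                chrom, start_s, end_s, name, score_s, strand = row[:6]
                clone, primer = _split_name(name)
                interval = GenomeInterval(
                    chromosome=chrom,
                    start=int(start_s) - offset,
                    end=int(end_s),
                    strand=strand,
                )
                score = float(score_s) if score_s not in ("", ".") else 0.0
                read_id = row[6] if len(row) > 6 and row[6] else None
            except (ValueError, CloneNameError, PlateGeometryError) as exc:
                errors.append(f"line {lineno}: {exc}")
                continue
            record = BesRecord(clone=clone, primer=primer, mapping=interval, read_id=read_id)
            key = (clone, primer)
            if key not in best:
                best[key] = (record, score)
                order.append(key)
            else:
                n_collapsed += 1
                old, old_score = best[key]
                new_rank = (-score, interval.start, interval.chromosome)
                old_rank = (-old_score, old.mapping.start, old.mapping.chromosome)
                if new_rank < old_rank:
                    best[key] = (record, score)

    if errors:
        for msg in errors:
            logger.warning("bad mapping row: %s", msg)
        if n_rows and len(errors) / n_rows > max_error_fraction:
            raise MappingTableError(
                f"{len(errors)}/{n_rows} rows unparseable "
                f"(> {max_error_fraction:.1%}); first: {errors[0]}"
            )
    if n_collapsed:
        logger.warning(
            "collapsed %d duplicate (clone, primer) mapping rows to best score",
            n_collapsed,
        )
    if n_rows == 0:
        logger.warning("mapping table %s is empty", path)

    records = [best[key][0] for key in order]

    if unmapped_sidecar is not None:
        records.extend(read_unmapped_sidecar(unmapped_sidecar))
    return records


def read_unmapped_sidecar(path: Union[str, Path]) -> list[BesRecord]:
    """Read the unmapped-read sidecar: ``clone.primer[\\tread_id]`` per line."""
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            clone, primer = _split_name(fields[0])
            read_id = fields[1] if len(fields) > 1 and fields[1] else None
            records.append(BesRecord(clone=clone, primer=primer, read_id=read_id))
    return records


def _record_sort_key(r: BesRecord):
    c = r.clone
    return (c.plate, c.row_index, c.column, r.primer)


def write_bes_mappings(
    records: Iterable[BesRecord],
    path: Union[str, Path],
    unmapped_sidecar: Optional[Union[str, Path]] = None,
) -> None:
    """Write mapped records as BED6(+read_id) and unmapped names to the sidecar."""
    records = sorted(records, key=_record_sort_key)
    with_ids = any(r.read_id for r in records)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for r in records:
            if r.mapping is None:
                continue
            m = r.mapping
            row = [m.chromosome, m.start, m.end, f"{r.clone.name}.{r.primer}", 0, m.strand]
            if with_ids:
                row.append(r.read_id or "")
            w.writerow(row)
    unmapped = [r for r in records if r.mapping is None]
    if unmapped_sidecar is not None:
        with open(unmapped_sidecar, "w") as fh:
            for r in unmapped:
                line = f"{r.clone.name}.{r.primer}"
                if r.read_id:
                    line += f"\t{r.read_id}"
                fh.write(line + "\n")
    elif unmapped:
        logger.warning(
            "%d unmapped records dropped (no sidecar path given)", len(unmapped)
        )


def pair_records(records: Iterable[BesRecord]) -> list[BacPair]:
    """Join end-reads into one (unclassified) :class:`BacPair` per clone address.

    Clones with zero, one or two mapped primers are all represented; extra
    records for an already-seen (clone, primer) are ignored with a warning.
    """
    by_clone: dict[CloneAddress, dict[str, BesRecord]] = defaultdict(dict)
    for r in records:
        slot = by_clone[r.clone]
        if r.primer in slot:
            logger.warning(
                "duplicate record for %s.%s ignored at pairing", r.clone.name, r.primer
            )
            continue
        slot[r.primer] = r
    pairs = [
        BacPair(clone=clone, sp6=slot.get(SP6), t7=slot.get(T7))
        for clone, slot in by_clone.items()
    ]
    pairs.sort(key=lambda p: (p.clone.plate, p.clone.row_index, p.clone.column))
    return pairs


def write_report(stats, path: Union[str, Path], format: str = "tsv") -> None:
    """Write any pipeline product deterministically.

    DataFrames (or lists of dicts) go to TSV with a fixed column order;
    dicts go to sorted-key JSON.  Re-writing identical inputs yields
    byte-identical files.
    """
    path = Path(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(stats, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        return
    if format != "tsv":
        raise ValueError(f"unknown report format {format!r}")
    if isinstance(stats, pd.DataFrame):
        frame = stats
    else:
        frame = pd.DataFrame(list(stats))
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_report(path: Union[str, Path], format: str = "tsv"):
    """Inverse of :func:`write_report` (DataFrame for tsv, object for json)."""
    if format == "json":
        with open(path) as fh:
            return json.load(fh)
    return pd.read_csv(path, sep="\t")
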
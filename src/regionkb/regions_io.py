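"""Region file import/export: BED and GFF dialects with an import report.

Peak files arrive from many callers and browsers with headers, track lines
and occasional malformed rows. Import is therefore forgiving line-by-line
but strict in accounting: every non-blank line is either a validated
interval or a failed record with a reason, and an upload whose first 50
lines yield no valid data is aborted outright.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .core import GenomicInterval

__all__ = [
    "ImportReport",
    "ImportError_",
    "parse_regions_file",
    "find_invalid_regions",
    "write_regions_table",
    "intervals_to_table",
]

#: imports yielding no valid record in this many leading lines are aborted
FIRST_LINES_PROBE = 50


class ImportError_(ValueError):
    """Raised when an upload is rejected as a whole (not per-record)."""


@dataclass
class ImportReport:
    """Outcome of one file import.

    ``n_imported + n_failed`` equals the number of non-blank lines processed;
    blank lines are skipped silently.
    """

    n_imported: int = 0
    n_failed: int = 0
    failed_lines: list[tuple[int, str, str]] = field(default_factory=list)
    genome_build: str = ""

    def record_failure(self, lineno: int, raw: str, reason: str) -> None:
        self.n_failed += 1
        self.failed_lines.append((lineno, raw.rstrip("\n"), reason))


def _split(line: str, delimiter: str) -> list[str] | None:
    if delimiter == "tab":
        return line.rstrip("\n").split("\t")
    if delimiter == "comma":
        return line.rstrip("\n").split(",")
    # auto: prefer tab, fall back to comma
    fields = line.rstrip("\n").split("\t")
    if len(fields) >= 3:
        return fields
    fields = line.rstrip("\n").split(",")
    if len(fields) >= 3:
        return fields
    return None


def _parse_bed_fields(fields: list[str]) -> GenomicInterval:
    if len(fields) < 3:
        raise ValueError("fewer than 3 columns")
    chrom = fields[0].strip()
    if not chrom:
        raise ValueError("empty chromosome name")
    start = int(fields[1])
    end = int(fields[2])
    name = fields[3].strip() if len(fields) > 3 and fields[3].strip() else None
    score: float | None = None
    if len(fields) > 4 and fields[4].strip() not in ("", "."):
        score = float(fields[4])
    strand = None
    if len(fields) > 5 and fields[5].strip() in ("+", "-", "."):
        strand = fields[5].strip()
    return GenomicInterval(chrom, start, end, name, score, strand)


def _parse_gff_fields(fields: list[str]) -> GenomicInterval:
    # GFF: seqname source feature start end score strand frame attribute
    if len(fields) < 5:
        raise ValueError("fewer than 5 columns for GFF")
    chrom = fields[0].strip()
    if not chrom:
        raise ValueError("empty chromosome name")
    start = int(fields[3]) - 1  # 1-based inclusive -> 0-based half-open
    end = int(fields[4])
    score: float | None = None
    if len(fields) > 5 and fields[5].strip() not in ("", "."):
        score = float(fields[5])
    strand = None
    if len(fields) > 6 and fields[6].strip() in ("+", "-", "."):
        strand = fields[6].strip()
    # feature-type and attribute columns are not retained
    return GenomicInterval(chrom, start, end, None, score, strand)


def _classify_invalid(iv: GenomicInterval) -> str | None:
    if iv.start < 0:
        return "negative start coordinate"
    if iv.end < iv.start:
        return "inverted region (end < start)"
    if iv.end == iv.start:
        return "empty region (end == start)"
    return None


def parse_regions_file(
    source: str | os.PathLike,
    format: str = "bed",
    delimiter: str = "auto",
    genome_build: str = "",
) -> tuple[list[GenomicInterval], ImportReport]:
    """Parse a BED or GFF region file into validated intervals plus a report.

    ``source`` may be a path or the file text itself (anything containing a
    newline or tab is treated as text). BED coordinates pass through
    unchanged; GFF start is decremented to reach the internal 0-based
    half-open convention. Header/comment/track lines, rows with too few
    columns or non-numeric coordinates, and inverted or empty regions are
    failed records with reasons. If the first 50 lines produce no valid
    record the import raises :class:`ImportError_`.
    """
    if format not in ("bed", "gff"):
        raise ImportError_(f"unknown format {format!r}: expected 'bed' or 'gff'")
    if delimiter not in ("tab", "comma", "auto"):
        raise ImportError_(f"unknown delimiter {delimiter!r}")
    if not genome_build:
        raise ImportError_("a genome build tag is required for import")

    text: str
    if isinstance(source, str) and ("\n" in source or "\t" in source):
        text = source
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()

    parse_one = _parse_bed_fields if format == "bed" else _parse_gff_fields
    report = ImportReport(genome_build=genome_build)
    intervals: list[GenomicInterval] = []

    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue  # blank lines are not records
        if lineno > FIRST_LINES_PROBE and report.n_imported == 0:
            break  # already doomed; handled below
        fields = _split(line, delimiter)
        if fields is None or len(fields) < 3:
            report.record_failure(lineno, line, "not a delimited record")
            continue
        try:
            iv = parse_one(fields)
        except (ValueError, IndexError) as exc:
            report.record_failure(lineno, line, str(exc))
            continue
        reason = _classify_invalid(iv)
        if reason is not None:
            report.record_failure(lineno, line, reason)
            continue
        intervals.append(iv)
        report.n_imported += 1

    if report.n_imported == 0:
        raise ImportError_(
            f"no valid data in the first {FIRST_LINES_PROBE} lines; import aborted"
        )
    return intervals, report


def find_invalid_regions(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Return intervals whose end precedes their start, preserving order.

    The archive-hygiene check: inverted coordinates betray an upstream
    coordinate-handling bug in the source dataset.
    """
    return [iv for iv in intervals if iv.end < iv.start]


def intervals_to_table(intervals: Iterable[GenomicInterval]) -> pd.DataFrame:
    """Standard tabular form of an interval list (BED-like column order)."""
    rows = [
        {
            "chrom": iv.chrom,
            "start": iv.start,
            "end": iv.end,
            "name": iv.name if iv.name is not None else ".",
            "score": iv.score if iv.score is not None else ".",
            "strand": iv.strand if iv.strand is not None else ".",
        }
        for iv in intervals
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def write_regions_table(rows, path: str | os.PathLike, delimiter: str = "\t") -> None:
    """Write tabular records as delimited text with a single header line.

    ``rows`` is a DataFrame, a list of dicts sharing keys, or a list of
    :class:`GenomicInterval`. Plain interval rows round-trip through
    :func:`parse_regions_file` (the header becomes one failed record).
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    elif rows and isinstance(next(iter(rows)), GenomicInterval):
        df = intervals_to_table(rows)
    else:
        df = pd.DataFrame(list(rows))
        if df.empty:
            df = pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"])
    df.to_csv(path, sep=delimiter, index=False)
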
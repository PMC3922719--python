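"""Core value types for genomic region analysis.

All coordinates are internally 0-based half-open ``[start, end)``, the BED
convention. GFF input (1-based inclusive) is converted on import and never
mixed with internal arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

__all__ = ["GenomicInterval", "RegionSet", "centre"]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """One genomic region on a named chromosome, 0-based half-open.

    ``start`` is inclusive and ``end`` exclusive, so the region length is
    ``end - start``. Validated intervals satisfy ``start < end``; records with
    ``end < start`` ("inverted") or ``end == start`` ("empty") are kept out of
    valid region sets but may exist transiently (e.g. when hunting for
    malformed archive rows).
    """

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)
    strand: str | None = field(default=None, compare=False)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def centre(self) -> int:
        """Floor midpoint; the point used for centre-distance constraints."""
        return (self.start + self.end) // 2

    def is_valid(self) -> bool:
        return bool(self.chrom) and self.start >= 0 and self.start < self.end

    def shift(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(
            self.chrom, self.start + offset, self.end + offset,
            self.name, self.score, self.strand,
        )

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.chrom}:{self.start}-{self.end}"


def centre(iv: GenomicInterval) -> int:
    return iv.centre


class RegionSet:
    """All intervals of one dataset, grouped by chromosome and sorted.

    Intervals are sorted by ``(start, end)`` within each chromosome. The
    constructor rejects invalid intervals (``start >= end``); run imports
    through :mod:`regionkb.regions_io` first, which separates malformed
    records into the import report.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        genome_build: str | None = None,
        label: str | None = None,
    ):
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            if not iv.is_valid():
                raise ValueError(f"invalid interval in RegionSet: {iv!r}")
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for ivs in by_chrom.values():
            ivs.sort(key=lambda i: (i.start, i.end))
        self.by_chrom = by_chrom
        self.genome_build = genome_build
        self.label = label
        self._arrays: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    @property
    def chroms(self) -> list[str]:
        return sorted(self.by_chrom)

    def __len__(self) -> int:
        return sum(len(v) for v in self.by_chrom.values())

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom in self.chroms:
            yield from self.by_chrom[chrom]

    def __contains__(self, iv: GenomicInterval) -> bool:
        return iv in self.by_chrom.get(iv.chrom, [])

    def on(self, chrom: str) -> list[GenomicInterval]:
        return self.by_chrom.get(chrom, [])

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) int64 arrays for one chromosome, sorted by start."""
        if chrom not in self._arrays:
            ivs = self.on(chrom)
            self._arrays[chrom] = (
                np.fromiter((i.start for i in ivs), dtype=np.int64, count=len(ivs)),
                np.fromiter((i.end for i in ivs), dtype=np.int64, count=len(ivs)),
            )
        return self._arrays[chrom]

    def restrict_chrom(self, chrom: str | None) -> "RegionSet":
        if chrom is None:
            return self
        return RegionSet(self.on(chrom), self.genome_build, self.label)

    def __repr__(self) -> str:  # pragma: no cover
        lbl = f" {self.label!r}" if self.label else ""
        return f"<RegionSet{lbl}: {len(self)} regions on {len(self.by_chrom)} chromosomes>"
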
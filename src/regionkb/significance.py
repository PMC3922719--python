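"""Placement-based overlap significance and the Overlap Correlation Value.

The statistical question: given a query region set and a reference region
set, is the observed proximity between them more than chance? For each
query region of length ``L`` the null model places an interval of length
``L`` uniformly at random over every start position that keeps it fully
inside a single interval of a *domain* — the portion of the genome
considered available for binding (whole genome, promoter windows,
intergenic space, or a custom BED file). The per-region p-value is the
fraction of those placements whose distance to the nearest in-domain
reference region is at most the observed distance:

    p = (# favorable placements) / (# valid placements)

Both counts are exact integers computed by interval arithmetic (each
reference expanded by the observed distance and the query length, the
expansion intersected with the valid-start space), so ``1/denominator <= p
<= 1`` always holds and the observed placement itself is favorable.

The Overlap Correlation Value (OCV) summarises a whole comparison as the
fraction of in-domain query regions with ``p`` strictly below a threshold
(default 0.05). Values near 1 indicate strong colocalisation; because the
statistic is directional, both directions and their arithmetic mean are
reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, tss_tes
from .core import GenomicInterval, RegionSet
from .overlap import bp_overlap

__all__ = [
    "DomainSet",
    "RegionPValue",
    "OCVSummary",
    "SignificanceResult",
    "interval_distance",
    "nearest_reference",
    "count_valid_placements",
    "count_favorable_placements",
    "region_pvalue",
    "run_significance",
    "ocv",
    "average_ocv",
    "build_genome_domain",
    "build_promoter_domain",
    "build_intergenic_domain",
]

log = logging.getLogger(__name__)

DEFAULT_P_THRESHOLD = 0.05


def _merge(ranges: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge half-open ranges into a disjoint sorted list (empty ones dropped)."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(r for r in ranges if r[0] < r[1]):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


class DomainSet:
    """The line-space of possible interval locations (the background).

    Holds disjoint, merged, per-chromosome-sorted intervals. Regions must be
    fully contained in a single domain interval to take part in the
    significance calculation.
    """

    def __init__(self, intervals: Iterable[GenomicInterval | tuple], label: str = "custom"):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            if isinstance(iv, GenomicInterval):
                chrom, s, e = iv.chrom, iv.start, iv.end
            else:
                chrom, s, e = iv
            by_chrom.setdefault(chrom, []).append((int(s), int(e)))
        self.by_chrom = {c: _merge(rs) for c, rs in by_chrom.items()}
        self.by_chrom = {c: rs for c, rs in self.by_chrom.items() if rs}
        self.label = label

    @property
    def total_length(self) -> int:
        return sum(e - s for rs in self.by_chrom.values() for s, e in rs)

    def __iter__(self):
        for chrom in sorted(self.by_chrom):
            for s, e in self.by_chrom[chrom]:
                yield GenomicInterval(chrom, s, e)

    def contains(self, iv: GenomicInterval) -> bool:
        """True iff the interval lies fully inside one domain interval."""
        for s, e in self.by_chrom.get(iv.chrom, ()):
            if s <= iv.start and iv.end <= e:
                return True
        return False

    def restrict(self, regions: RegionSet) -> tuple[RegionSet, int]:
        """Keep only fully in-domain regions; also return the dropped count."""
        kept = [iv for iv in regions if self.contains(iv)]
        return (
            RegionSet(kept, genome_build=regions.genome_build, label=regions.label),
            len(regions) - len(kept),
        )

    def shift(self, offset: int) -> "DomainSet":
        return DomainSet(
            ((c, s + offset, e + offset) for c, rs in self.by_chrom.items() for s, e in rs),
            label=self.label,
        )


@dataclass(frozen=True)
class RegionPValue:
    """Per-query-region significance record."""

    query: GenomicInterval
    reference: GenomicInterval
    query_size: int
    distance: int
    numerator: int
    denominator: int
    p: float


@dataclass
class OCVSummary:
    """Overlap Correlation Value of one directional comparison."""

    threshold: float
    ocv: float
    n_tested: int
    direction: tuple[str, str] = ("query", "reference")


@dataclass
class SignificanceResult:
    """Full output of one query-vs-reference significance run."""

    records: list[RegionPValue]
    n_query_dropped: int = 0
    n_reference_dropped: int = 0
    n_query_skipped_no_reference: int = 0
    direction: tuple[str, str] = ("query", "reference")

    def table(self) -> pd.DataFrame:
        """Result table; the p-value is the last column."""
        rows = [
            {
                "query_chrom": r.query.chrom, "query_start": r.query.start,
                "query_end": r.query.end,
                "ref_chrom": r.reference.chrom, "ref_start": r.reference.start,
                "ref_end": r.reference.end,
                "query_size": r.query_size, "distance": r.distance,
                "numerator": r.numerator, "denominator": r.denominator,
                "p_value": r.p,
            }
            for r in self.records
        ]
        return pd.DataFrame(
            rows,
            columns=["query_chrom", "query_start", "query_end", "ref_chrom",
                     "ref_start", "ref_end", "query_size", "distance",
                     "numerator", "denominator", "p_value"],
        )


def interval_distance(q: GenomicInterval, r: GenomicInterval) -> float:
    """Gap between two intervals; 0 when they overlap or are bookended.

    Different chromosomes yield +inf — such a reference is never nearest.
    """
    if q.chrom != r.chrom:
        return float("inf")
    return float(max(0, -bp_overlap(q, r)))


def nearest_reference(
    q: GenomicInterval, refs: RegionSet
) -> tuple[GenomicInterval, int]:
    """Reference minimising the gap to q; ties go to the lower (start, end)."""
    candidates = refs.on(q.chrom)
    if not candidates:
        raise ValueError(f"no reference regions on chromosome {q.chrom}")
    starts, ends = refs.arrays(q.chrom)
    # gap = max(0, start - q.end + 1?) no: half-open gap = max(start - q.end, q.start - end, 0)
    gaps = np.maximum(np.maximum(starts - q.end, q.start - ends), 0)
    i = int(np.argmin(gaps))  # first minimum in (start, end) sort order
    return candidates[i], int(gaps[i])


def count_valid_placements(L: int, domain: DomainSet) -> int:
    """Number of start positions fitting an interval of length L in the domain."""
    if L < 1:
        raise ValueError("placement length must be >= 1")
    return sum(
        max(0, (e - s) - L + 1)
        for rs in domain.by_chrom.values()
        for s, e in rs
    )


def _favorable_start_ranges(
    L: int, domain_ranges: list[tuple[int, int]],
    starts: np.ndarray, ends: np.ndarray, d: int,
) -> int:
    """Count valid starts on one chromosome within distance d of some reference.

    A placement [s, s+L) is within distance d of reference [r0, r1) iff
    r0 - d - L <= s <= r1 + d. Favorable windows (one per reference) are
    merged and intersected with the valid-start ranges [D0, D1 - L].
    """
    if starts.size == 0:
        return 0
    win_lo = starts - d - L
    win_hi = ends + d + 1  # half-open on the start axis
    # starts are sorted, hence win_lo is sorted: merge in one pass
    merged_lo: list[int] = []
    merged_hi: list[int] = []
    for lo, hi in zip(win_lo.tolist(), win_hi.tolist()):
        if merged_hi and lo <= merged_hi[-1]:
            if hi > merged_hi[-1]:
                merged_hi[-1] = hi
        else:
            merged_lo.append(lo)
            merged_hi.append(hi)
    total = 0
    vi = 0
    valid = [(s, e - L + 1) for s, e in domain_ranges if e - s >= L]
    for lo, hi in zip(merged_lo, merged_hi):
        for vs, ve in valid:
            a, b = max(lo, vs), min(hi, ve)
            if a < b:
                total += b - a
    return total


def count_favorable_placements(
    L: int, domain: DomainSet, refs: RegionSet, d: int
) -> int:
    """Valid placements whose gap to the nearest reference is <= d.

    Computed chromosome by chromosome with exact interval arithmetic; on
    chromosomes without references no placement is favorable.
    """
    total = 0
    for chrom, ranges in domain.by_chrom.items():
        starts, ends = refs.arrays(chrom)
        total += _favorable_start_ranges(L, ranges, starts, ends, d)
    return total


def region_pvalue(
    q: GenomicInterval, refs: RegionSet, domain: DomainSet
) -> RegionPValue:
    """Placement p-value of one query region against its nearest reference.

    Requires the query fully inside one domain interval and the references
    already restricted to the domain.
    """
    if not domain.contains(q):
        raise ValueError(f"query region {q} is not contained in the domain")
    ref, d = nearest_reference(q, refs)
    L = q.length
    denominator = count_valid_placements(L, domain)
    if denominator == 0:
        raise ValueError("domain admits no placement of the query length")
    numerator = count_favorable_placements(L, domain, refs, d)
    return RegionPValue(
        query=q, reference=ref, query_size=L, distance=d,
        numerator=numerator, denominator=denominator,
        p=numerator / denominator,
    )


def run_significance(
    query: RegionSet, reference: RegionSet, domain: DomainSet
) -> SignificanceResult:
    """Per-region placement p-values of a query set against a reference set.

    Query and reference regions not fully contained in one domain interval
    are dropped (their counts are reported); query regions whose chromosome
    has no in-domain reference are skipped with a warning and excluded from
    the tested count.
    """
    q_in, q_dropped = domain.restrict(query)
    r_in, r_dropped = domain.restrict(reference)
    if len(q_in) == 0:
        raise ValueError("no query regions fall within the domain")
    if len(r_in) == 0:
        raise ValueError("no reference regions fall within the domain")
    records: list[RegionPValue] = []
    skipped = 0
    # denominator and favorable-count machinery are shared across queries of
    # equal length; cache denominators by L
    denom_cache: dict[int, int] = {}
    for q in q_in:
        if not r_in.on(q.chrom):
            skipped += 1
            continue
        ref, d = nearest_reference(q, r_in)
        L = q.length
        if L not in denom_cache:
            denom_cache[L] = count_valid_placements(L, domain)
        denominator = denom_cache[L]
        if denominator == 0:
            skipped += 1
            continue
        numerator = count_favorable_placements(L, domain, r_in, d)
        records.append(
            RegionPValue(q, ref, L, d, numerator, denominator, numerator / denominator)
        )
    if skipped:
        log.warning(
            "%d query region(s) skipped: no in-domain reference on their chromosome",
            skipped,
        )
    return SignificanceResult(
        records=records,
        n_query_dropped=q_dropped,
        n_reference_dropped=r_dropped,
        n_query_skipped_no_reference=skipped,
        direction=(query.label or "query", reference.label or "reference"),
    )


def ocv(
    results: SignificanceResult | Sequence[RegionPValue],
    threshold: float = DEFAULT_P_THRESHOLD,
) -> OCVSummary:
    """Overlap Correlation Value: fraction of regions with p strictly below
    the threshold."""
    if isinstance(results, SignificanceResult):
        records = results.records
        direction = results.direction
    else:
        records = list(results)
        direction = ("query", "reference")
    if not records:
        raise ValueError("cannot compute an OCV from an empty result list")
    n_below = sum(1 for r in records if r.p < threshold)
    return OCVSummary(
        threshold=threshold,
        ocv=n_below / len(records),
        n_tested=len(records),
        direction=direction,
    )


def average_ocv(forward: OCVSummary | float, reverse: OCVSummary | float) -> float:
    """Arithmetic mean of the two directional OCVs."""
    f = forward.ocv if isinstance(forward, OCVSummary) else float(forward)
    r = reverse.ocv if isinstance(reverse, OCVSummary) else float(reverse)
    return (f + r) / 2.0


# -- prebuilt domain constructors -----------------------------------------


def build_genome_domain(chrom_sizes: dict[str, int]) -> DomainSet:
    """Whole-genome domain: one interval [0, size) per chromosome."""
    for c, size in chrom_sizes.items():
        if size <= 0:
            raise ValueError(f"chromosome {c} has non-positive size")
    return DomainSet(
        ((c, 0, size) for c, size in chrom_sizes.items()), label="whole_genome"
    )


def build_promoter_domain(
    genes: Sequence[GeneModel],
    chrom_sizes: dict[str, int],
    flank: int = 10_000,
) -> DomainSet:
    """Promoter domain: TSS +/- flank windows, clipped and merged."""
    if not genes:
        raise ValueError("empty gene table")
    windows = []
    for g in genes:
        tss, _ = tss_tes(g)
        size = chrom_sizes.get(g.chrom)
        hi = tss + flank if size is None else min(size, tss + flank)
        windows.append((g.chrom, max(0, tss - flank), hi))
    return DomainSet(windows, label="promoters_10kb" if flank == 10_000 else f"promoters_{flank}")


def build_intergenic_domain(
    genes: Sequence[GeneModel], chrom_sizes: dict[str, int]
) -> DomainSet:
    """Intergenic domain: complement of merged gene bodies within each chromosome."""
    if not genes:
        raise ValueError("empty gene table")
    bodies: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}
    for g in genes:
        if g.chrom in bodies:
            bodies[g.chrom].append((g.txStart, g.txEnd))
    pieces = []
    for chrom, size in chrom_sizes.items():
        pos = 0
        for s, e in _merge(bodies[chrom]):
            s, e = max(0, s), min(size, e)
            if s > pos:
                pieces.append((chrom, pos, s))
            pos = max(pos, e)
        if pos < size:
            pieces.append((chrom, pos, size))
    return DomainSet(pieces, label="intergenic")
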
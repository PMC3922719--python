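"""Seeded synthetic data and brute-force oracles.

Generators emit region sets, gene tables, domains and chromosome-sizes
tables on a toy genome, so every analysis is testable without downloading
real peak data. All generators are pure functions of their spec and seed.

The oracle functions re-derive analysis results by exhaustive enumeration
(all pairs, all placements). They exist for testing only and are never
imported by the production analysis paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .annotation import GeneModel
from .core import GenomicInterval, RegionSet
from .overlap import OverlapPair, OverlapParams, bp_overlap, centre_distance, pair_matches
from .significance import DomainSet, RegionPValue

__all__ = [
    "SimSpec",
    "TOY_CHROM_SIZES",
    "simulate_region_set",
    "plant_overlap_structure",
    "simulate_gene_table",
    "oracle_overlap_pairs",
    "oracle_matching_regions",
    "oracle_sections",
    "oracle_region_pvalue",
]

#: default toy genome: three short chromosomes, small enough that
#: enumeration oracles stay sub-second
TOY_CHROM_SIZES: dict[str, int] = {"chr1": 10_000_000, "chr2": 5_000_000, "chr3": 1_000_000}


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one synthetic region set."""

    n_regions: int = 500
    size_min: int = 50
    size_max: int = 500
    chrom_sizes: dict[str, int] = field(default_factory=lambda: dict(TOY_CHROM_SIZES))
    seed: int = 0
    overlap_fraction: float = 0.0
    jitter: int = 0

    def __post_init__(self):
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must be in [0, 1]")
        if self.size_min < 1 or self.size_max < self.size_min:
            raise ValueError("region sizes must be positive with size_min <= size_max")


def _draw_regions(rng: np.random.Generator, n: int, spec: SimSpec) -> list[GenomicInterval]:
    chroms = sorted(spec.chrom_sizes)
    weights = np.array([spec.chrom_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        size = int(rng.integers(spec.size_min, spec.size_max + 1))
        size = min(size, spec.chrom_sizes[chrom])
        start = int(rng.integers(0, spec.chrom_sizes[chrom] - size + 1))
        out.append(GenomicInterval(chrom, start, start + size))
    return out


def simulate_region_set(spec: SimSpec, label: str | None = None) -> RegionSet:
    """Uniform random regions: uniform chromosome (length-weighted), start
    and size, clipped inside chromosome bounds; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    return RegionSet(_draw_regions(rng, spec.n_regions, spec), label=label)


def plant_overlap_structure(
    base: RegionSet, spec: SimSpec, label: str | None = None
) -> RegionSet:
    """A derived set with a planted overlapping fraction.

    ``floor(overlap_fraction * n_regions)`` regions are copies of sampled
    base regions shifted by at most ``jitter`` bp (guaranteeing >= 1 bp of
    overlap whenever jitter < region size); the remainder are placed
    uniformly as in :func:`simulate_region_set`.
    """
    if len(base) == 0:
        raise ValueError("base region set is empty")
    rng = np.random.default_rng(spec.seed)
    n_planted = int(spec.overlap_fraction * spec.n_regions)
    base_list = list(base)
    planted = []
    for idx in rng.integers(0, len(base_list), size=n_planted):
        b = base_list[int(idx)]
        off = int(rng.integers(-spec.jitter, spec.jitter + 1)) if spec.jitter else 0
        size = spec.chrom_sizes.get(b.chrom, b.end + abs(off))
        start = min(max(0, b.start + off), max(0, size - b.length))
        planted.append(GenomicInterval(b.chrom, start, start + b.length))
    rest = _draw_regions(rng, spec.n_regions - n_planted, spec)
    return RegionSet(planted + rest, label=label)


def simulate_gene_table(
    n_genes: int,
    chrom_sizes: dict[str, int] | None = None,
    seed: int = 0,
    tx_min: int = 2_000,
    tx_max: int = 50_000,
    assembly: str = "toy1",
) -> list[GeneModel]:
    """Random strand-aware gene models with CDS inside tx and 1-3 exons."""
    chrom_sizes = dict(TOY_CHROM_SIZES) if chrom_sizes is None else chrom_sizes
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_sizes)
    genes = []
    for i in range(n_genes):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        tx_len = int(rng.integers(tx_min, min(tx_max, chrom_sizes[chrom] // 2) + 1))
        tx_start = int(rng.integers(0, chrom_sizes[chrom] - tx_len + 1))
        tx_end = tx_start + tx_len
        cds_pad = int(rng.integers(0, max(1, tx_len // 4)))
        n_exons = int(rng.integers(1, 4))
        bounds = sorted(rng.integers(tx_start, tx_end + 1, size=2 * n_exons).tolist())
        exon_starts = tuple(bounds[0::2])
        exon_ends = tuple(max(s + 1, b) for s, b in zip(exon_starts, bounds[1::2]))
        genes.append(
            GeneModel(
                gene_id=f"G{i + 1:04d}",
                accession=f"NM_{i + 1:06d}",
                chrom=chrom,
                strand="+" if rng.random() < 0.5 else "-",
                txStart=tx_start,
                txEnd=tx_end,
                cdsStart=tx_start + cds_pad,
                cdsEnd=tx_end - cds_pad if tx_end - cds_pad > tx_start + cds_pad else tx_end,
                exonStarts=exon_starts,
                exonEnds=exon_ends,
                assembly=assembly,
            )
        )
    return genes


def derive_spec(spec: SimSpec, **changes) -> SimSpec:
    return replace(spec, **changes)


# -- brute-force oracles (test-only) --------------------------------------


def oracle_overlap_pairs(
    A: RegionSet, B: RegionSet, params: OverlapParams = OverlapParams()
) -> list[OverlapPair]:
    """All-pairs O(n^2) evaluation of the matching rule."""
    A = A.restrict_chrom(params.chrom_restrict)
    B = B.restrict_chrom(params.chrom_restrict)
    pairs = []
    for a in A:
        for b in B.on(a.chrom):
            if pair_matches(a, b, params):
                pairs.append(OverlapPair(a, b, bp_overlap(a, b), centre_distance(a, b)))
    return pairs


def oracle_matching_regions(
    A: RegionSet, B: RegionSet, params: OverlapParams = OverlapParams()
) -> list[GenomicInterval]:
    """A regions with >= 1 qualifying partner, by linear scan."""
    A = A.restrict_chrom(params.chrom_restrict)
    B = B.restrict_chrom(params.chrom_restrict)
    return [
        a for a in A
        if any(pair_matches(a, b, params) for b in B.on(a.chrom))
    ]


def oracle_sections(
    A: RegionSet, B: RegionSet, params: OverlapParams = OverlapParams()
) -> set[tuple[str, int, int]]:
    """Distinct intersection intervals of qualifying pairs."""
    out = set()
    for p in oracle_overlap_pairs(A, B, params):
        a, b = p.region_a, p.region_b
        out.add((a.chrom, max(a.start, b.start), min(a.end, b.end)))
    return out


def oracle_pair_mask(
    A: RegionSet, B: RegionSet, params: OverlapParams = OverlapParams()
) -> dict[str, np.ndarray]:
    """Dense all-pairs qualification matrix per chromosome.

    Entry [i, j] is True iff the i-th A region and j-th B region of that
    chromosome (both in (start, end) order) satisfy the matching rule.
    Exhaustive by construction; used to derive every analysis in tests.
    """
    A = A.restrict_chrom(params.chrom_restrict)
    B = B.restrict_chrom(params.chrom_restrict)
    out: dict[str, np.ndarray] = {}
    for chrom in A.chroms:
        sa, ea = A.arrays(chrom)
        sb, eb = B.arrays(chrom)
        if sb.size == 0:
            out[chrom] = np.zeros((sa.size, 0), dtype=bool)
            continue
        ov = np.minimum(ea[:, None], eb[None, :]) - np.maximum(sa[:, None], sb[None, :])
        mask = ov >= params.min_bp_overlap
        if params.exclusive_proximity:
            mask &= ov <= 0
        if params.max_centre_distance is not None:
            ca = (sa + ea) // 2
            cb = (sb + eb) // 2
            mask &= np.abs(ca[:, None] - cb[None, :]) <= params.max_centre_distance
        out[chrom] = mask
    return out


def oracle_region_pvalue(
    q: GenomicInterval, refs: RegionSet, domain: DomainSet
) -> RegionPValue:
    """Exhaustive placement enumeration; exact integers, no interval tricks.

    Walks every start position that keeps a query-length interval inside a
    single domain interval, computes its gap to the nearest reference by
    linear scan, and counts placements at most as far as the observed one.
    """
    L = q.length
    # observed distance: linear scan, ties to lower (start, end)
    best = None
    for r in refs:
        if r.chrom != q.chrom:
            continue
        gap = max(0, max(r.start - q.end, q.start - r.end))
        key = (gap, r.start, r.end)
        if best is None or key < best[0]:
            best = (key, r)
    if best is None:
        raise ValueError(f"no reference on chromosome {q.chrom}")
    d, ref = best[0][0], best[1]

    denominator = 0
    numerator = 0
    for chrom, ranges in domain.by_chrom.items():
        ref_list = [r for r in refs if r.chrom == chrom]
        for s, e in ranges:
            for start in range(s, e - L + 1):
                denominator += 1
                gaps = [
                    max(0, max(r.start - (start + L), start - r.end))
                    for r in ref_list
                ]
                if gaps and min(gaps) <= d:
                    numerator += 1
    if denominator == 0:
        raise ValueError("domain admits no placement of the query length")
    return RegionPValue(
        query=q, reference=ref, query_size=L, distance=d,
        numerator=numerator, denominator=denominator, p=numerator / denominator,
    )
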
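"""Pairwise and multi-set overlap analyses for region sets.

The matching rule is a signed base-pair threshold: ``bp_overlap(a, b)`` is
positive for shared bases, zero for bookended intervals and negative for a
gap of that magnitude, so a positive ``min_bp_overlap`` demands shared
sequence while a negative one admits nearby-but-separated regions (proximity
mode, typically combined with a maximum centre distance). All comparisons
are partitioned by chromosome; the efficient path uses a per-chromosome
interval index with a widened query window, with candidate pairs re-checked
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .core import GenomicInterval, RegionSet

__all__ = [
    "OverlapParams",
    "OverlapPair",
    "SectionRecord",
    "VennCounts",
    "bp_overlap",
    "centre_distance",
    "pair_matches",
    "overlap_percentages",
    "regions_overlapping",
    "regions_not_overlapping",
    "overlap_sections",
    "regions_overlapping_all",
    "sections_common_all",
    "venn_counts",
]


@dataclass(frozen=True)
class OverlapParams:
    """Matching constraints for one analysis.

    ``min_bp_overlap``: signed; positive requires that many shared bases,
    zero admits bookended regions, negative allows separation up to its
    magnitude. ``max_centre_distance``: optional cap on the distance between
    floor-midpoints. ``chrom_restrict``: run the analysis on one chromosome
    only. ``exclusive_proximity``: with a negative threshold, additionally
    exclude genuinely overlapping pairs (keep only separated neighbours).
    """

    min_bp_overlap: int = 1
    max_centre_distance: int | None = None
    chrom_restrict: str | None = None
    exclusive_proximity: bool = False

    def __post_init__(self):
        if self.max_centre_distance is not None and self.max_centre_distance < 0:
            raise ValueError("max_centre_distance must be >= 0")


@dataclass(frozen=True)
class OverlapPair:
    region_a: GenomicInterval
    region_b: GenomicInterval
    bp_overlap: int
    centre_distance: int


@dataclass(frozen=True)
class SectionRecord:
    """The intersection interval of one qualifying region pair."""

    chrom: str
    start: int
    end: int
    source_a: GenomicInterval
    source_b: GenomicInterval

    def as_interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


def bp_overlap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Signed overlap: shared bases if positive, gap size (negated) if negative."""
    if a.chrom != b.chrom:
        raise ValueError(f"intervals on different chromosomes: {a.chrom} vs {b.chrom}")
    return min(a.end, b.end) - max(a.start, b.start)


def centre_distance(a: GenomicInterval, b: GenomicInterval) -> int:
    """Absolute distance between floor-midpoints."""
    if a.chrom != b.chrom:
        raise ValueError(f"intervals on different chromosomes: {a.chrom} vs {b.chrom}")
    return abs(a.centre - b.centre)


def pair_matches(a: GenomicInterval, b: GenomicInterval, params: OverlapParams) -> bool:
    ov = bp_overlap(a, b)
    if ov < params.min_bp_overlap:
        return False
    if params.exclusive_proximity and ov > 0:
        return False
    if params.max_centre_distance is not None:
        if centre_distance(a, b) > params.max_centre_distance:
            return False
    return True


class _MatchIndex:
    """Per-chromosome interval index over a reference set B.

    Queries widen the probe interval by the admissible gap plus one so that
    bookended and separated candidates surface; every candidate is then
    re-checked with the exact rule.
    """

    def __init__(self, B: RegionSet):
        self._trees: dict[str, IntervalTree] = {}
        for chrom, ivs in B.by_chrom.items():
            self._trees[chrom] = IntervalTree.from_tuples(
                (iv.start, iv.end, iv) for iv in ivs
            )

    def matches(self, a: GenomicInterval, params: OverlapParams) -> list[GenomicInterval]:
        tree = self._trees.get(a.chrom)
        if tree is None:
            return []
        pad = max(0, -params.min_bp_overlap) + 1
        found = [
            hit.data for hit in tree.overlap(a.start - pad, a.end + pad)
            if pair_matches(a, hit.data, params)
        ]
        found.sort(key=lambda iv: (iv.start, iv.end))
        return found


def _restricted(sets: Iterable[RegionSet], params: OverlapParams) -> list[RegionSet]:
    return [s.restrict_chrom(params.chrom_restrict) for s in sets]


def regions_overlapping(
    A: RegionSet,
    B: RegionSet,
    params: OverlapParams = OverlapParams(),
    extract_both: bool = False,
) -> list[GenomicInterval] | list[OverlapPair]:
    """A-regions matching B (one row per A region), or all qualifying pairs.

    Without ``extract_both`` each A region with at least one qualifying B
    partner is reported once; with it, one :class:`OverlapPair` per
    qualifying (a, b) pair is returned, carrying the signed bp overlap and
    the centre distance.
    """
    A, B = _restricted((A, B), params)
    index = _MatchIndex(B)
    if not extract_both:
        return [a for a in A if index.matches(a, params)]
    pairs: list[OverlapPair] = []
    for a in A:
        for b in index.matches(a, params):
            pairs.append(OverlapPair(a, b, bp_overlap(a, b), centre_distance(a, b)))
    return pairs


def regions_not_overlapping(
    A: RegionSet, B: RegionSet, params: OverlapParams = OverlapParams()
) -> list[GenomicInterval]:
    """Exact complement of :func:`regions_overlapping` within A."""
    A, B = _restricted((A, B), params)
    index = _MatchIndex(B)
    return [a for a in A if not index.matches(a, params)]


def overlap_sections(
    A: RegionSet, B: RegionSet, params: OverlapParams = OverlapParams()
) -> list[SectionRecord]:
    """Intersection interval per qualifying pair; exact duplicates collapsed.

    One A region overlapping k B regions contributes up to k sections, so the
    section count can exceed the matching-region count. Sections are only
    defined for a positive overlap requirement.
    """
    if params.min_bp_overlap < 1:
        raise ValueError("overlap sections require min_bp_overlap >= 1")
    A, B = _restricted((A, B), params)
    index = _MatchIndex(B)
    seen: dict[tuple[str, int, int], SectionRecord] = {}
    for a in A:
        for b in index.matches(a, params):
            key = (a.chrom, max(a.start, b.start), min(a.end, b.end))
            if key not in seen:
                seen[key] = SectionRecord(key[0], key[1], key[2], a, b)
    return sorted(seen.values(), key=lambda s: (s.chrom, s.start, s.end))


def overlap_percentages(
    sets: Sequence[RegionSet], params: OverlapParams = OverlapParams()
) -> pd.DataFrame:
    """Directional overlap percentages for every ordered pair of sets.

    For each ordered (A, B): the percentage of A regions with at least one
    qualifying match in B, and the same with roles swapped.
    """
    if len(sets) < 2:
        raise ValueError("need at least two region sets")
    restricted = _restricted(sets, params)
    for orig, s in zip(sets, restricted):
        if len(s) == 0:
            raise ValueError(f"empty region set {orig.label or ''!r} in percentage analysis")
    labels = [s.label or f"set{i + 1}" for i, s in enumerate(sets)]
    counts: dict[tuple[int, int], int] = {}
    for i, Ai in enumerate(restricted):
        for j, Bj in enumerate(restricted):
            if i != j:
                counts[(i, j)] = len(regions_overlapping(Ai, Bj, params))
    rows = []
    for i in range(len(sets)):
        for j in range(len(sets)):
            if i == j:
                continue
            rows.append(
                {
                    "dataset_a": labels[i],
                    "dataset_b": labels[j],
                    "n_a": len(restricted[i]),
                    "n_b": len(restricted[j]),
                    "n_a_matching_b": counts[(i, j)],
                    "pct_a_matching_b": 100.0 * counts[(i, j)] / len(restricted[i]),
                    "pct_b_matching_a": 100.0 * counts[(j, i)] / len(restricted[j]),
                }
            )
    return pd.DataFrame(rows)


def regions_overlapping_all(
    A: RegionSet, others: Sequence[RegionSet], params: OverlapParams = OverlapParams()
) -> list[GenomicInterval]:
    """A regions with at least one qualifying match in every other set."""
    if not others:
        raise ValueError("need at least one other region set")
    A = A.restrict_chrom(params.chrom_restrict)
    indexes = [_MatchIndex(o.restrict_chrom(params.chrom_restrict)) for o in others]
    return [a for a in A if all(ix.matches(a, params) for ix in indexes)]


def sections_common_all(
    sets: Sequence[RegionSet], params: OverlapParams = OverlapParams()
) -> list[SectionRecord]:
    """Sections common to two or three sets.

    With three sets the first two are sectioned and the result is sectioned
    against the third with the same parameters, so the outcome depends on the
    order given.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError("sections in common are defined for 2 or 3 region sets")
    sections = overlap_sections(sets[0], sets[1], params)
    if len(sets) == 3:
        intermediate = RegionSet(
            (s.as_interval() for s in sections),
            genome_build=sets[0].genome_build,
        )
        sections = overlap_sections(intermediate, sets[2], params)
    return sections


@dataclass
class VennCounts:
    """Region counts for a 2- or 3-set comparison.

    Pairwise shared counts are relative to the first-named set of each pair
    (the number of its regions matching the other), and the triple count is
    the number of sections common to all three in the given order; zone
    counts are therefore order-dependent, with the reference order recorded
    in ``labels``.
    """

    labels: list[str]
    totals: list[int]
    pairwise: dict[tuple[str, str], int]
    triple: int | None = None

    def to_text(self) -> str:
        lines = ["# Venn comparison (reference order: " + ", ".join(self.labels) + ")"]
        for lbl, tot in zip(self.labels, self.totals):
            lines.append(f"total\t{lbl}\t{tot}")
        for (la, lb), n in self.pairwise.items():
            lines.append(f"shared\t{la} & {lb}\t{n}")
        if self.triple is not None:
            lines.append(f"shared\t{' & '.join(self.labels)}\t{self.triple}")
        return "\n".join(lines) + "\n"


def venn_counts(
    sets: Sequence[RegionSet], params: OverlapParams = OverlapParams()
) -> VennCounts:
    """Zone counts for a Venn comparison of exactly 2 or 3 sets."""
    if not 2 <= len(sets) <= 3:
        raise ValueError(
            "Venn comparison requires exactly two or three datasets; "
            "select three datasets to proceed"
        )
    restricted = _restricted(sets, params)
    labels = [s.label or f"set{i + 1}" for i, s in enumerate(sets)]
    pairwise: dict[tuple[str, str], int] = {}
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            pairwise[(labels[i], labels[j])] = len(
                regions_overlapping(restricted[i], restricted[j], params)
            )
    triple = None
    if len(sets) == 3:
        section_params = params
        if params.min_bp_overlap < 1:
            section_params = OverlapParams(1, params.max_centre_distance,
                                           params.chrom_restrict)
        triple = len(sections_common_all(restricted, section_params))
    return VennCounts(labels, [len(s) for s in restricted], pairwise, triple)


def draw_venn(counts: VennCounts, path: str) -> None:
    """Render the zone counts as a simple fixed-layout circle diagram."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    fig, ax = plt.subplots(figsize=(5, 5))
    n = len(counts.labels)
    centres = [(-0.35, 0.2), (0.35, 0.2), (0.0, -0.4)][:n]
    colors = ["tab:blue", "tab:orange", "tab:green"]
    for (x, y), lbl, tot, col in zip(centres, counts.labels, counts.totals, colors):
        ax.add_patch(Circle((x, y), 0.62, alpha=0.3, color=col))
        ax.text(x, y + 0.68, f"{lbl} ({tot})", ha="center", fontsize=9)
    lines = [f"{la} & {lb}: {v}" for (la, lb), v in counts.pairwise.items()]
    if counts.triple is not None:
        lines.append("all three: %d" % counts.triple)
    ax.text(0, -1.25, "\n".join(lines), ha="center", fontsize=9)
    ax.set_xlim(-1.4, 1.4)
    ax.set_ylim(-1.6, 1.2)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
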
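"""Placement p-values, OCV, and domain constructors."""

import numpy as np
import pytest

from regionkb.annotation import GeneModel
from regionkb.core import GenomicInterval, RegionSet
from regionkb.significance import (
    DomainSet,
    average_ocv,
    build_genome_domain,
    build_intergenic_domain,
    build_promoter_domain,
    count_favorable_placements,
    count_valid_placements,
    interval_distance,
    nearest_reference,
    ocv,
    region_pvalue,
    run_significance,
)
from regionkb.simulate import SimSpec, oracle_region_pvalue, simulate_region_set


def iv(c, s, e):
    return GenomicInterval(c, s, e)


class TestDistances:
    @pytest.mark.parametrize(
        "q,r,expected",
        [
            ((100, 200), (150, 250), 0),
            ((100, 200), (250, 300), 50),
            ((100, 200), (200, 300), 0),  # bookended
        ],
    )
    def test_interval_distance(self, q, r, expected):
        assert interval_distance(iv("chr1", *q), iv("chr1", *r)) == expected

    def test_cross_chromosome_is_infinite(self):
        assert interval_distance(iv("chr1", 0, 10), iv("chr2", 0, 10)) == float("inf")

    def test_nearest_prefers_touching_reference(self):
        refs = RegionSet([iv("chr1", 300, 400), iv("chr1", 190, 210)])
        ref, d = nearest_reference(iv("chr1", 100, 200), refs)
        assert ref == iv("chr1", 190, 210) and d == 0

    def test_equidistant_tie_goes_to_lower_start(self):
        refs = RegionSet([iv("chr1", 250, 260), iv("chr1", 0, 50)])
        ref, d = nearest_reference(iv("chr1", 100, 200), refs)
        assert d == 50 and ref == iv("chr1", 0, 50)

    def test_nearest_matches_linear_scan(self):
        rng = np.random.default_rng(4)
        refs = RegionSet(
            [iv("chr1", int(s), int(s) + int(l))
             for s, l in zip(rng.integers(0, 100_000, 200), rng.integers(1, 500, 200))]
        )
        for _ in range(50):
            s = int(rng.integers(0, 100_000))
            q = iv("chr1", s, s + int(rng.integers(1, 400)))
            _, d = nearest_reference(q, refs)
            expected = min(
                max(0, max(r.start - q.end, q.start - r.end)) for r in refs
            )
            assert d == expected


class TestPlacementCounts:
    def test_valid_placements_single_domain(self):
        assert count_valid_placements(10, DomainSet([("chr1", 0, 100)])) == 91

    def test_valid_placements_split_domain(self):
        dom = DomainSet([("chr1", 0, 50), ("chr1", 60, 100)])
        assert count_valid_placements(10, dom) == 41 + 31

    def test_too_long_query_has_no_placement(self):
        assert count_valid_placements(200, DomainSet([("chr1", 0, 100)])) == 0

    def test_favorable_worked_toy(self):
        dom = DomainSet([("chr1", 0, 100)])
        refs = RegionSet([iv("chr1", 50, 60)])
        assert count_favorable_placements(10, dom, refs, 0) == 21  # starts 40..60

    def test_favorable_saturates_at_domain_span(self):
        dom = DomainSet([("chr1", 0, 100)])
        refs = RegionSet([iv("chr1", 50, 60)])
        assert count_favorable_placements(10, dom, refs, 1000) == count_valid_placements(10, dom)

    def test_disjoint_reference_windows_add_up(self):
        dom = DomainSet([("chr1", 0, 1000)])
        refs = RegionSet([iv("chr1", 100, 110), iv("chr1", 800, 810)])
        got = count_favorable_placements(10, dom, refs, 0)
        # per-ref counts when the expansion windows are disjoint
        one = count_favorable_placements(10, dom, RegionSet([iv("chr1", 100, 110)]), 0)
        two = count_favorable_placements(10, dom, RegionSet([iv("chr1", 800, 810)]), 0)
        assert got == one + two

    def test_favorable_monotone_in_distance(self):
        dom = DomainSet([("chr1", 0, 5000)])
        refs = RegionSet([iv("chr1", 1000, 1100), iv("chr1", 3000, 3050)])
        counts = [count_favorable_placements(25, dom, refs, d) for d in (0, 10, 100, 1000)]
        assert counts == sorted(counts)


class TestRegionPValue:
    def test_worked_toy_21_over_91(self):
        dom = DomainSet([("chr1", 0, 100)])
        refs = RegionSet([iv("chr1", 50, 60)])
        r = region_pvalue(iv("chr1", 40, 50), refs, dom)
        assert (r.numerator, r.denominator) == (21, 91)
        assert r.p == pytest.approx(21 / 91)
        assert r.distance == 0

    def test_single_placement_domain_gives_p_one(self):
        dom = DomainSet([("chr1", 40, 50)])
        refs = RegionSet([iv("chr1", 40, 50)])
        r = region_pvalue(iv("chr1", 40, 50), refs, dom)
        assert r.denominator == 1 and r.p == 1.0

    def test_query_equal_to_sole_reference_minimises_p(self):
        dom = DomainSet([("chr1", 0, 10_000)])
        refs = RegionSet([iv("chr1", 5000, 5100)])
        r = region_pvalue(iv("chr1", 5000, 5100), refs, dom)
        oracle = oracle_region_pvalue(iv("chr1", 5000, 5100), refs, dom)
        assert (r.numerator, r.denominator) == (oracle.numerator, oracle.denominator)
        # overlapping the sole reference achieves the minimum distance, hence
        # the minimum achievable p for this configuration
        assert r.distance == 0
        assert r.numerator == count_favorable_placements(100, dom, refs, 0)

    def test_matches_enumeration_on_random_configs(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            n_pieces = int(rng.integers(1, 4))
            pieces, pos = [], 0
            for _ in range(n_pieces):
                pos += int(rng.integers(0, 300))
                width = int(rng.integers(50, 3000))
                pieces.append(("chr1", pos, pos + width))
                pos += width
            dom = DomainSet(pieces)
            refs = RegionSet(
                [
                    iv("chr1", s, s + int(rng.integers(5, 60)))
                    for s in rng.integers(0, pos, int(rng.integers(1, 5)))
                ]
            )
            L = int(rng.integers(1, 40))
            starts = [
                s
                for c, a, b in pieces
                if b - a >= L
                for s in (int(rng.integers(a, b - L + 1)),)
            ]
            if not starts:
                continue
            q = iv("chr1", starts[0], starts[0] + L)
            got = region_pvalue(q, refs, dom)
            exp = oracle_region_pvalue(q, refs, dom)
            assert (got.numerator, got.denominator) == (exp.numerator, exp.denominator)
            assert got.distance == exp.distance

    def test_bounds_invariant(self):
        dom = DomainSet([("chr1", 0, 2000)])
        refs = RegionSet([iv("chr1", 700, 750)])
        rng = np.random.default_rng(1)
        for _ in range(25):
            L = int(rng.integers(1, 100))
            s = int(rng.integers(0, 2000 - L))
            r = region_pvalue(iv("chr1", s, s + L), refs, dom)
            assert 1 <= r.numerator <= r.denominator
            assert 1 / r.denominator <= r.p <= 1.0

    def test_shift_invariance(self):
        dom = DomainSet([("chr1", 100, 4100), ("chr1", 5000, 6000)])
        refs = RegionSet([iv("chr1", 1000, 1060), iv("chr1", 5400, 5410)])
        q = iv("chr1", 2000, 2030)
        base = region_pvalue(q, refs, dom)
        off = 12_345
        shifted = region_pvalue(
            q.shift(off),
            RegionSet([r.shift(off) for r in refs]),
            dom.shift(off),
        )
        assert (base.numerator, base.denominator) == (shifted.numerator, shifted.denominator)

    def test_out_of_domain_query_rejected(self):
        dom = DomainSet([("chr1", 0, 100)])
        with pytest.raises(ValueError, match="not contained"):
            region_pvalue(iv("chr1", 90, 120), RegionSet([iv("chr1", 0, 10)]), dom)


class TestRunSignificance:
    def test_boundary_straddlers_dropped_and_counted(self):
        dom = DomainSet([("chr1", 0, 1000), ("chr1", 2000, 3000)])
        query = RegionSet([iv("chr1", 10, 50), iv("chr1", 990, 1010)])
        refs = RegionSet([iv("chr1", 100, 150), iv("chr1", 1500, 1600)])
        res = run_significance(query, refs, dom)
        assert res.n_query_dropped == 1
        assert res.n_reference_dropped == 1  # the ref in the domain gap
        assert len(res.records) == 1

    def test_out_of_domain_reference_invisible_to_nearest(self):
        dom = DomainSet([("chr1", 0, 1000)])
        query = RegionSet([iv("chr1", 500, 520)])
        # nearer reference straddles the domain edge and must be ignored
        refs = RegionSet([iv("chr1", 530, 1200), iv("chr1", 100, 150)])
        res = run_significance(query, refs, dom)
        assert res.records[0].reference == iv("chr1", 100, 150)

    def test_composes_regionwise(self):
        dom = DomainSet([("chr1", 0, 5000)])
        query = RegionSet([iv("chr1", 100, 150), iv("chr1", 3000, 3020)])
        refs = RegionSet([iv("chr1", 200, 260), iv("chr1", 4000, 4010)])
        res = run_significance(query, refs, dom)
        for rec, q in zip(res.records, query):
            solo = region_pvalue(q, refs, dom)
            assert (rec.numerator, rec.denominator) == (solo.numerator, solo.denominator)

    def test_table_has_pvalue_last(self):
        dom = DomainSet([("chr1", 0, 5000)])
        query = RegionSet([iv("chr1", 100, 150)])
        refs = RegionSet([iv("chr1", 200, 260)])
        df = run_significance(query, refs, dom).table()
        assert list(df.columns)[-1] == "p_value"
        assert {"numerator", "denominator", "distance", "query_size"} < set(df.columns)

    def test_all_queries_outside_domain_errors(self):
        dom = DomainSet([("chr2", 0, 100)])
        query = RegionSet([iv("chr1", 0, 10)])
        refs = RegionSet([iv("chr2", 0, 10)])
        with pytest.raises(ValueError, match="no query regions"):
            run_significance(query, refs, dom)


class TestOCV:
    def _records(self, ps):
        dom = DomainSet([("chr1", 0, 100)])
        refs = RegionSet([iv("chr1", 50, 60)])
        base = region_pvalue(iv("chr1", 40, 50), refs, dom)
        from dataclasses import replace

        return [replace(base, p=p) for p in ps]

    def test_fraction_strictly_below_threshold(self):
        s = ocv(self._records([0.01, 0.04, 0.2, 0.5]), 0.05)
        assert s.ocv == 0.5 and s.n_tested == 4

    def test_threshold_is_strict(self):
        assert ocv(self._records([0.05, 0.3]), 0.05).ocv == 0.0

    def test_extremes(self):
        assert ocv(self._records([0.01, 0.002]), 0.05).ocv == 1.0
        assert ocv(self._records([0.9, 0.8]), 0.05).ocv == 0.0

    def test_empty_results_error(self):
        with pytest.raises(ValueError):
            ocv([])

    def test_average_is_arithmetic_mean(self):
        assert average_ocv(0.50, 0.72) == pytest.approx(0.61)
        assert average_ocv(0.3, 0.3) == 0.3
        assert average_ocv(0.0, 1.0) == 0.5


class TestDomainBuilders:
    def _genes(self):
        return [
            GeneModel("A1", "chr1", "+", 5000, 9000),
            GeneModel("B1", "chr1", "-", 50_000, 70_000),
        ]

    def test_genome_domain_covers_chromosomes(self, chrom_sizes):
        dom = build_genome_domain(chrom_sizes)
        assert dom.total_length == sum(chrom_sizes.values())
        assert len(list(dom)) == len(chrom_sizes)

    def test_promoter_windows_clipped_and_merged(self):
        genes = [GeneModel("A1", "chr1", "+", 5000, 9000)]
        dom = build_promoter_domain(genes, {"chr1": 100_000}, flank=10_000)
        assert list(dom) == [iv("chr1", 0, 15_000)]
        near = [
            GeneModel("A1", "chr1", "+", 30_000, 40_000),
            GeneModel("A2", "chr1", "+", 31_000, 45_000),
        ]
        merged = build_promoter_domain(near, {"chr1": 100_000}, flank=10_000)
        assert list(merged) == [iv("chr1", 20_000, 41_000)]

    def test_intergenic_complements_gene_bodies(self):
        genes = [GeneModel("A1", "chr1", "+", 100, 200)]
        dom = build_intergenic_domain(genes, {"chr1": 1000})
        assert list(dom) == [iv("chr1", 0, 100), iv("chr1", 200, 1000)]

    def test_gene_covering_chromosome_leaves_nothing(self):
        genes = [GeneModel("A1", "chr1", "+", 0, 1000)]
        dom = build_intergenic_domain(genes, {"chr1": 1000, "chr2": 500})
        assert list(dom) == [iv("chr2", 0, 500)]

    def test_gene_bodies_plus_intergenic_tile_the_chromosome(self):
        sizes = {"chr1": 200_000}
        genes = self._genes()
        inter = build_intergenic_domain(genes, sizes)
        covered = np.zeros(sizes["chr1"], dtype=bool)
        for piece in inter:
            covered[piece.start:piece.end] = True
        for g in genes:
            covered[g.txStart:g.txEnd] = True
        assert covered.all()


class TestCalibration:
    def test_null_queries_give_near_uniform_pvalues(self, chrom_sizes):
        dom = build_genome_domain(chrom_sizes)
        refs = simulate_region_set(SimSpec(n_regions=500, seed=11), label="ref")
        null_q = simulate_region_set(SimSpec(n_regions=2000, seed=12), label="null")
        res = run_significance(null_q, refs, dom)
        s = ocv(res)
        assert s.n_tested == 2000
        assert abs(s.ocv - 0.05) <= 0.02
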
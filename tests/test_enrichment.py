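"""Annotation composition, TFBS ratios, permutation/Fisher/hypergeometric tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylscape import enrichment
from methylscape.core_io import GenomicInterval
from methylscape.errors import ConfigError, DataError


def _sites(positions, chrom="chr1"):
    return pd.DataFrame({"chrom": chrom, "pos": positions})


class TestAnnotateSites:
    def test_precedence_rule(self):
        tracks = {
            "promoter": [GenomicInterval("chr1", 0, 100)],
            "intron": [GenomicInterval("chr1", 0, 100)],
        }
        labels, _ = enrichment.annotate_sites(
            _sites([50]), tracks, precedence=("promoter", "intron")
        )
        assert labels.iloc[0] == "promoter"

    def test_unannotated_fallback_and_composition_sums_to_one(self):
        tracks = {"promoter": [GenomicInterval("chr1", 0, 100)]}
        labels, comp = enrichment.annotate_sites(
            _sites([50, 500, 600]), tracks, precedence=("promoter",)
        )
        assert list(labels) == ["promoter", "unannotated", "unannotated"]
        assert comp.sum() == pytest.approx(1.0)

    def test_missing_precedence_track_rejected(self):
        with pytest.raises(ConfigError):
            enrichment.annotate_sites(_sites([1]), {}, precedence=("promoter",))

    def test_matches_brute_force_membership(self, rng):
        tracks = {
            name: [
                GenomicInterval("chr1", int(s), int(s) + int(l))
                for s, l in zip(rng.integers(0, 5000, 30), rng.integers(1, 200, 30))
            ]
            for name in ("a", "b", "c")
        }
        sites = _sites(sorted(rng.integers(0, 6000, 200)))
        labels, _ = enrichment.annotate_sites(sites, tracks, precedence=("a", "b", "c"))
        for pos, label in zip(sites["pos"], labels):
            expected = "unannotated"
            for name in ("a", "b", "c"):
                if any(iv.start <= pos < iv.end for iv in tracks[name]):
                    expected = name
                    break
            assert label == expected


class TestTfbsRatio:
    def test_direct_arithmetic(self):
        # factor A holds 5% of TFBS bp but 10% of TFBS-overlapping sites
        tracks = {
            "A": [GenomicInterval("chr1", 0, 50)],
            "B": [GenomicInterval("chr1", 1000, 1950)],
        }
        sites = _sites([10] + list(range(1000, 1009)))  # 1 in A, 9 in B
        out = enrichment.tfbs_enrichment_ratio(sites, tracks)
        assert out.loc["A", "obs_prop"] == pytest.approx(0.1)
        assert out.loc["A", "bg_prop"] == pytest.approx(0.05)
        assert out.loc["A", "ratio"] == pytest.approx(2.0)

    def test_factor_without_sites_has_zero_ratio(self):
        tracks = {
            "A": [GenomicInterval("chr1", 0, 100)],
            "B": [GenomicInterval("chr1", 200, 300)],
        }
        out = enrichment.tfbs_enrichment_ratio(_sites([250]), tracks)
        assert out.loc["A", "ratio"] == 0.0

    def test_uniform_sites_give_ratio_near_one(self, rng):
        edges = np.linspace(0, 100_000, 21).astype(int)
        tracks = {
            f"f{i}": [GenomicInterval("chr1", int(a), int(b))]
            for i, (a, b) in enumerate(zip(edges[:-1], edges[1:]))
        }
        sites = _sites(sorted(rng.integers(0, 100_000, 5000)))
        out = enrichment.tfbs_enrichment_ratio(sites, tracks)
        n, p = 5000, 0.05
        sd_prop = np.sqrt(p * (1 - p) / n)
        assert (np.abs(out["obs_prop"] - p) < 3 * sd_prop).all()


class TestPermutationOverlap:
    UNIVERSE = {"chr1": 10_000}

    def test_subject_covering_universe_degenerates(self):
        res = enrichment.permutation_overlap_test(
            [GenomicInterval("chr1", 10, 20)],
            [GenomicInterval("chr1", 0, 10_000)],
            self.UNIVERSE,
            n_perm=200,
            seed=1,
        )
        assert res["p"] == 1.0 and res["z"] is None

    def test_engineered_enrichment_attains_minimal_p(self):
        query = [GenomicInterval("chr1", i * 10, i * 10 + 5) for i in range(10)]
        subject = [GenomicInterval("chr1", 0, 100)]
        res = enrichment.permutation_overlap_test(
            query, subject, self.UNIVERSE, n_perm=199, seed=2
        )
        assert res["p"] == pytest.approx(1 / 200)
        assert res["z"] > 3

    def test_seed_determinism_and_p_range(self):
        args = (
            [GenomicInterval("chr1", 100, 200)],
            [GenomicInterval("chr1", 150, 400)],
            self.UNIVERSE,
        )
        a = enrichment.permutation_overlap_test(*args, n_perm=100, seed=7)
        b = enrichment.permutation_overlap_test(*args, n_perm=100, seed=7)
        assert a == b
        assert 1 / 101 <= a["p"] <= 1.0

    def test_interval_outside_universe_rejected(self):
        with pytest.raises(DataError):
            enrichment.permutation_overlap_test(
                [GenomicInterval("chr1", 0, 20_000)], [], self.UNIVERSE
            )


class TestFisherRegionEnrichment:
    def test_or_and_p_match_hypergeometric_enumeration(self):
        a, b, c, d = 30, 10, 10, 50
        oddsr, p = enrichment._fisher_or_p(a, b, c, d)
        assert oddsr == pytest.approx(15.0)
        # exact upper tail: P(X >= a) for X ~ Hypergeom(N, a+b, a+c)
        N = a + b + c + d
        p_exact = stats.hypergeom.sf(a - 1, N, a + b, a + c)
        assert p == pytest.approx(float(p_exact), rel=1e-9)

    def test_query_equal_set_is_maximally_enriched(self):
        universe = {"chr1": 20_000}
        track = [GenomicInterval("chr1", 0, 5_000)]
        filtered, full = enrichment.fisher_region_enrichment(
            track, {"self": track}, universe
        )
        assert "self" in filtered.index
        # minimal attainable p with 20 bins and 5 query bins: 1/C(20,5)
        assert full.loc["self", "p"] == pytest.approx(1 / 15504, rel=1e-6)

    def test_haldane_correction_on_zero_cell(self):
        oddsr, _ = enrichment._fisher_or_p(5, 0, 3, 7)
        assert oddsr == pytest.approx((5.5 * 7.5) / (0.5 * 3.5))

    def test_independent_query_set_usually_unfiltered(self, rng):
        universe = {"chr1": 50_000}
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            query = [
                GenomicInterval("chr1", int(s), int(s) + 100)
                for s in r.integers(0, 49_000, 20)
            ]
            track = [
                GenomicInterval("chr1", int(s), int(s) + 100)
                for s in r.integers(0, 49_000, 20)
            ]
            filtered, _ = enrichment.fisher_region_enrichment(
                query, {"t": track}, universe
            )
            hits += int(len(filtered) > 0)
        assert hits <= 1

    def test_query_outside_universe_rejected(self):
        with pytest.raises(DataError):
            enrichment.fisher_region_enrichment(
                [GenomicInterval("chr1", 0, 100)], {}, {"chr2": 1000}
            )


class TestPromoterSiteCounts:
    def test_disjoint_sites_counted(self):
        proms = {"g1": GenomicInterval("chr1", 0, 1000)}
        sites = [GenomicInterval("chr1", 10, 30), GenomicInterval("chr1", 500, 520)]
        res = enrichment.count_promoter_sites(proms, {"g1": "C1"}, sites)
        assert res["counts"]["g1"] == 2

    def test_no_sites_skips_anova_with_note(self):
        proms = {
            f"g{i}": GenomicInterval("chr1", i * 1000, i * 1000 + 500) for i in range(4)
        }
        clusters = {"g0": "C1", "g1": "C1", "g2": "C2", "g3": "C2"}
        res = enrichment.count_promoter_sites(proms, clusters, [])
        assert (res["counts"] == 0).all()
        assert res["anova"] is None and "no sites" in res["note"]

    def test_synthetic_c3_enrichment_detected(self, default_study):
        from methylscape.integration import promoter_windows

        proms = promoter_windows(default_study["genome"].genes)
        truth = default_study["manifest"].gene["cluster"]
        clusters = truth[truth != "null"].to_dict()
        res = enrichment.count_promoter_sites(
            proms, clusters, default_study["tfbs"]["EZH2"]
        )
        assert res["summary"].loc["C3", "mean"] == res["summary"]["mean"].max()
        assert res["anova"][1] < 0.01


class TestHypergeomGeneset:
    def test_exact_enumeration_example(self):
        pop = {f"g{i}" for i in range(20)}
        gene_set = {f"g{i}" for i in range(5)}
        selected = {"g0", "g1", "g2", "g3", "g10"}
        p, p_bonf = enrichment.hypergeom_geneset(selected, gene_set, pop)
        assert p == pytest.approx(76 / 15504)
        assert p_bonf == pytest.approx(76 / 15504)

    def test_zero_overlap_is_not_significant(self):
        pop = {f"g{i}" for i in range(100)}
        p, _ = enrichment.hypergeom_geneset({"g50"}, {"g0", "g1"}, pop)
        assert p > 0.9

    def test_selected_equals_population_gives_p_one(self):
        pop = {f"g{i}" for i in range(10)}
        p, _ = enrichment.hypergeom_geneset(pop, {"g0", "g1"}, pop)
        assert p == pytest.approx(1.0)

    def test_bonferroni_scaling_caps_at_one(self):
        pop = {f"g{i}" for i in range(10)}
        p, p_bonf = enrichment.hypergeom_geneset({"g0"}, {"g0"}, pop, n_sets=50)
        assert p_bonf == min(1.0, p * 50)

    def test_non_subset_rejected(self):
        with pytest.raises(DataError):
            enrichment.hypergeom_geneset({"x"}, {"g0"}, {"g0", "g1"})
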
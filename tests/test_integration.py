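"""DEG calling, quadrant classification, co-expression, Cox stratification."""

import numpy as np
import pandas as pd
import pytest

from methylscape import integration
from methylscape.core_io import GeneModel, GenomicInterval, SurvivalTable, ExpressionMatrix
from methylscape.errors import DataError


def _expr(tpm_normal, tpm_tumor, gene_ids=None):
    tpm_normal = np.atleast_2d(tpm_normal)
    tpm_tumor = np.atleast_2d(tpm_tumor)
    n_n, n_t = tpm_normal.shape[1], tpm_tumor.shape[1]
    ids = [f"n{i}" for i in range(n_n)] + [f"t{i}" for i in range(n_t)]
    genes = gene_ids or [f"g{i}" for i in range(tpm_normal.shape[0])]
    tpm = pd.DataFrame(
        np.hstack([tpm_normal, tpm_tumor]),
        index=pd.Index(genes, name="gene_id"),
        columns=ids,
    )
    labels = pd.Series(["normal"] * n_n + ["tumor"] * n_t, index=ids)
    return ExpressionMatrix(tpm=tpm, sample_labels=labels)


class TestPromoterWindows:
    def test_plus_strand_window(self):
        g = GeneModel("g", "chr1", "+", 10_000, 10_000, 30_000)
        iv = integration.promoter_windows([g])["g"]
        assert (iv.start, iv.end) == (5_500, 10_500)

    def test_minus_strand_window(self):
        g = GeneModel("g", "chr1", "-", 10_000, 5_000, 10_000)
        iv = integration.promoter_windows([g])["g"]
        assert (iv.start, iv.end) == (9_500, 14_500)

    def test_clipped_at_zero(self):
        g = GeneModel("g", "chr1", "+", 100, 100, 10_000)
        iv = integration.promoter_windows([g])["g"]
        assert (iv.start, iv.end) == (0, 600)


class TestCallDegs:
    def test_log2fc_arithmetic(self):
        e = _expr(np.full((1, 4), 2.0), np.full((1, 4), 8.0))
        out = integration.call_degs(e)
        assert out["log2fc"].iloc[0] == pytest.approx(np.log2(9 / 3))

    def test_identical_cohorts_all_ns(self, rng):
        vals = rng.random((20, 4)) * 100
        e = _expr(vals, vals)
        out = integration.call_degs(e)
        assert (out["status"] == "ns").all()

    def test_status_invariant_to_sample_order(self, rng):
        n_vals = rng.random((30, 5)) * 50
        t_vals = rng.random((30, 5)) * 50
        t_vals[:10] *= 20
        e1 = _expr(n_vals, t_vals)
        e2 = _expr(n_vals[:, ::-1], t_vals[:, ::-1])
        out1 = integration.call_degs(e1)
        out2 = integration.call_degs(e2)
        assert (out1["status"] == out2["status"]).all()

    def test_fold_change_invariant_under_common_scaling(self, rng):
        vals_n = rng.random((20, 4)) * 100 + 1
        vals_t = rng.random((20, 4)) * 100 + 1
        a = integration.call_degs(_expr(vals_n, vals_t), pseudocount=0)
        b = integration.call_degs(_expr(10 * vals_n, 10 * vals_t), pseudocount=0)
        np.testing.assert_allclose(a["log2fc"], b["log2fc"], atol=1e-12)
        assert (a["status"] == b["status"]).all()

    def test_small_cohort_rejected(self):
        e = _expr(np.full((2, 1), 1.0), np.full((2, 4), 1.0))
        with pytest.raises(DataError):
            integration.call_degs(e)


def _dmr_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "direction", "n_dmcs", "density",
                 "mean_delta", "q_region"],
    )


class TestClassifyQuadrants:
    PROMS = {"gA": GenomicInterval("chr1", 1000, 2000, "+", "gA")}

    def _degs(self, status):
        return pd.DataFrame(
            {"gene_id": ["gA"], "log2fc": [2.0 if status == "up" else -2.0],
             "p": [1e-4], "q": [1e-3], "status": [status]}
        )

    def test_hyper_up_is_c3(self):
        dmrs = _dmr_frame([("chr1", 1100, 1300, "hyper", 3, 0.015, 0.3, 1e-4)])
        table, counts = integration.classify_quadrants(dmrs, self.PROMS, self._degs("up"))
        assert table["cluster"].iloc[0] == "C3" and counts["C3"] == 1

    def test_hypo_down_is_c4(self):
        dmrs = _dmr_frame([("chr1", 1100, 1300, "hypo", 3, 0.015, -0.3, 1e-4)])
        table, _ = integration.classify_quadrants(dmrs, self.PROMS, self._degs("down"))
        assert table["cluster"].iloc[0] == "C4"

    def test_non_significant_dmr_excluded(self):
        dmrs = _dmr_frame([("chr1", 1100, 1300, "hyper", 3, 0.015, 0.3, 0.5)])
        table, counts = integration.classify_quadrants(dmrs, self.PROMS, self._degs("up"))
        assert len(table) == 0 and sum(counts.values()) == 0

    def test_direction_from_smallest_q_then_largest_delta(self):
        dmrs = _dmr_frame(
            [
                ("chr1", 1100, 1200, "hyper", 2, 0.02, 0.2, 1e-5),
                ("chr1", 1400, 1500, "hypo", 2, 0.02, -0.4, 1e-3),
            ]
        )
        table, _ = integration.classify_quadrants(dmrs, self.PROMS, self._degs("up"))
        assert table["prom_direction"].iloc[0] == "hyper"

    def test_counts_sum_to_assignments(self, default_study):
        from methylscape import dmc, dmr

        filtered = dmc.filter_matrix(default_study["methylome"])
        calls = dmc.call_dmcs(filtered)
        regions = dmr.aggregate_dmr_significance(dmr.build_dmrs(calls))
        degs = integration.call_degs(default_study["expression"])
        proms = integration.promoter_windows(default_study["genome"].genes)
        table, counts = integration.classify_quadrants(regions, proms, degs)
        assert sum(counts.values()) == len(table)
        for row in table.itertuples():
            assert integration.CLUSTER_TABLE[(row.prom_direction, row.expr_direction)] == row.cluster


class TestGenebodyContrast:
    def test_body_mean_arithmetic(self):
        genes = [GeneModel("g", "chr1", "+", 10_000, 10_000, 30_000)]
        dmcs = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "pos": [15_000, 20_000],  # inside body, outside promoter
                "delta": [-0.2, -0.4],
            }
        )
        res = integration.genebody_promoter_contrast(dmcs, genes, {"g": "C1"})
        assert res["per_gene"]["body_mean_delta"].iloc[0] == pytest.approx(-0.3)

    def test_designed_c1_c3_contrast(self, default_study):
        from methylscape import dmc

        filtered = dmc.filter_matrix(default_study["methylome"])
        calls = dmc.call_dmcs(filtered)
        truth = default_study["manifest"].gene["cluster"]
        clusters = truth[truth.isin(["C1", "C3"])].to_dict()
        res = integration.genebody_promoter_contrast(
            calls, default_study["genome"].genes, clusters
        )
        assert res["cluster_summary"].loc["C1", ("prom_mean_delta", "mean")] > 0
        assert res["cluster_summary"].loc["C3", ("prom_mean_delta", "mean")] > 0


class TestCoexpression:
    def test_duplicated_target_attains_r_one(self, rng):
        vals = rng.random((10, 8)) * 50
        vals[3] = vals[0]  # duplicate of g0
        e = _expr(vals[:, :4], vals[:, 4:])
        out = integration.coexpression_null(e, "g0", n_perm=200, seed=1)
        assert "g3" in set(out["gene_id"])
        r3 = out.set_index("gene_id").loc["g3", "r"]
        assert r3 == pytest.approx(1.0)

    def test_independent_noise_yields_alpha_level_hits(self, rng):
        vals = rng.random((200, 10)) * 100
        e = _expr(vals[:, :5], vals[:, 5:])
        out = integration.coexpression_null(e, "g0", n_perm=300, alpha=0.01, seed=3)
        # target correlates perfectly with itself; few others survive BH
        assert len(out) <= 1 + 0.05 * 200

    def test_seed_determinism(self, rng):
        vals = rng.random((30, 8)) * 10
        e = _expr(vals[:, :4], vals[:, 4:])
        a = integration.coexpression_null(e, "g1", n_perm=100, seed=9)
        b = integration.coexpression_null(e, "g1", n_perm=100, seed=9)
        pd.testing.assert_frame_equal(a, b)


def _efron_partial_loglik(beta, time, event, x):
    """Reference Efron partial log-likelihood for one covariate."""
    ll = 0.0
    for t in np.unique(time[event == 1]):
        d_set = (time == t) & (event == 1)
        risk = time >= t
        d = d_set.sum()
        theta_risk = np.exp(beta * x[risk]).sum()
        theta_tie = np.exp(beta * x[d_set]).sum()
        ll += beta * x[d_set].sum()
        for el in range(d):
            ll -= np.log(theta_risk - el / d * theta_tie)
    return ll


class TestCox:
    def test_median_split(self):
        surv = SurvivalTable(
            data=pd.DataFrame(
                {
                    "patient_id": ["a", "b", "c", "d"],
                    "time_days": [10.0, 20.0, 30.0, 40.0],
                    "event": [1, 1, 0, 1],
                }
            )
        )
        var = pd.Series([1.0, 2.0, 3.0, 4.0], index=["a", "b", "c", "d"])
        out = integration.stratify_by_variance(var, surv)
        assert list(out.data["var_group"]) == [0, 0, 1, 1]

    def test_identical_groups_ci_covers_one(self, rng):
        n = 60
        t = rng.exponential(100, n)
        surv = SurvivalTable(
            data=pd.DataFrame(
                {
                    "patient_id": [f"p{i}" for i in range(n)],
                    "time_days": t,
                    "event": np.ones(n, int),
                    "var_group": rng.integers(0, 2, n),
                }
            )
        )
        fit = integration.fit_cox(surv, ["var_group"])
        assert fit["ci_low"] <= 1.0 <= fit["ci_high"]

    def test_toy_fit_matches_grid_search_oracle(self):
        time = np.array([5.0, 8.0, 12.0, 20.0, 25.0, 30.0])
        event = np.array([1, 1, 1, 1, 0, 1])
        x = np.array([1.0, 1.0, 0.0, 1.0, 0.0, 0.0])
        surv = SurvivalTable(
            data=pd.DataFrame(
                {
                    "patient_id": [f"p{i}" for i in range(6)],
                    "time_days": time,
                    "event": event,
                    "var_group": x,
                }
            )
        )
        fit = integration.fit_cox(surv, ["var_group"])
        betas = np.arange(-3.0, 3.0, 1e-4)
        lls = [_efron_partial_loglik(b, time, event, x) for b in betas]
        hr_oracle = np.exp(betas[int(np.argmax(lls))])
        assert fit["hr"] == pytest.approx(hr_oracle, abs=1e-3)
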
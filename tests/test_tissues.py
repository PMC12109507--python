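import numpy as np
import pandas as pd
import pytest
from scipy import stats

import omixmap as om
from conftest import make_spec


def stats_table(p, m=10, genes=None):
    genes = genes or [f"g{i}" for i in range(len(p))]
    return pd.DataFrame({"gene": genes, "m": m,
                         "m_eff": 2.0, "statistic": 1.0, "p": p})


class TestEnrichmentTopk:
    def test_matches_hand_welch_t(self):
        # 2 genes in the top-k set, 4 outside; one-sided Welch oracle
        z_in = np.array([3.0, 2.5])
        z_out = np.array([0.5, -0.5, 0.2, -0.2])
        p = stats.norm.sf(np.concatenate([z_in, z_out]))
        spec = make_spec(np.column_stack([[9, 8, 1, 2, 3, 4],
                                          [1, 2, 9, 8, 3, 4]]))
        res = om.enrichment_topk(stats_table(p), spec, k=2).set_index(
            "tissue")
        # hand Welch: t = (m1-m2)/sqrt(s1^2/n1 + s2^2/n2), Welch-Satterthwaite df
        n1, n2 = 2, 4
        v1, v2 = z_in.var(ddof=1), z_out.var(ddof=1)
        t = (z_in.mean() - z_out.mean()) / np.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        assert res.loc["t0", "p"] == pytest.approx(stats.t.sf(t, df),
                                                   rel=1e-6)

    def test_type_i_error_under_exchangeability(self):
        rng = np.random.default_rng(0)
        hits = 0
        reps = 400
        for _ in range(reps):
            p = rng.uniform(size=300)
            spec = make_spec(rng.normal(size=(300, 1)))
            res = om.enrichment_topk(stats_table(p), spec, k=60)
            hits += res["p"].iloc[0] < 0.05
        assert hits / reps == pytest.approx(0.05, abs=0.02)

    def test_k_bounds_enforced(self):
        spec = make_spec(np.random.default_rng(1).normal(size=(200, 2)))
        with pytest.raises(ValueError, match="k="):
            om.enrichment_topk(stats_table(np.full(200, 0.5)), spec, k=200)

    def test_disease_tissue_most_enriched(self, small_scenario, small_spec):
        res = om.enrichment_topk(small_scenario["gene_stats"],
                                 small_spec["rna"], k=60)
        assert res.iloc[0]["tissue"] == small_scenario["truth"].disease_tissue


class TestGenePropertyRegression:
    def test_matches_hand_ols(self):
        # 6 observations, closed-form OLS with intercept + log m covariate
        zg = np.array([1.0, 2.0, 0.5, 1.5, 0.2, 2.2])
        x = np.array([0.3, 1.1, -0.2, 0.8, -0.5, 1.4])
        m = np.array([5, 10, 20, 10, 5, 10])
        p_in = stats.norm.sf(zg)
        spec = make_spec(x[:, None])
        res = om.gene_property_regression(stats_table(p_in, m=m), spec)
        X = np.column_stack([np.ones(6), x, np.log(m)])
        beta = np.linalg.solve(X.T @ X, X.T @ zg)
        resid = zg - X @ beta
        s2 = resid @ resid / (6 - 3)
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        t_hand = beta[1] / se
        assert res["p"].iloc[0] == pytest.approx(stats.t.sf(t_hand, 3),
                                                 abs=1e-6)

    def test_null_type_i_error(self):
        rng = np.random.default_rng(2)
        hits = 0
        reps = 400
        for _ in range(reps):
            p = rng.uniform(size=250)
            spec = make_spec(rng.normal(size=(250, 1)))
            res = om.gene_property_regression(stats_table(p), spec)
            hits += res["p"].iloc[0] < 0.05
        assert hits / reps == pytest.approx(0.05, abs=0.02)

    def test_detects_injected_relation(self):
        # Z_g = 0.3 * specificity + noise: the one-sided coefficient test
        # should reject the null in nearly every replicate at this n
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(60):
            x = rng.normal(size=400)
            zg = 0.3 * x + rng.normal(size=400)
            p = stats.norm.sf(zg).clip(1e-12, 1.0)
            res = om.gene_property_regression(stats_table(p), make_spec(
                x[:, None]))
            hits += res["p"].iloc[0] < 0.05
        assert hits >= 54  # >= 90% power

    def test_zero_variance_specificity_gives_p_one(self):
        spec = make_spec(np.zeros((150, 1)))
        res = om.gene_property_regression(
            stats_table(np.random.default_rng(4).uniform(size=150)), spec)
        assert res["p"].iloc[0] == 1.0


class TestSpecificityRankTest:
    def test_exact_small_sample_oracle(self):
        # {4,5,6} vs {1,2,3}: only 1 of C(6,3)=20 assignments is as extreme
        spec = make_spec(np.array([[4.0], [5.0], [6.0], [1.0], [2.0], [3.0]]),
                         genes=list("abcdef"))
        res = om.specificity_rank_test(["a", "b", "c"], spec)
        assert res["p"].iloc[0] == pytest.approx(1 / 20)

    def test_empty_significant_set_warns_all_one(self):
        spec = make_spec(np.random.default_rng(5).normal(size=(30, 3)))
        res = om.specificity_rank_test([], spec)
        assert (res["p"] == 1.0).all()

    def test_random_gene_sets_give_uniformish_p(self):
        rng = np.random.default_rng(6)
        ps = []
        spec = make_spec(rng.normal(size=(200, 1)))
        for _ in range(300):
            sig = rng.choice(spec.z.index, 20, replace=False)
            ps.append(om.specificity_rank_test(sig, spec)["p"].iloc[0])
        assert (np.array(ps) < 0.05).mean() == pytest.approx(0.05, abs=0.03)

    def test_disease_tissue_top_ranked(self, small_scenario, small_spec):
        truth = small_scenario["truth"]
        res = om.specificity_rank_test(sorted(truth.causal_genes),
                                       small_spec["rna"])
        assert res.iloc[0]["tissue"] == truth.disease_tissue


class TestCombineMeanRank:
    def mk(self, method, order, ps=None):
        ps = ps or np.linspace(0.01, 0.5, len(order))
        df = pd.DataFrame({"tissue": order, "p": ps})
        df["method"] = method
        df["rank"] = stats.rankdata(df["p"])
        return df

    def test_identical_rankings_idempotent(self):
        dfs = [self.mk(m, ["a", "b", "c"]) for m in ("x", "y", "z")]
        comb = om.combine_mean_rank(dfs)
        assert list(comb["tissue"]) == ["a", "b", "c"]

    def test_hand_mean_ranks(self):
        # ranks A,B,C = (1,2,3), (2,1,3), (3,2,1) -> means (2, 1.67, 2.33)
        a = self.mk("m1", ["A", "B", "C"], [0.01, 0.02, 0.03])
        b = self.mk("m2", ["A", "B", "C"], [0.02, 0.01, 0.03])
        c = self.mk("m3", ["A", "B", "C"], [0.03, 0.02, 0.01])
        comb = om.combine_mean_rank([a, b, c]).set_index("tissue")
        assert comb.loc["A", "combined_mean_rank"] == pytest.approx(2.0)
        assert comb.loc["B", "combined_mean_rank"] == pytest.approx(5 / 3)
        assert comb.loc["C", "combined_mean_rank"] == pytest.approx(7 / 3)
        assert list(comb.index) == ["B", "A", "C"]

    def test_single_method_degenerate(self):
        a = self.mk("only", ["x", "y"], [0.2, 0.1])
        comb = om.combine_mean_rank([a])
        assert list(comb["tissue"]) == ["y", "x"]

    def test_mismatched_tissue_sets_rejected(self):
        a = self.mk("m1", ["x", "y"])
        b = self.mk("m2", ["x", "z"])
        with pytest.raises(ValueError, match="different tissue sets"):
            om.combine_mean_rank([a, b])


def test_bonferroni_reporting_threshold():
    assert om.bonferroni_threshold(32) == 0.05 / 32


def test_methods_invariant_to_tissue_column_order():
    rng = np.random.default_rng(13)
    p = rng.uniform(size=200)
    tab = stats_table(p)
    z = rng.normal(size=(200, 4))
    spec = make_spec(z, tissues=list("abcd"))
    perm = om.SpecificityMatrix(z=spec.z[["c", "a", "d", "b"]],
                                layer=spec.layer)
    sig = list(spec.z.index[:20])
    for fn, kwargs in [(om.enrichment_topk, {"k": 50}),
                       (om.gene_property_regression, {})]:
        a = fn(tab, spec, **kwargs).set_index("tissue")["p"]
        b = fn(tab, perm, **kwargs).set_index("tissue")["p"]
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index())
    a = om.specificity_rank_test(sig, spec).set_index("tissue")["p"]
    b = om.specificity_rank_test(sig, perm).set_index("tissue")["p"]
    pd.testing.assert_series_equal(a.sort_index(), b.sort_index())
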
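import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import omixmap as om
from omixmap.finemap import FineMapResult, bh_fdr
from conftest import make_spec


def bh_oracle(p):
    """Brute-force step-up: q_i = min_{j >= i} p_(j) * m / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, p[order[i]] * m / (i + 1))
        q[order[i]] = running
    return q


class TestBhFdr:
    def test_single_p_is_itself(self):
        assert bh_fdr([0.037])[0] == pytest.approx(0.037)

    def test_worked_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert (bh_fdr([1.0, 1.0, 1.0]) == 1.0).all()

    def test_empty(self):
        assert len(bh_fdr([])) == 0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 0.0])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1,
                    max_size=40))
    def test_agrees_with_brute_force_oracle(self, p):
        np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), rtol=1e-10)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


def fm_result(genes, p_cond, q=None, strategy="rna", p_uncond=None):
    p_cond = np.asarray(p_cond, float)
    q = bh_fdr(p_cond) if q is None else np.asarray(q, float)
    table = pd.DataFrame({
        "p_uncond": p_uncond if p_uncond is not None else p_cond,
        "p_cond": p_cond, "q": q, "selected": q < 0.05,
        "priority": 0.0}, index=pd.Index(genes, name="gene"))
    return FineMapResult(table=table, strategy=strategy)


class TestIntegration:
    def test_equal_inputs_return_themselves(self):
        res = om.integrate_pvalues(fm_result(["a", "b"], [0.2, 0.01]),
                                   fm_result(["a", "b"], [0.2, 0.01],
                                             strategy="protein"))
        np.testing.assert_allclose(res.table["p_integrated"], [0.2, 0.01])

    def test_worked_geometric_mean(self):
        res = om.integrate_pvalues(fm_result(["g"], [0.04]),
                                   fm_result(["g"], [0.09]))
        assert res.table["p_integrated"].iloc[0] == pytest.approx(0.06)

    def test_printed_protein_rna_pair(self):
        # P(Protein) = 7.93e-5 and P(RNA) = 0.054 integrate to ~2.07e-3
        res = om.integrate_pvalues(fm_result(["CREB1"], [0.054]),
                                   fm_result(["CREB1"], [7.93e-5]))
        assert res.table["p_integrated"].iloc[0] == pytest.approx(2.07e-3,
                                                                  rel=0.01)

    def test_missing_gene_contributes_p_one(self):
        res = om.integrate_pvalues(fm_result(["a", "c"], [0.04, 0.5]),
                                   fm_result(["b", "c"], [0.09, 0.5]))
        tab = res.table
        assert tab.loc["a", "p_integrated"] == pytest.approx(np.sqrt(0.04))
        assert tab.loc["b", "p_integrated"] == pytest.approx(np.sqrt(0.09))

    def test_disjoint_gene_sets_rejected(self):
        with pytest.raises(ValueError, match="no genes"):
            om.integrate_pvalues(fm_result(["a"], [0.5]),
                                 fm_result(["b"], [0.5]))

    def test_geometric_mean_bounded_by_inputs(self):
        rng = np.random.default_rng(1)
        pa, pb = rng.uniform(size=50), rng.uniform(size=50)
        genes = [f"g{i}" for i in range(50)]
        res = om.integrate_pvalues(fm_result(genes, pa),
                                   fm_result(genes, pb))
        lo = np.minimum(pa, pb)
        hi = np.maximum(pa, pb)
        pi = res.table["p_integrated"].to_numpy()
        assert ((lo <= pi + 1e-15) & (pi <= hi + 1e-15)).all()


class TestFinemap:
    def test_null_data_selects_nothing_and_keeps_p(self, small_cfg):
        truth = om.null_truth(small_cfg)
        ann = om.make_annotation(small_cfg)
        gwas, ld = om.generate_gwas(small_cfg, truth, ann)
        mapping = om.map_snps_to_genes(gwas, ann)
        gs = om.gene_statistics(gwas, ld, mapping)
        res = om.finemap(gs, gwas, ld, mapping)
        if not res.selected_genes:  # typical seed: nothing passes FDR
            pd.testing.assert_series_equal(res.table["p_cond"],
                                           res.table["p_uncond"],
                                           check_names=False)

    def test_two_gene_shared_signal(self):
        """Two genes sharing one causal signal through LD r = 0.95: the
        expression-guided mode keeps the tissue-specific gene and conditions
        the other to non-significance; the p-value mode keeps the smaller-p
        gene."""
        r = 0.95
        R = np.array([[1.0, r], [r, 1.0]])
        z = np.array([6.0, 5.7])
        blocks = om.LdBlocks(blocks=[om.LdBlock(snps=["s1", "s2"], R=R)])
        table = pd.DataFrame({
            "snp": ["s1", "s2"], "chromosome": ["1", "1"],
            "position": [1000, 2000], "a1": "A", "a2": "G", "z": z,
            "p": 2 * __import__("scipy").stats.norm.sf(np.abs(z)),
            "n": 1000})
        gwas = om.GwasSummary(table=table)
        mapping = {"X": ["s1"], "Y": ["s2"]}
        gs = om.gene_statistics(gwas, blocks, mapping)
        # X is specific in the disease tissue, Y is not; 10 filler genes
        rng = np.random.default_rng(2)
        zmat = rng.normal(size=(12, 3)) * 0.1
        genes = ["X", "Y"] + [f"f{i}" for i in range(10)]
        zmat[0, 0] = 5.0
        zmat[1, 0] = 0.0
        spec = make_spec(zmat, genes=genes)
        guided = om.finemap(gs, gwas, blocks, mapping, spec=spec,
                            tail="auto")
        assert guided.selected_genes == ["X"]
        assert guided.table.loc["Y", "q"] >= 0.05
        plain = om.finemap(gs, gwas, blocks, mapping)
        assert plain.selected_genes == ["X"]  # smaller unconditional p

    def test_selection_respects_cap_and_fdr(self, small_scenario,
                                            small_spec):
        gs = small_scenario["gene_stats"]
        res = om.finemap(gs, small_scenario["gwas"], small_scenario["ld"],
                         small_scenario["mapping"], spec=small_spec["rna"],
                         max_genes=5)
        assert len(res.selected_genes) <= 5
        assert (res.table.loc[res.selected_genes, "q"] < 0.05).all()

    def test_estimates_disease_tissue(self, small_scenario, small_spec):
        res = om.finemap(small_scenario["gene_stats"],
                         small_scenario["gwas"], small_scenario["ld"],
                         small_scenario["mapping"], spec=small_spec["rna"])
        assert res.disease_tissue == small_scenario["truth"].disease_tissue
        assert res.converged

    def test_pvalue_mode_deterministic(self, small_scenario):
        kw = dict(gwas=small_scenario["gwas"], ld=small_scenario["ld"],
                  mapping=small_scenario["mapping"])
        a = om.finemap(small_scenario["gene_stats"], **kw)
        b = om.finemap(small_scenario["gene_stats"], **kw)
        pd.testing.assert_frame_equal(a.table, b.table)


class TestProteinSpecific:
    def ranks(self, genes, vals, layer):
        return om.NormalizedRankMatrix(
            r=pd.DataFrame({"cortex": vals}, index=pd.Index(genes)),
            layer=layer)

    def test_identical_results_empty_table(self):
        res = fm_result(["a", "b"], [0.001, 0.5])
        tab = om.protein_specific_genes(
            res, res, self.ranks(["a", "b"], [0.9, 0.1], "protein"),
            self.ranks(["a", "b"], [0.2, 0.3], "rna"), "cortex")
        assert tab.empty

    def test_inclusion_criteria(self):
        prot = fm_result(["a", "b"], [0.001, 0.001], q=[0.01, 0.01])
        rna = fm_result(["a", "b"], [0.2, 0.01], q=[0.30, 0.04])
        tab = om.protein_specific_genes(
            prot, rna, self.ranks(["a", "b"], [0.9, 0.8], "protein"),
            self.ranks(["a", "b"], [0.1, 0.2], "rna"), "cortex")
        assert list(tab["gene"]) == ["a"]  # b significant in RNA: excluded
        assert tab["rank_protein"].iloc[0] == 0.9
        assert tab["rank_rna"].iloc[0] == 0.1

    def test_unknown_tissue_rejected(self):
        res = fm_result(["a"], [0.001])
        with pytest.raises(ValueError, match="absent"):
            om.protein_specific_genes(
                res, res, self.ranks(["a"], [0.9], "protein"),
                self.ranks(["a"], [0.1], "rna"), "liver")


class TestOverlap:
    def test_identical_sets(self):
        out = om.overlap_summary({"a": {"x", "y"}, "b": {"x", "y"}})
        d = out.set_index("region")["count"]
        assert d["a&b"] == 2 and d["a"] == 0 and d["b"] == 0

    def test_disjoint_sets(self):
        out = om.overlap_summary({"a": {"x"}, "b": {"y"}})
        d = out.set_index("region")["count"]
        assert d["a&b"] == 0 and d["a"] == 1 and d["b"] == 1

    def test_three_way_enumeration_oracle(self):
        sets = {"A": {"a", "b", "c"}, "B": {"b", "c", "d"}, "C": {"c", "e"}}
        out = om.overlap_summary(sets).set_index("region")["count"]
        universe = set().union(*sets.values())
        # brute-force membership-pattern enumeration
        from collections import Counter
        pattern = Counter()
        for g in universe:
            key = "&".join(sorted(k for k, s in sets.items() if g in s))
            pattern[key] += 1
        for region, count in out.items():
            assert count == pattern.get(region, 0)

    def test_needs_two_strategies(self):
        with pytest.raises(ValueError):
            om.overlap_summary({"a": {"x"}})
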
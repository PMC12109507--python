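"""Tissue-specificity Z-scores and RNA/protein cross-layer correlation.

Generates a small paired RNA/protein expression study, computes
robust-regression specificity Z-scores per tissue, and reports how well the
two omics layers agree tissue by tissue.
"""

import omixmap as om

cfg = om.SimConfig(n_genes=800, n_tissues=10, n_causal=20, n_discordant=4,
                   seed=42)
truth = om.make_truth(cfg)
rna, prot = om.generate_expression(cfg, truth)

spec_rna = om.rez_zscores(rna)
spec_prot = om.rez_zscores(prot)

corr = om.tissue_correlations(spec_prot)
print("protein-layer tissue-tissue Spearman (first 4 tissues):")
print(corr.iloc[:4, :4].round(2))
print("# off-diagonal entries near 0: tissue-specific residual expression "
      "is largely independent between unrelated tissues\n")

cl = om.cross_layer_correlations(spec_rna, spec_prot, n_boot=500, seed=0)
print(f"mean per-tissue RNA-vs-protein Spearman: {cl.mean:.3f} "
      f"(95% CI {cl.ci_low:.3f}-{cl.ci_high:.3f}, {cl.n_genes} genes)")
print("# the generator calibrates this moderate agreement (~0.46): protein "
      "specificity tracks RNA specificity only partially, which is why the "
      "two layers find different disease genes")

ranks = om.normalized_ranks(spec_rna)
top = ranks.r[truth.disease_tissue].nlargest(3)
print(f"\nmost {truth.disease_tissue}-specific genes (normalized rank, "
      "1.0 = most specific):")
for gene, r in top.items():
    flag = "causal" if gene in truth.causal_genes else "background"
    print(f"  {gene}: {r:.3f} ({flag})")
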
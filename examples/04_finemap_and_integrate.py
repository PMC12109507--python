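"""Conditional gene fine-mapping under four strategies.

Runs the greedy conditional selection guided by p-values alone, by RNA
specificity, and by protein specificity, integrates the two omics-guided
results by the geometric mean of their conditional p-values, and reports
the protein-specific genes (significant at the protein layer only) with
their normalized specificity ranks.
"""

import omixmap as om

cfg = om.SimConfig(n_genes=900, n_tissues=10, n_causal=25, n_discordant=5,
                   seed=5)
truth = om.make_truth(cfg)
rna, prot = om.generate_expression(cfg, truth)
spec_rna, spec_prot = om.rez_zscores(rna), om.rez_zscores(prot)
annotation = om.make_annotation(cfg)
gwas, ld = om.generate_gwas(cfg, truth, annotation)
mapping = om.map_snps_to_genes(gwas, annotation)
stats = om.gene_statistics(gwas, ld, mapping)

res_p = om.finemap(stats, gwas, ld, mapping)
res_rna = om.finemap(stats, gwas, ld, mapping, spec=spec_rna)
res_prot = om.finemap(stats, gwas, ld, mapping, spec=spec_prot)
integ = om.integrate_pvalues(res_rna, res_prot)

for name, res in [("p-value", res_p), ("RNA", res_rna),
                  ("protein", res_prot), ("RNA+protein", integ)]:
    sel = res.selected_genes
    hits = len(set(sel) & truth.causal_genes)
    print(f"{name:>12}: {len(sel)} genes selected at FDR < 0.05, "
          f"{hits} truly causal")

overlap = om.overlap_summary({"pvalue": res_p, "rna": res_rna,
                              "protein": res_prot})
core = overlap.set_index("region").loc["protein&pvalue&rna", "count"]
print(f"\ngenes found by all three strategies: {core} "
      "(strategies agree on unambiguous loci and differ where LD or "
      "expression discordance intervenes)")

table = om.protein_specific_genes(res_prot, res_rna,
                                  om.normalized_ranks(spec_prot),
                                  om.normalized_ranks(spec_rna),
                                  truth.disease_tissue)
print(f"\nprotein-specific genes in {truth.disease_tissue} "
      "(protein FDR < 0.05, RNA FDR >= 0.05):")
cols = ["gene", "p_protein", "p_rna", "rank_protein", "rank_rna"]
print(table[cols].head(6).round(3).to_string(index=False))
print("# high protein rank with low RNA rank marks genes an RNA-only "
      "analysis would miss")
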
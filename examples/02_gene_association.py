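"""LD-aware gene-level association tests from GWAS summary statistics.

Simulates LD-structured z-scores with known causal genes, pools each gene's
SNP chi-squares with an effective-test correction for LD, and shows that the
smallest gene p-values concentrate at (or next to) the causal genes.
"""

import omixmap as om

cfg = om.SimConfig(n_genes=600, n_tissues=8, n_causal=10, n_discordant=0,
                   seed=7)
truth = om.make_truth(cfg)
annotation = om.make_annotation(cfg)
gwas, ld = om.generate_gwas(cfg, truth, annotation)

mapping = om.map_snps_to_genes(gwas, annotation, window_kb=10)
stats = om.gene_statistics(gwas, ld, mapping)

print(f"{len(gwas.table)} SNPs mapped to {len(mapping)} genes "
      f"({cfg.n_snps_per_gene} SNPs per gene)")
top = stats.nsmallest(8, "p")
print("\nsmallest gene p-values (m_eff = effective number of independent "
      "SNPs under LD):")
for _, row in top.iterrows():
    flag = "CAUSAL" if row["gene"] in truth.causal_genes else "neighbour"
    print(f"  {row['gene']}: p={row['p']:.2e}  m={row['m']}  "
          f"m_eff={row['m_eff']:.2f}  ({flag})")
print("# neighbours of causal genes inherit signal through LD — the "
      "gene-level ambiguity that conditional fine-mapping resolves")

hit = sorted(truth.causal_genes)[0]
n_sig = (stats["p"] < 0.05 / len(stats)).sum()
print(f"\n{n_sig} genes pass the Bonferroni line 0.05/{len(stats)}; "
      f"true causal count is {cfg.n_causal} (gene {hit} et al.)")
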
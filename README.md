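# omixmap

Multi-omics expression-guided mapping of disease-associated tissues and
genes from GWAS summary statistics.

## The problem

Genome-wide association studies localise disease risk to loci, not to genes:
linkage disequilibrium (LD) spreads a causal variant's signal across every
gene in its neighbourhood, and the gene with the smallest association
p-value at a locus is frequently not the causal one. Tissue-specific
expression offers an independent arbiter — causal genes tend to be
specifically expressed in the tissue the disease acts through — and protein
abundance, being closer to function than RNA, captures cases that RNA-based
prioritisation misses (genes with post-transcriptional regulation show high
protein but low RNA tissue specificity). `omixmap` implements this
integrative analysis end to end for researchers who have GWAS summary
statistics and paired gene × tissue expression profiles (protein and/or
RNA), plus a fully specified synthetic-data generator for method evaluation.

## The model

**Tissue specificity.** For tissue *t*, the log expression vector
*y<sub>t</sub>* (over genes) is regressed on the per-gene mean of the other
tissues by a Huber M-estimate (tuning 1.345, IRLS); the specificity Z-score
is the residual standardised by the normalised MAD,
*Z<sub>g,t</sub>* = *r<sub>g,t</sub>* / MAD(*r<sub>·,t</sub>*). Housekeeping
genes sit on the regression line; tissue-enriched genes populate the upper
residual tail. The normalised rank
*r<sub>g,t</sub>* = rank(*Z<sub>g,t</sub>*)/*N* (ascending; 1.0 = most
specific) makes specificity comparable between omics layers.

**Gene-level association.** A gene's statistic pools its SNPs' squared
z-scores. Under the null, Σ*z*² for *z* ~ MVN(0, R) is distributed as
Σλ<sub>i</sub>χ²₁ with λ the eigenvalues of the SNP correlation matrix R;
the package evaluates this tail essentially exactly (Imhof quadrature, Ruben
series for batches, Kuonen saddlepoint in the far tail) and reports the
effective test count m<sub>eff</sub> = (Σλ)²/Σλ². Conditional statistics
residualise a gene's z-scores on an already-selected SNP set through the
joint LD matrix.

**Disease tissues.** Three estimators — top-k tissue-specific gene-set
enrichment of gene association Z-scores (Welch t), gene-property regression
of association Z on specificity Z, and a Wilcoxon rank-sum test of
significant genes' specificity — are combined by the mean of their
per-tissue ranks.

**Fine-mapping and integration.** Genes are accepted greedily under a
Benjamini–Hochberg FDR threshold (default 0.05, at most 1000 genes), each
candidate conditioned on the SNPs of already-accepted genes within LD
reach. Candidates are ordered by unconditional p-value (plain conditional
testing) or by specificity Z in the currently estimated disease tissue
(expression-guided), iterating tissue estimation and selection to a fixed
point. RNA- and protein-guided conditional p-values are integrated per gene
as the geometric mean P<sub>integrated</sub> = √(P<sub>RNA</sub> ·
P<sub>Protein</sub>). Genes with protein q < 0.05 but RNA q ≥ 0.05 are
reported as protein-specific findings with their normalised ranks in the
disease tissue.

## Worked example

```python
import omixmap as om

cfg = om.SimConfig(seed=1)                  # 3000 genes, 20 tissues,
truth = om.make_truth(cfg)                  # 50 causal genes, 5 discordant
rna, prot = om.generate_expression(cfg, truth)
spec = om.rez_zscores(rna)
ann = om.make_annotation(cfg)
gwas, ld = om.generate_gwas(cfg, truth, ann)
mapping = om.map_snps_to_genes(gwas, ann, window_kb=10)
stats = om.gene_statistics(gwas, ld, mapping)
result = om.finemap(stats, gwas, ld, mapping, spec=spec)
print(result.disease_tissue, len(result.selected_genes))
```

prints `tissue_01 55`: the expression-guided conditional analysis
re-identifies the simulated disease tissue and selects 55 genes at
FDR < 0.05 (50 are truly causal; most LD neighbours are conditioned away).
The `examples/` directory walks through each capability — specificity and
cross-layer correlation, gene tests, tissue association, the four
fine-mapping strategies, and ROC evaluation. Running
`python examples/05_evaluate_strategies.py` ends with

```
mean AUC per strategy:
pvalue        0.9162
rna           0.9538
protein       0.9640
integrated    0.9872
paired two-tailed t-test, integrated vs p-value-guided: p = 0.0027
```

— the integrated RNA+protein strategy ranks causal genes best, both
expression-guided strategies beat p-value-only conditioning, and the
difference is significant across scenarios.

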
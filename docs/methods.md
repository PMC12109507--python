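# Methods

This note documents the statistical model behind `omixmap`, the design
choices that were genuinely open, what the synthetic-data generator does and
does not emulate, and the numerical decisions that affect results.

## Tissue-specificity Z-scores

Expression values are log-transformed (log2(x+1), configurable off) because
abundance data are heavy-tailed and a linear trend across tissues is only
plausible on the log scale. For each tissue the gene vector is regressed on
the per-gene mean of the remaining tissues with a Huber M-estimator
(tuning constant 1.345, iteratively reweighted least squares, at most 50
iterations, coefficient tolerance 1e-8, via statsmodels RLM); the
specificity Z is the residual divided by the normalised median absolute
deviation of the residuals. Robustness matters here: the genes we want to
detect (tissue-enriched ones) are exactly the outliers an ordinary
regression would let distort the trend line. A tissue whose values are
constant yields a zero Z column with a warning; a numerically exact fit
(residual MAD below 1e-12 of the data scale) likewise yields zeros rather
than float noise. Normalised ranks divide the ascending within-tissue rank
of Z by the gene count, with average ranks on ties — ties then preserve the
column mean (N+1)/(2N), and a tie-free column is exactly the grid
{1/N, …, 1}.

Cross-layer agreement is summarised as the per-tissue Spearman correlation
between RNA and protein Z-scores, with a percentile bootstrap (2000
resamples over genes) for the confidence interval of the mean.

## Gene-level association under LD

For SNP z-scores z ~ MVN(0, R) under the null, the pooled statistic Σz² is
distributed as Σλᵢχ²₁ with λ the eigenvalues of R. The reported statistic is
rescaled to the effective-test scale, S = (m_eff/m)·Σz² with
m_eff = (Σλ)²/Σλ², and m_eff accompanies every result as an interpretable
"number of independent SNPs". The p-value, however, is computed from the
exact null distribution of the quadratic form rather than from a
chi-squared(m_eff) tail. The moment-matched chi-squared is well calibrated
near α = 0.05 but anti-conservative by roughly an order of magnitude at the
p ≈ 1e-5 thresholds that Benjamini–Hochberg selection over thousands of
genes actually exercises; with it, the null pipeline would select false
genes in a third of runs. Three evaluation routes are used:

* **Imhof quadrature** (numerical inversion of the characteristic function)
  for single statistics in the distribution's bulk;
* **Ruben's series** — a chi-squared mixture expansion whose weights are
  cached per eigenvalue set — for batches of statistics sharing an LD
  structure (all genes of a simulation); a dense grid of the log-survival
  curve is cached and interpolated, so repeated replicates cost almost
  nothing;
* **Kuonen's saddlepoint** (Lugannani–Rice) in the far tail, where the
  oscillatory integral and the truncated series lose precision, and as the
  fast path for the many small conditional tests inside fine-mapping
  (relative error of a few percent, immaterial to selection decisions).

Degenerate structures short-circuit to closed forms and are exact: one SNP
(or perfect LD, a rank-one R) reduces to chi-squared with 1 df, R = I to
chi-squared with m df.

Conditional statistics residualise a gene's z-scores on a conditioning SNP
set A: z_B|A = (z_B − R_BA R_AA⁻¹ z_A)/√diag(R_BB − R_BA R_AA⁻¹ R_AB), with
the gene test applied to the residuals and their conditional correlation. A
ridge of 1e-4 stabilises R_AA⁻¹; SNPs whose conditional variance falls at or
below the ridge scale (< 1e-3) are treated as fully explained and dropped —
conditioning a gene on itself therefore returns p = 1. SNPs shared between
the candidate and the conditioning set are removed from the candidate
first. Collinear conditioning SNPs are dropped greedily with a warning when
R_AA is singular beyond the ridge.

## Disease-tissue association

Gene association strength enters as the probit transform Z_g = Φ⁻¹(1−p_g),
with p capped at 1e-300 to avoid infinities. The three methods are: (i)
one-sided Welch t-test of Z_g inside vs outside the tissue's top-k (default
1000) most specific genes — a gene-level proxy for heritability-enrichment
analyses on top-k tissue gene sets, and labelled as such; (ii) OLS of Z_g on
the tissue's specificity Z with an intercept and log SNP-count covariate,
one-sided on the specificity coefficient; (iii) one-sided Wilcoxon rank-sum
comparing significant genes' specificity against the rest (exact null for
combined n ≤ 20, normal approximation with continuity correction
otherwise). Tissues are ranked within each method (average ranks on ties)
and combined by the mean rank; ties in the combined rank break by the
Wilcoxon method's p, then by tissue name. The conventional reporting line
is Bonferroni, 0.05/T.

## Conditional fine-mapping and integration

Candidates are visited in priority order — ascending unconditional p
(tie-break: gene name) in the plain mode, descending specificity Z in the
current disease tissue in the expression-guided mode — and each candidate is
conditioned on the union of SNPs of already-accepted genes that share an LD
block or lie within 1 Mb (a bound on joint matrix size; configurable in
principle). A candidate is accepted while its current p-value passes the BH
cutoff of the evolving p-value vector, up to max_genes (default 1000; the
cap applies to accepted genes). In the expression-guided mode the disease
tissue is re-estimated from the selected genes with the Wilcoxon test and
the pass repeats until the selection is unchanged (at most 10 rounds;
exhaustion flags the result non-converged). The initial significant set
comes from BH on the unconditional p-values; when it is empty the first
pass falls back to p-value ordering. The guiding priority is the single
top-ranked tissue's specificity Z — the simplest faithful reading of
expression-guided conditioning; a multi-tissue weighting is isolated behind
the same ordering function should evidence favour it.

Integration takes the per-gene geometric mean of the RNA- and
protein-guided conditional p-values over the union of tested genes, a gene
absent from one layer contributing p = 1 there (conservative: integration
can only be driven by observed evidence); BH q-values are recomputed on the
integrated values. BH is applied within each strategy's candidate universe
separately. Protein-specific genes are those with protein q < 0.05 and RNA
q ≥ 0.05, reported with their normalised specificity ranks in the disease
tissue at both layers.

## Evaluation

Gene rankings are scored by −log10 of the conditional p (genes a strategy
never tested score 0, keeping universes aligned), AUC is the Mann–Whitney
identity with ties counting 1/2 (via scikit-learn, pinned in tests to a
pairwise enumeration oracle), and strategies are compared across scenarios
by paired two-tailed t-tests (identically zero differences return p = 1 by
convention). Literature labelling marks a gene positive when its
disease–gene co-mention count reaches 5; the PubMed client is a
network-optional adapter (stdlib urllib, disk cache storing the verbatim
query, ≥ 0.34 s between calls, failures become missing entries rather than
zeros) and never runs in offline analyses. Over-representation analysis is
a one-sided hypergeometric upper tail against a user-supplied background
with BH correction, labelled as BH in outputs.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, at
the study's default conditions: 20 tissues, 3000 genes, 10 SNPs per gene,
50 causal genes with 5 protein-high/RNA-low "discordant" genes, GWAS sample
size 10,000.

* **Expression.** Log-scale base expression per gene N(5, 2²) shared across
  tissues and layers plus independent N(0,1) tissue deviations. Causal genes
  gain +2.5 SD in the disease tissue at the RNA layer; the protein deviation
  is λ·RNA + (1−λ)·noise with λ calibrated by 1-D bisection against a
  Monte-Carlo estimate (fixed internal seed, tolerance 0.02) so the mean
  per-tissue cross-layer Spearman of the specificity Z-scores hits the
  target (default 0.46, the level reported for paired human tissue
  proteome/transcriptome data). Discordant genes model broken RNA→protein
  coupling: their RNA deviation in the disease tissue is forced to
  −(1+|e|) — the bottom decile, where real protein-specific findings'
  RNA ranks live — and their protein deviation is redrawn from fresh mixing
  noise plus the spike.
* **GWAS.** Genes lie in clusters of 3 per LD block on a synthetic
  chromosome (blocks 2 Mb apart; windows never overlap). Within a block the
  SNP correlation is AR(1) over SNP indices (adjacent r = 0.8) shrunk
  towards a block-wide shared factor of weight 0.9·0.8 = 0.72, so genes
  sharing a locus share association signal — the gene-level ambiguity of
  real GWAS loci. The factor weight was set against a structural target
  (the fraction of causal loci whose smallest-p gene is not the causal
  gene, ~20% here, approaching published gene-prioritisation ambiguity
  rates), not against any downstream metric. z-scores are drawn from
  MVN(R·a, R) per block, with a nonzero only at each causal gene's causal
  SNP: effect × √n, effects uniform in [0.055, 0.08] so lead z-scores span
  5.5–8 — loci at or beyond genome-wide significance, the regime
  fine-mapping actually operates in. Discordant genes carry the low end of
  that range and their causal SNP sits at the gene edge facing a
  neighbouring gene, guaranteeing a strong-LD partner that absorbs their
  signal once conditioned on.
* **Scenarios.** `make_scenarios(n)` produces n studies with distinct
  disease tissues and (with high probability) near-disjoint causal sets,
  seeded base.seed + i. Causal genes are sampled at most one per LD block,
  so every causal gene has non-causal LD neighbours.

What the generator does **not** emulate: minor-allele-frequency spectra and
per-SNP sample-size variation; overlapping gene windows and shared SNPs
between genes (real loci are messier — full signal absorption as seen in
real conditional analyses requires shared SNPs, which the non-overlapping
layout rules out); trans effects; sample overlap between omics layers;
batch structure in expression. Passing tests therefore demonstrate that the
pipeline's statistics are calibrated and that its comparative behaviour
(expression guidance > p-value guidance; integration > single layers;
protein-specific genes recoverable) emerges under the assumed structure —
not that the same effect sizes would be observed on real data.

## Problem sizes and determinism

All randomness flows from explicit seeds (SimConfig.seed; numpy
default_rng), and same-seed runs are byte-identical. The acceptance script
uses 50 replicates for tissue recovery, 100 for null FDR, 60 for discordant
recovery and 6 scenarios for the AUC comparison; the test suite uses the
larger replicate counts its statistical assertions are stated at (100/200/
100). These sizes put Monte-Carlo standard errors well inside the asserted
margins.

## Known limitations

* The exact quadratic-form tail assumes the LD matrix is the truth; with an
  estimated R from a small reference panel, additional noise would inflate
  the tails (no panel-size correction is applied).
* The expression-guided iteration can lock onto a self-consistent wrong
  tissue when the significant-gene set is small or heavily diluted by LD
  neighbours (visible in deliberately tiny simulations); at the default
  scale the true tissue is recovered in ≈100% of replicates.
* Allele harmonisation against the LD panel is id-based only; strand or
  allele-flip errors in real summary statistics are the user's
  responsibility (the gene test itself is sign-free, so flips affect only
  conditional analyses).
* AUC comparisons use the simulation's truth labels; with literature-count
  labels the evaluation inherits publication bias, which the package does
  not model.
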
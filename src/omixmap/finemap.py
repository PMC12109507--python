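"""Conditional fine-mapping of genes and multi-omics p-value integration.

Genes are selected greedily: candidates are visited in a priority order —
ascending unconditional p-value (the plain conditional gene-test mode), or
descending tissue-specificity Z in the currently estimated disease tissue
(the expression-guided mode) — and each candidate's statistic is conditioned
on the SNPs of already-accepted genes within LD reach.  A candidate is
accepted while its current p-value passes the Benjamini-Hochberg cutoff of
the evolving p-value vector, up to a cap on the number of selected genes.
In the expression-guided mode the disease tissue is re-estimated from the
selected genes (Wilcoxon specificity rank test) and the procedure repeats
until the selection stabilises.

RNA- and protein-guided results are integrated per gene as the geometric mean
of the two conditional p-values, sqrt(P_RNA * P_Protein) — a balanced
combination that cannot be dominated by a single extreme layer — with BH
q-values recomputed on the integrated values.  Genes significant on the
protein side (q < threshold) but not on the RNA side are reported as
protein-specific, annotated with their normalised specificity ranks in the
disease tissue at both layers.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .assoc import conditional_gene_pvalue
from .config import get_logger
from .io import GwasSummary, LdBlocks
from .specificity import NormalizedRankMatrix, SpecificityMatrix
from .tissues import specificity_rank_test

__all__ = ["FineMapResult", "IntegratedResult", "bh_fdr", "finemap",
           "integrate_pvalues", "protein_specific_genes", "overlap_summary"]

logger = get_logger(__name__)

REACH_BP = 1_000_000  # conditioning reach for genes not sharing an LD block


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone non-decreasing in p)."""
    p = np.asarray(list(p), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _bh_cutoff(p: np.ndarray, alpha: float) -> float:
    """Largest p(i) with p(i) <= i*alpha/m (0.0 when nothing passes)."""
    srt = np.sort(p)
    thresh = alpha * np.arange(1, p.size + 1) / p.size
    ok = np.nonzero(srt <= thresh)[0]
    return float(srt[ok[-1]]) if ok.size else 0.0


@dataclass
class FineMapResult:
    """Per-gene unconditional/conditional p, BH q and selection flag for one
    guiding strategy."""

    table: pd.DataFrame  # index gene: p_uncond, p_cond, q, selected, priority
    strategy: str
    disease_tissue: Optional[str] = None
    converged: bool = True
    n_iter: int = 1

    @property
    def selected_genes(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])


@dataclass
class IntegratedResult:
    """Geometric-mean integration of RNA- and protein-guided conditional
    p-values with recomputed BH q-values."""

    table: pd.DataFrame  # index gene: p_rna, p_protein, p_integrated, q,
    #                      selected
    fdr_threshold: float = 0.05

    @property
    def selected_genes(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])


class _GeneContext:
    """Precomputed per-gene SNP ids, z-scores, LD block ids and span."""

    def __init__(self, gwas: GwasSummary, ld: LdBlocks,
                 mapping: Mapping[str, Sequence[str]]):
        t = gwas.table
        self.zmap = dict(zip(t["snp"], t["z"].astype(float)))
        posmap = dict(zip(t["snp"], t["position"].astype(int)))
        chrommap = dict(zip(t["snp"], t["chromosome"].astype(str)))
        self.z = {}
        self.snps = {}
        self.blocks = {}
        self.span = {}
        for gene, snps in mapping.items():
            keep = [s for s in snps if s in ld and s in self.zmap]
            if not keep:
                continue
            self.snps[gene] = keep
            self.z[gene] = np.array([self.zmap[s] for s in keep])
            self.blocks[gene] = {ld.block_of(s) for s in keep}
            pos = [posmap[s] for s in keep]
            self.span[gene] = (chrommap[keep[0]], min(pos), max(pos))
        self.ld = ld

    def near(self, a: str, b: str) -> bool:
        if self.blocks[a] & self.blocks[b]:
            return True
        ca, lo_a, hi_a = self.span[a]
        cb, lo_b, hi_b = self.span[b]
        return ca == cb and (lo_b - hi_a <= REACH_BP and
                             lo_a - hi_b <= REACH_BP)

    def conditional_p(self, gene: str, conditioning: Iterable[str],
                      tail: str) -> float:
        a_snps: list[str] = []
        seen = set()
        for g in conditioning:
            for s in self.snps[g]:
                if s not in seen:
                    seen.add(s)
                    a_snps.append(s)
        b_snps = [s for s in self.snps[gene] if s not in seen]
        if not b_snps:
            return 1.0
        joint = self.ld.submatrix(b_snps + a_snps)
        nb = len(b_snps)
        z_b = np.array([self.zmap[s] for s in b_snps])
        z_a = np.array([self.zmap[s] for s in a_snps])
        stat = conditional_gene_pvalue(
            z_b, z_a, joint[:nb, :nb], joint[:nb, nb:], joint[nb:, nb:],
            gene=gene, method=tail)
        return stat.p


def _greedy_pass(order: list[str], ctx: _GeneContext, p_uncond: pd.Series,
                 fdr_threshold: float, max_genes: int, tail: str,
                 ) -> tuple[pd.Series, list[str]]:
    idx = {g: i for i, g in enumerate(p_uncond.index)}
    p_arr = p_uncond.to_numpy(dtype=float).copy()
    cutoff = _bh_cutoff(p_arr, fdr_threshold)
    accepted: list[str] = []
    by_block: dict[int, list[str]] = {}
    for gene in order:
        near = {a for b in ctx.blocks[gene] for a in by_block.get(b, [])}
        near |= {a for a in accepted if a not in near and ctx.near(a, gene)}
        if near:
            p_arr[idx[gene]] = ctx.conditional_p(gene, sorted(near), tail)
            cutoff = _bh_cutoff(p_arr, fdr_threshold)
        if cutoff > 0.0 and p_arr[idx[gene]] <= cutoff and \
                len(accepted) < max_genes:
            accepted.append(gene)
            for b in ctx.blocks[gene]:
                by_block.setdefault(b, []).append(gene)
    return pd.Series(p_arr, index=p_uncond.index), accepted


def finemap(gene_stats: pd.DataFrame, gwas: GwasSummary, ld: LdBlocks,
            mapping: Mapping[str, Sequence[str]],
            spec: Optional[SpecificityMatrix] = None, *,
            fdr_threshold: float = 0.05, max_genes: int = 1000,
            max_iter: int = 10, tail: str = "saddlepoint") -> FineMapResult:
    """Greedy conditional gene selection, p-value-guided (spec=None) or
    guided by tissue-specific expression (spec given).

    With a specificity matrix the procedure alternates between estimating the
    disease tissue from the currently selected genes and re-prioritising
    candidates by their specificity Z in that tissue, until the selected set
    is unchanged (at most ``max_iter`` rounds; the result is flagged
    non-converged if the loop is exhausted).
    """
    ctx = _GeneContext(gwas, ld, mapping)
    stats_tab = gene_stats.set_index("gene")
    genes = [g for g in stats_tab.index if g in ctx.snps]
    p_uncond = stats_tab.loc[genes, "p"].astype(float)
    strategy = "pvalue" if spec is None else spec.layer

    if spec is None:
        order = sorted(genes, key=lambda g: (p_uncond[g], g))
        p_vec, accepted = _greedy_pass(order, ctx, p_uncond, fdr_threshold,
                                       max_genes, tail)
        q = pd.Series(bh_fdr(p_vec), index=p_vec.index)
        selected = {g for g in accepted if q[g] < fdr_threshold}
        priority = -np.log10(p_uncond.clip(lower=1e-300))
        table = pd.DataFrame({
            "p_uncond": p_uncond, "p_cond": p_vec, "q": q,
            "selected": [g in selected for g in p_vec.index],
            "priority": priority})
        return FineMapResult(table=table, strategy=strategy)

    spec_genes = [g for g in genes if g in spec.z.index]
    if len(spec_genes) < len(genes):
        logger.info("finemap: %d genes lack specificity scores; they rank "
                    "after scored genes", len(genes) - len(spec_genes))
    q0 = pd.Series(bh_fdr(p_uncond), index=p_uncond.index)
    sig = set(p_uncond.index[q0 < fdr_threshold])
    prev_selection: Optional[set[str]] = None
    tissue: Optional[str] = None
    converged = False
    n_iter = 0
    p_vec, accepted = p_uncond.copy(), []
    for n_iter in range(1, max_iter + 1):
        if sig:
            tissue_p = specificity_rank_test(sig, spec)
            tissue = tissue_p.iloc[0]["tissue"]
            zt = spec.z[tissue]
            order = sorted(genes, key=lambda g:
                           (-zt.get(g, -np.inf), g))
        else:
            tissue = None
            order = sorted(genes, key=lambda g: (p_uncond[g], g))
        p_vec, accepted = _greedy_pass(order, ctx, p_uncond, fdr_threshold,
                                       max_genes, tail)
        q = pd.Series(bh_fdr(p_vec), index=p_vec.index)
        selection = {g for g in accepted if q[g] < fdr_threshold}
        if selection == prev_selection:
            converged = True
            break
        prev_selection = selection
        sig = selection
    q = pd.Series(bh_fdr(p_vec), index=p_vec.index)
    selected = {g for g in accepted if q[g] < fdr_threshold}
    if tissue is not None:
        priority = spec.z[tissue].reindex(p_vec.index)
    else:
        priority = -np.log10(p_uncond.clip(lower=1e-300))
    if not converged:
        logger.warning("finemap (%s): selection did not stabilise within %d "
                       "iterations", strategy, max_iter)
    table = pd.DataFrame({
        "p_uncond": p_uncond, "p_cond": p_vec, "q": q,
        "selected": [g in selected for g in p_vec.index],
        "priority": priority})
    return FineMapResult(table=table, strategy=strategy,
                         disease_tissue=tissue, converged=converged,
                         n_iter=n_iter)


def integrate_pvalues(res_rna: FineMapResult, res_prot: FineMapResult,
                      fdr_threshold: float = 0.05) -> IntegratedResult:
    """Per-gene geometric mean of the two layers' conditional p-values.

    The integrated universe is the union of both layers' gene sets; a gene
    absent from one layer contributes p = 1 there (non-significant by
    convention), so integration can only be driven by observed evidence.
    """
    genes = res_rna.table.index.union(res_prot.table.index)
    if len(res_rna.table.index.intersection(res_prot.table.index)) == 0:
        raise ValueError("RNA and protein results share no genes")
    p_rna = res_rna.table["p_cond"].reindex(genes).fillna(1.0)
    p_prot = res_prot.table["p_cond"].reindex(genes).fillna(1.0)
    p_int = np.sqrt(p_rna * p_prot)
    q = pd.Series(bh_fdr(p_int), index=genes)
    table = pd.DataFrame({"p_rna": p_rna, "p_protein": p_prot,
                          "p_integrated": p_int, "q": q,
                          "selected": q < fdr_threshold})
    return IntegratedResult(table=table, fdr_threshold=fdr_threshold)


def protein_specific_genes(res_prot: FineMapResult, res_rna: FineMapResult,
                           ranks_prot: NormalizedRankMatrix,
                           ranks_rna: NormalizedRankMatrix, tissue: str,
                           fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Genes significant in the protein-guided analysis but not the RNA one,
    annotated with their normalised specificity ranks in the disease tissue.
    """
    for ranks, label in ((ranks_prot, "protein"), (ranks_rna, "RNA")):
        if tissue not in ranks.r.columns:
            raise ValueError(f"tissue {tissue!r} absent from {label} rank "
                             "matrix")
    genes = res_prot.table.index.union(res_rna.table.index)
    q_prot = res_prot.table["q"].reindex(genes).fillna(1.0)
    q_rna = res_rna.table["q"].reindex(genes).fillna(1.0)
    keep = (q_prot < fdr_threshold) & (q_rna >= fdr_threshold)
    out = pd.DataFrame({
        "gene": genes[keep],
        "p_protein": res_prot.table["p_cond"].reindex(genes[keep]).to_numpy(),
        "q_protein": q_prot[keep].to_numpy(),
        "p_rna": res_rna.table["p_cond"].reindex(genes[keep]).fillna(1.0)
        .to_numpy(),
        "q_rna": q_rna[keep].to_numpy(),
        "rank_protein": ranks_prot.r[tissue].reindex(genes[keep]).to_numpy(),
        "rank_rna": ranks_rna.r[tissue].reindex(genes[keep]).to_numpy(),
    })
    return out.sort_values("p_protein").reset_index(drop=True)


def overlap_summary(results: Mapping[str, "FineMapResult | set"],
                    ) -> pd.DataFrame:
    """Counts of every exclusive intersection region among selected-gene
    sets (the regions of a Venn diagram)."""
    if len(results) < 2:
        raise ValueError("need at least 2 strategies to compare")
    sets = {name: set(r.selected_genes) if isinstance(r, FineMapResult)
            else set(r) for name, r in results.items()}
    names = sorted(sets)
    rows = []
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set().union(*(sets[n] for n in names
                                    if n not in combo), set())
            exclusive = inside - outside
            rows.append({"region": "&".join(combo),
                         "n_strategies": k, "count": len(exclusive)})
    return pd.DataFrame(rows)
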
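"""Disease-tissue association by three methods and their mean-rank combination.

The three estimators view the same question — in which tissue are the
GWAS-implicated genes specifically expressed? — through different statistics:

* ``enrichment_topk``: are gene-level association Z-scores higher inside the
  tissue's top-k most specific genes than outside (one-sided Welch t-test)?
  This is a gene-level stand-in for stratified heritability enrichment on
  top-k tissue-specific gene annotations, and is labelled as such in outputs.
* ``gene_property_regression``: ordinary least squares of gene association Z
  on the tissue's specificity Z with an intercept and a log SNP-count
  covariate, one-sided p on the specificity coefficient.
* ``specificity_rank_test``: one-sided Wilcoxon rank-sum comparing the
  specificity of significant genes against the rest (exact null when the
  combined sample is small).

Tissues are ranked within each method (rank 1 = smallest p) and the mean rank
across methods is the combined association metric.  The conventional
reporting line is the Bonferroni threshold 0.05 / T for T tissues.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .config import get_logger
from .specificity import SpecificityMatrix

__all__ = ["assoc_zscores", "enrichment_topk", "gene_property_regression",
           "specificity_rank_test", "combine_mean_rank",
           "bonferroni_threshold"]

logger = get_logger(__name__)

P_FLOOR = 1e-300  # probit cap to avoid infinities


def bonferroni_threshold(n_tissues: int, alpha: float = 0.05) -> float:
    return alpha / n_tissues


def assoc_zscores(gene_stats: pd.DataFrame) -> pd.Series:
    """Probit-transformed gene association strength, Z_g = probit(1 - p_g)."""
    p = gene_stats.set_index("gene")["p"].clip(lower=P_FLOOR)
    return pd.Series(stats.norm.isf(p), index=p.index, name="assoc_z")


def _align(gene_stats: pd.DataFrame, spec: SpecificityMatrix,
           ) -> tuple[pd.Series, pd.DataFrame]:
    zg = assoc_zscores(gene_stats)
    shared = zg.index.intersection(spec.z.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} genes shared between gene "
                         "statistics and specificity")
    if len(shared) < 100:
        logger.warning("tissue association on only %d shared genes; "
                       "estimates will be unstable", len(shared))
    return zg.loc[shared], spec.z.loc[shared]


def _finish(records: list[dict], method: str) -> pd.DataFrame:
    df = pd.DataFrame(records)
    df["method"] = method
    df["rank"] = stats.rankdata(df["p"], method="average")
    return df.sort_values("rank").reset_index(drop=True)


def enrichment_topk(gene_stats: pd.DataFrame, spec: SpecificityMatrix,
                    k: int = 1000) -> pd.DataFrame:
    """Top-k tissue-specific gene-set enrichment of association Z (one-sided
    Welch t-test, top-k vs remaining genes)."""
    zg, zspec = _align(gene_stats, spec)
    if k >= len(zg):
        raise ValueError(f"k={k} must be smaller than the shared gene count "
                         f"({len(zg)})")
    records = []
    for tissue in zspec.columns:
        top = zspec[tissue].nlargest(k).index
        inside = zg.loc[top]
        outside = zg.drop(top)
        t = stats.ttest_ind(inside, outside, equal_var=False,
                            alternative="greater")
        records.append({"tissue": tissue, "p": float(t.pvalue)})
    return _finish(records, "enrichment_topk")


def gene_property_regression(gene_stats: pd.DataFrame,
                             spec: SpecificityMatrix) -> pd.DataFrame:
    """Gene-property regression: OLS of association Z on tissue specificity
    with intercept and log SNP-count covariate; one-sided p for a positive
    specificity coefficient."""
    zg, zspec = _align(gene_stats, spec)
    log_m = np.log(gene_stats.set_index("gene").loc[zg.index, "m"]
                   .to_numpy(dtype=float))
    records = []
    y = zg.to_numpy()
    for tissue in zspec.columns:
        x = zspec[tissue].to_numpy()
        if np.ptp(x) == 0.0:
            logger.warning("gene_property_regression: zero variance in %s "
                           "specificity; p set to 1", tissue)
            records.append({"tissue": tissue, "p": 1.0})
            continue
        design = np.column_stack([np.ones_like(x), x, log_m])
        fit = sm.OLS(y, design).fit()
        t_stat = fit.tvalues[1]
        p = float(stats.t.sf(t_stat, fit.df_resid))
        records.append({"tissue": tissue, "p": p})
    return _finish(records, "gene_property")


def specificity_rank_test(sig_genes: Iterable[str], spec: SpecificityMatrix,
                          ) -> pd.DataFrame:
    """One-sided Wilcoxon rank-sum: do significant genes have higher
    specificity Z than the remaining genes?  Exact null when the combined
    sample size is <= 20, normal approximation with continuity correction
    otherwise."""
    sig = spec.z.index.intersection(pd.Index(list(sig_genes)))
    records = []
    if len(sig) == 0:
        logger.warning("specificity_rank_test: empty significant gene set; "
                       "all tissue p set to 1")
        records = [{"tissue": t, "p": 1.0} for t in spec.z.columns]
        return _finish(records, "specificity_rank")
    rest = spec.z.index.difference(sig)
    method = "exact" if len(sig) + len(rest) <= 20 else "asymptotic"
    for tissue in spec.z.columns:
        res = stats.mannwhitneyu(spec.z.loc[sig, tissue],
                                 spec.z.loc[rest, tissue],
                                 alternative="greater", method=method,
                                 use_continuity=True)
        records.append({"tissue": tissue, "p": float(res.pvalue)})
    return _finish(records, "specificity_rank")


def combine_mean_rank(results: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Mean of within-method tissue ranks (rank 1 = smallest p), sorted
    ascending; ties broken by the specificity_rank p when available, then by
    tissue name."""
    if not results:
        raise ValueError("no method results to combine")
    tissue_sets = [set(df["tissue"]) for df in results]
    if any(s != tissue_sets[0] for s in tissue_sets[1:]):
        union = set().union(*tissue_sets)
        missing = {i: sorted(union - s) for i, s in enumerate(tissue_sets)
                   if union - s}
        raise ValueError(f"methods cover different tissue sets; missing per "
                         f"method: {missing}")
    ranks = pd.DataFrame({df["method"].iloc[0]:
                          df.set_index("tissue")["rank"] for df in results})
    combined = ranks.mean(axis=1).rename("combined_mean_rank").to_frame()
    tie_break = None
    for df in results:
        if df["method"].iloc[0] == "specificity_rank":
            tie_break = df.set_index("tissue")["p"]
    combined["_tie"] = tie_break.reindex(combined.index) \
        if tie_break is not None else 1.0
    combined.index.name = "tissue"
    combined = combined.reset_index().sort_values(
        ["combined_mean_rank", "_tie", "tissue"], kind="stable")
    return combined.drop(columns="_tie").reset_index(drop=True)
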
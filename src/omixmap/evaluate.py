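"""Scoring of gene prioritisations and local over-representation analysis.

Gene rankings are scored by the area under the ROC curve against binary
labels (ground truth flags in simulation; literature co-mention counts for
real studies, positive when a gene-disease pair has at least 5 publications).
Strategies are compared across scenarios with a paired two-tailed t-test on
the per-scenario AUCs.  Over-representation of a query gene set in annotated
collections uses the one-sided hypergeometric upper tail with BH correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .config import get_logger
from .finemap import FineMapResult, IntegratedResult, bh_fdr

__all__ = ["roc_auc", "paired_ttest", "literature_labels", "ora_enrichment",
           "strategy_scores", "AucReport", "compare_strategies"]

logger = get_logger(__name__)


def strategy_scores(result: "FineMapResult | IntegratedResult",
                    universe: Sequence[str]) -> pd.Series:
    """-log10 conditional gene p-values over a common gene universe; genes a
    strategy never tested score -log10(1) = 0, keeping universes aligned."""
    col = "p_cond" if isinstance(result, FineMapResult) else "p_integrated"
    p = result.table[col].reindex(universe).fillna(1.0).clip(lower=1e-300)
    return pd.Series(-np.log10(p.to_numpy()), index=pd.Index(universe),
                     name="score")


def roc_auc(scores: pd.Series, labels: pd.Series) -> float:
    """AUC via the Mann-Whitney identity (ties count 1/2), computed over the
    genes present in both inputs."""
    shared = scores.index.intersection(labels.index)
    y = labels.loc[shared].astype(int)
    if y.nunique() < 2:
        raise ValueError("labels contain a single class; AUC undefined")
    return float(roc_auc_score(y.to_numpy(), scores.loc[shared].to_numpy()))


def paired_ttest(auc_a: Sequence[float], auc_b: Sequence[float]) -> float:
    """Two-tailed paired t-test p-value on per-scenario AUC differences;
    identically zero differences return p = 1 by convention."""
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need two paired vectors of equal length >= 2")
    if np.allclose(a, b):
        return 1.0
    return float(stats.ttest_rel(a, b).pvalue)


def literature_labels(counts: Mapping[str, int] | pd.Series,
                      threshold: int = 5,
                      universe: Optional[Sequence[str]] = None,
                      ) -> pd.DataFrame:
    """Binary labels from publication counts: positive iff count >= threshold.

    Genes in ``universe`` but absent from the count table are labelled 0 with
    a logged count (no fabricated publication counts).
    """
    counts = pd.Series(dict(counts) if not isinstance(counts, pd.Series)
                       else counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("publication counts must be non-negative")
    if universe is not None:
        missing = pd.Index(universe).difference(counts.index)
        if len(missing):
            logger.warning("literature_labels: %d genes missing from the "
                           "count table labelled 0", len(missing))
        counts = counts.reindex(universe).fillna(-1.0)
    label = (counts >= threshold).astype(int)
    out = pd.DataFrame({"gene": counts.index,
                        "count": counts.to_numpy(),
                        "label": label.to_numpy()})
    out.loc[out["count"] < 0, "count"] = np.nan
    out["source"] = "literature"
    return out.reset_index(drop=True)


def ora_enrichment(query: Sequence[str], background: Sequence[str],
                   collections: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Hypergeometric over-representation of a query set in gene collections.

    Sets are intersected with the background first; p is the one-sided upper
    tail P(overlap >= observed) and q the BH correction across sets.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    query = set(query) & background
    if not set(query) <= background:
        raise ValueError("query must be a subset of the background")
    M, n = len(background), len(query)
    rows = []
    for name, genes in collections.items():
        s = set(genes) & background
        k = len(s & query)
        p = float(stats.hypergeom.sf(k - 1, M, len(s), n)) if s else 1.0
        rows.append({"set": name, "set_size": len(s), "overlap": k,
                     "p": min(p, 1.0)})
    df = pd.DataFrame(rows)
    df["q"] = bh_fdr(df["p"]) if len(df) else []
    return df.sort_values("p").reset_index(drop=True)


@dataclass
class AucReport:
    """Per scenario x strategy AUCs and pairwise paired t-test p-values."""

    aucs: pd.DataFrame        # index scenario, columns strategy
    ttest_p: pd.DataFrame     # strategy x strategy, two-tailed

    def mean_auc(self) -> pd.Series:
        return self.aucs.mean(axis=0)


def compare_strategies(scores: Mapping[object, Mapping[str, pd.Series]],
                       labels: Mapping[object, pd.Series]) -> AucReport:
    """AUC per scenario and strategy plus all pairwise paired t-tests.

    ``scores[scenario][strategy]`` is a per-gene score Series and
    ``labels[scenario]`` the matching binary labels.
    """
    rows = {}
    for scen, per_strategy in scores.items():
        rows[scen] = {name: roc_auc(s, labels[scen])
                      for name, s in per_strategy.items()}
    aucs = pd.DataFrame(rows).T.sort_index()
    strategies = list(aucs.columns)
    tt = pd.DataFrame(np.nan, index=strategies, columns=strategies)
    if len(aucs) >= 2:
        for a in strategies:
            for b in strategies:
                if a != b:
                    tt.loc[a, b] = paired_ttest(aucs[a], aucs[b])
    return AucReport(aucs=aucs, ttest_p=tt)
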
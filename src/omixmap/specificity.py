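"""Tissue-specific expression scoring.

The robust-regression Z-score of a gene in a tissue is the residual of that
tissue's (log-scale) expression vector, regressed on the per-gene mean of all
other tissues, standardised by the normalised median absolute deviation of
the residuals.  The regression is a Huber M-estimate (tuning constant 1.345,
iteratively reweighted least squares), so housekeeping genes — highly
expressed everywhere — define the trend line and do not inflate specificity,
while genes enriched in a single tissue land in the residual tail.

Normalised ranks convert Z-scores to a (0, 1] scale comparable across omics
layers: genes are ranked ascending within each tissue and divided by the gene
count, so 1/N marks the least and 1.0 the most tissue-specific gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.robust.scale import mad

from .config import get_logger
from .io import ExpressionProfile

__all__ = ["SpecificityMatrix", "NormalizedRankMatrix", "CrossLayerResult",
           "rez_zscores", "tissue_correlations", "cross_layer_correlations",
           "normalized_ranks"]

logger = get_logger(__name__)

HUBER_T = 1.345
MAX_ITER = 50
COEF_TOL = 1e-8


@dataclass
class SpecificityMatrix:
    """Gene x tissue robust-regression Z-scores for one omics layer."""

    z: pd.DataFrame
    layer: str

    @property
    def n_genes(self) -> int:
        return self.z.shape[0]

    @property
    def tissues(self) -> pd.Index:
        return self.z.columns


@dataclass
class NormalizedRankMatrix:
    """Ascending-rank position of each gene's Z within a tissue, divided by
    the gene count; ties receive average ranks."""

    r: pd.DataFrame
    layer: str
    ties: str = "average"


@dataclass
class CrossLayerResult:
    per_tissue: pd.Series
    mean: float
    ci_low: float
    ci_high: float
    n_genes: int


def rez_zscores(expr: ExpressionProfile, log_transform: bool = True,
                ) -> SpecificityMatrix:
    """Robust-regression tissue-specificity Z-scores.

    Each tissue column is regressed (Huber IRLS, intercept + slope) on the
    per-gene mean of the remaining tissues; Z = residual / normalised MAD of
    the residuals.  A tissue with identical values in every gene yields a
    zero column with a warning.
    """
    values = expr.values
    if values.shape[1] < 3:
        raise ValueError("rez_zscores requires at least 3 tissues")
    if values.shape[0] < 10:
        raise ValueError("rez_zscores requires at least 10 genes")
    X = np.log2(values.to_numpy(dtype=float) + 1.0) if log_transform \
        else values.to_numpy(dtype=float)
    n_genes, n_tissues = X.shape
    total = X.sum(axis=1)
    Z = np.zeros_like(X)
    for j in range(n_tissues):
        y = X[:, j]
        others = (total - y) / (n_tissues - 1)
        if np.ptp(y) == 0.0:
            logger.warning("rez_zscores: tissue %r constant; Z set to 0",
                           str(values.columns[j]))
            continue
        design = sm.add_constant(others)
        fit = sm.RLM(y, design, M=sm.robust.norms.HuberT(HUBER_T)).fit(
            maxiter=MAX_ITER, tol=COEF_TOL, conv="coefs")
        resid = np.asarray(fit.resid)
        scale = mad(resid)
        # an (almost) exact fit leaves only float noise: Z is genuinely 0
        if scale <= 1e-12 * max(1.0, np.abs(y).max()):
            continue
        Z[:, j] = resid / scale
    return SpecificityMatrix(
        z=pd.DataFrame(Z, index=values.index, columns=values.columns),
        layer=expr.layer)


def tissue_correlations(spec: SpecificityMatrix) -> pd.DataFrame:
    """Tissue x tissue Spearman correlation of specificity Z-scores."""
    rho = stats.spearmanr(spec.z.to_numpy()).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-tissue case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=spec.tissues, columns=spec.tissues)


def _spearman_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Spearman correlation between two equally shaped matrices."""
    ra = stats.rankdata(a, axis=0)
    rb = stats.rankdata(b, axis=0)
    ra = ra - ra.mean(axis=0)
    rb = rb - rb.mean(axis=0)
    num = (ra * rb).sum(axis=0)
    den = np.sqrt((ra ** 2).sum(axis=0) * (rb ** 2).sum(axis=0))
    with np.errstate(invalid="ignore"):
        return num / den


def cross_layer_correlations(spec_rna: SpecificityMatrix,
                             spec_prot: SpecificityMatrix,
                             n_boot: int = 2000,
                             seed: int = 0) -> CrossLayerResult:
    """Per-tissue Spearman correlation between RNA and protein specificity
    Z-scores, with a percentile bootstrap CI (over genes) for the mean."""
    genes = spec_rna.z.index.intersection(spec_prot.z.index)
    tissues = spec_rna.tissues.intersection(spec_prot.tissues)
    dropped = (len(spec_rna.z.index) - len(genes),
               len(spec_prot.z.index) - len(genes))
    if any(dropped):
        logger.info("cross_layer_correlations: dropped %d RNA / %d protein "
                    "genes absent from the other layer", *dropped)
    if len(genes) < 3:
        raise ValueError("fewer than 3 shared genes between layers")
    a = spec_rna.z.loc[genes, tissues].to_numpy()
    b = spec_prot.z.loc[genes, tissues].to_numpy()
    per_tissue = pd.Series(_spearman_columns(a, b), index=tissues)
    mean = float(per_tissue.mean())
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boot = np.empty(n_boot)
        for i in range(n_boot):
            idx = rng.integers(0, len(genes), len(genes))
            boot[i] = _spearman_columns(a[idx], b[idx]).mean()
        ci_low, ci_high = np.percentile(boot, [2.5, 97.5])
    else:
        ci_low = ci_high = np.nan
    return CrossLayerResult(per_tissue=per_tissue, mean=mean,
                            ci_low=float(ci_low), ci_high=float(ci_high),
                            n_genes=len(genes))


def normalized_ranks(spec: SpecificityMatrix) -> NormalizedRankMatrix:
    """Per tissue, ascending ranks of Z divided by the gene count N; average
    ranks on ties, so each tie-free column is a permutation of {1/N, ..., 1}."""
    ranks = stats.rankdata(spec.z.to_numpy(), axis=0, method="average")
    r = ranks / spec.n_genes
    return NormalizedRankMatrix(
        r=pd.DataFrame(r, index=spec.z.index, columns=spec.z.columns),
        layer=spec.layer)
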
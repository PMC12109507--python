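"""Gene-level association statistics from GWAS summary statistics.

A gene's statistic pools the squared z-scores of the SNPs in its window.
Under the null the pooled statistic is a quadratic form whose weights are the
eigenvalues of the SNP correlation matrix R; the reported degrees of freedom
are the effective number of independent tests m_eff = (sum lam)^2 / sum lam^2,
the statistic is rescaled to that effective scale, and the p-value is the
exact tail of the quadratic form (see ``_quadform``).  Conditional statistics
residualise a gene's z-scores on an already-selected SNP set through the joint
LD matrix, which is the engine of the conditional fine-mapping procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._quadform import effective_tests, quadform_sf, quadform_sf_many
from .config import GeneAnnotation, MhcRegion, get_logger
from .io import GwasSummary, LdBlocks

__all__ = ["GeneStat", "map_snps_to_genes", "gene_pvalue",
           "conditional_gene_pvalue", "gene_statistics"]

logger = get_logger(__name__)

RIDGE = 1e-4
# conditional variances at or below the ridge scale mean the SNP is fully
# explained by the conditioning set
_VAR_FLOOR = 1e-3


@dataclass
class GeneStat:
    gene: Optional[str]
    m: int
    m_eff: float
    statistic: float
    p: float
    conditional_p: Optional[float] = None


def map_snps_to_genes(gwas: GwasSummary, annotation: GeneAnnotation,
                      window_kb: int = 10,
                      mhc: Optional[MhcRegion] = MhcRegion(),
                      ) -> dict[str, list[str]]:
    """Assign each SNP to every gene whose window [start-w, end+w] (1-based,
    inclusive) contains its position; SNPs inside the MHC region are excluded
    before assignment and genes with no SNPs are dropped with a logged count.
    """
    snps = gwas.table
    if mhc is not None:
        in_mhc = (snps["chromosome"].astype(str) == mhc.chromosome) & \
            snps["position"].between(mhc.start, mhc.end)
        if in_mhc.any():
            logger.info("map_snps_to_genes: excluded %d SNPs in the MHC "
                        "region", int(in_mhc.sum()))
            snps = snps[~in_mhc]
    windows = annotation.windows(window_kb)
    shared = set(windows["chromosome"]) & set(snps["chromosome"].astype(str))
    if not shared:
        raise ValueError("annotation and GWAS share no chromosomes")
    mapping: dict[str, list[str]] = {}
    n_empty = 0
    for chrom, sub in snps.groupby("chromosome", sort=False):
        pos = sub["position"].to_numpy()
        ids = sub["snp"].to_numpy()
        order = np.argsort(pos, kind="stable")
        pos, ids = pos[order], ids[order]
        for _, row in windows[windows["chromosome"] == str(chrom)].iterrows():
            lo = np.searchsorted(pos, row["win_start"], side="left")
            hi = np.searchsorted(pos, row["win_end"], side="right")
            if hi > lo:
                mapping[row["gene"]] = list(ids[lo:hi])
            else:
                n_empty += 1
    n_empty += int((~windows["chromosome"].isin(shared)).sum())
    if n_empty:
        logger.info("map_snps_to_genes: dropped %d genes with no SNPs",
                    n_empty)
    return mapping


_EIG_CACHE: dict[bytes, np.ndarray] = {}


def _eigenvalues(R: np.ndarray, cache: bool = False) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("R must be square")
    key = None
    if cache:
        key = np.round(R, 12).tobytes()
        hit = _EIG_CACHE.get(key)
        if hit is not None:
            return hit
    lam = np.linalg.eigvalsh(R)
    if lam.min() < -1e-6 * max(lam.max(), 1.0):
        raise ValueError("correlation matrix is not positive semi-definite")
    lam = np.clip(lam, 0.0, None)
    if cache:
        if len(_EIG_CACHE) > 20000:
            _EIG_CACHE.clear()
        _EIG_CACHE[key] = lam
    return lam


def gene_pvalue(z: np.ndarray, R: np.ndarray, gene: Optional[str] = None,
                method: str = "auto") -> GeneStat:
    """Gene statistic and p-value from SNP z-scores and their correlation.

    statistic = (m_eff / m) * sum z_i^2 with m_eff the effective number of
    tests; the p-value is the exact null tail of sum lam_i chi2_1 evaluated at
    sum z_i^2 (identical to the chi-squared(m_eff) tail of the scaled
    statistic in the single-SNP, perfect-LD and R = I limits).
    """
    z = np.asarray(z, dtype=float).ravel()
    if z.size == 0:
        raise ValueError("empty z vector")
    lam = _eigenvalues(R)
    m = z.size
    m_eff = effective_tests(lam)
    ssq = float(np.square(z).sum())
    statistic = m_eff / m * ssq
    p = quadform_sf(ssq, lam, method=method)
    return GeneStat(gene=gene, m=m, m_eff=m_eff, statistic=statistic, p=p)


def _drop_collinear(R_aa: np.ndarray, z_a: np.ndarray,
                    R_ba: np.ndarray) -> tuple[np.ndarray, ...]:
    """Drop the most collinear conditioning SNPs until R_aa is invertible."""
    keep = list(range(R_aa.shape[0]))
    while len(keep) > 1:
        sub = R_aa[np.ix_(keep, keep)] + RIDGE * np.eye(len(keep))
        if np.linalg.matrix_rank(sub) == len(keep) and \
                np.linalg.cond(sub) < 1e10:
            break
        off = np.abs(sub - np.eye(len(keep)))
        worst = int(np.argmax(off.sum(axis=1)))
        logger.warning("conditional_gene_pvalue: dropped collinear "
                       "conditioning SNP (index %d)", keep[worst])
        keep.pop(worst)
    return R_aa[np.ix_(keep, keep)], z_a[keep], R_ba[:, keep]


def conditional_gene_pvalue(z_b: np.ndarray, z_a: np.ndarray,
                            R_bb: np.ndarray, R_ba: np.ndarray,
                            R_aa: np.ndarray, gene: Optional[str] = None,
                            method: str = "auto") -> GeneStat:
    """Gene statistic for B's SNPs after conditioning on SNP set A.

    Residual z for B given A is (z_B - R_BA R_AA^-1 z_A) standardised by the
    conditional standard deviations; the gene test is then applied to the
    residual z with the conditional correlation matrix.  SNPs of B that are
    fully explained by A (conditional variance ~ 0) are removed; if none
    remain the signal is fully explained and p = 1.
    """
    z_b = np.asarray(z_b, dtype=float).ravel()
    z_a = np.asarray(z_a, dtype=float).ravel()
    if z_a.size == 0:
        return gene_pvalue(z_b, R_bb, gene=gene, method=method)
    R_bb = np.asarray(R_bb, dtype=float)
    R_ba = np.asarray(R_ba, dtype=float).reshape(z_b.size, z_a.size)
    R_aa = np.asarray(R_aa, dtype=float)
    R_aa, z_a, R_ba = _drop_collinear(R_aa, z_a, R_ba)
    A = R_aa + RIDGE * np.eye(R_aa.shape[0])
    try:
        coef = np.linalg.solve(A, np.vstack([z_a, R_ba]).T)
    except np.linalg.LinAlgError as exc:
        raise ValueError("conditioning matrix singular beyond ridge") from exc
    z_adj = z_b - R_ba @ coef[:, 0]
    cov = R_bb - R_ba @ coef[:, 1:]
    cov = (cov + cov.T) / 2.0
    d = np.diag(cov).copy()
    keep = d > _VAR_FLOOR
    if not keep.any():
        return GeneStat(gene=gene, m=z_b.size, m_eff=1.0, statistic=0.0,
                        p=1.0)
    z_res = z_adj[keep] / np.sqrt(d[keep])
    sub = cov[np.ix_(keep, keep)]
    denom = np.sqrt(np.outer(d[keep], d[keep]))
    R_cond = np.clip(sub / denom, -1.0, 1.0)
    np.fill_diagonal(R_cond, 1.0)
    return gene_pvalue(z_res, R_cond, gene=gene, method=method)


def gene_statistics(gwas: GwasSummary, ld: LdBlocks,
                    mapping: Mapping[str, Sequence[str]],
                    ) -> pd.DataFrame:
    """Unconditional gene statistics for every mapped gene.

    Genes whose LD submatrices share an eigenvalue spectrum (the common case
    when blocks share a structure) are evaluated in one vectorised batch.
    Returns a DataFrame with columns gene, m, m_eff, statistic, p.
    """
    zmap = dict(zip(gwas.table["snp"], gwas.table["z"].astype(float)))
    rows = []
    groups: dict[bytes, list[int]] = {}
    ssqs, lams = [], []
    n_missing_total = 0
    for gene, snps in mapping.items():
        snps = [s for s in snps if s in ld and s in zmap]
        n_missing_total += len(mapping[gene]) - len(snps)
        if not snps:
            continue
        z = np.array([zmap[s] for s in snps])
        lam = _eigenvalues(ld.submatrix(snps), cache=True)
        key = np.round(lam, 10).tobytes()
        groups.setdefault(key, []).append(len(rows))
        ssqs.append(float(np.square(z).sum()))
        lams.append(lam)
        rows.append({"gene": gene, "m": len(snps),
                     "m_eff": effective_tests(lam)})
    if n_missing_total:
        logger.info("gene_statistics: %d mapped SNPs absent from LD/GWAS "
                    "dropped", n_missing_total)
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=["gene", "m", "m_eff", "statistic", "p"])
    ssq_arr = np.asarray(ssqs)
    pvals = np.empty(len(df))
    for key, idx in groups.items():
        idx = np.asarray(idx)
        pvals[idx] = quadform_sf_many(ssq_arr[idx], lams[idx[0]])
    df["statistic"] = df["m_eff"] / df["m"] * ssq_arr
    df["p"] = pvals
    return df.sort_values("gene").reset_index(drop=True)
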
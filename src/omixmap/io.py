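"""Readers and writers for the tabular formats the pipeline touches.

All matrices are plain TSV with a header row; writers prepend a comment line
recording the package version and, when given, the seed of the run, and every
reader skips ``#`` comment lines, so reader/writer pairs round-trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import GeneAnnotation, get_logger

__all__ = [
    "ExpressionProfile", "GwasSummary", "LdBlock", "LdBlocks",
    "read_expression", "write_expression", "read_gwas", "write_gwas",
    "read_ld", "read_annotation", "write_annotation", "read_gmt", "write_gmt",
    "write_tsv", "read_tsv",
]

VERSION = "0.1.0"
logger = get_logger(__name__)

# recognised header aliases for GWAS summary files (lower-cased)
GWAS_ALIASES: dict[str, tuple[str, ...]] = {
    "snp": ("snp", "rsid", "markername", "id", "snpid", "variant_id"),
    "chromosome": ("chr", "chrom", "chromosome", "#chr", "#chrom"),
    "position": ("pos", "bp", "position", "base_pair_location"),
    "a1": ("a1", "effect_allele", "alt", "allele1", "ea"),
    "a2": ("a2", "other_allele", "ref", "allele2", "nea", "oa"),
    "p": ("p", "pval", "pvalue", "p_value", "p-value"),
    "z": ("z", "zscore", "z_score", "stat"),
    "beta": ("beta", "b", "effect", "effect_size", "log_odds"),
    "se": ("se", "stderr", "standard_error", "sebeta"),
    "n": ("n", "nsample", "samplesize", "sample_size", "neff"),
}


def _comment_header(seed: Optional[int] = None, **meta: object) -> str:
    parts = [f"# omixmap {VERSION}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    parts.extend(f"{k}={v}" for k, v in meta.items())
    return " ".join(parts) + "\n"


def write_tsv(df: pd.DataFrame, path: str | Path, *, index: bool = False,
              seed: Optional[int] = None, **meta: object) -> None:
    with open(path, "w") as fh:
        fh.write(_comment_header(seed, **meta))
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs: object) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# ---------------------------------------------------------------------------
# expression matrices

@dataclass
class ExpressionProfile:
    """Gene x tissue abundance matrix for one omics layer (natural scale)."""

    values: pd.DataFrame
    layer: str

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def tissues(self) -> pd.Index:
        return self.values.columns


def read_expression(path: str | Path, layer: str) -> ExpressionProfile:
    """Read a gene x tissue TSV; first column gene ids, remaining columns
    tissues.  Duplicate gene rows are resolved by keeping the row with the
    highest row-sum; a duplicate tissue column or a non-numeric cell is an
    error naming the offending location."""
    with open(path) as fh:
        header = next(line for line in fh if not line.startswith("#"))
    tissues = header.rstrip("\n").split("\t")[1:]
    dup = [t for t in set(tissues) if tissues.count(t) > 1]
    if dup:
        raise ValueError(f"duplicate tissue columns in {path}: {sorted(dup)}")
    raw = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                      keep_default_na=False)
    genes = raw.iloc[:, 0]
    mat = np.empty((len(raw), len(tissues)))
    for j, t in enumerate(raw.columns[1:]):
        col = pd.to_numeric(raw[t], errors="coerce")
        bad = col.index[col.isna()]
        if len(bad):
            raise ValueError(
                f"non-numeric cell in {path}: gene {genes.iloc[bad[0]]!r}, "
                f"tissue {t!r}, value {raw[t].iloc[bad[0]]!r}")
        mat[:, j] = col.to_numpy()
    values = pd.DataFrame(mat, index=pd.Index(genes, name="gene"),
                          columns=tissues)
    if values.index.duplicated().any():
        n0 = len(values)
        # keep, per duplicated symbol, the row with the highest row-sum
        rowsum = values.sum(axis=1).to_numpy()
        keep = np.zeros(len(values), dtype=bool)
        for g, idx in pd.Series(range(len(values)),
                                index=values.index).groupby(level=0):
            rows = idx.to_numpy()
            keep[rows[np.argmax(rowsum[rows])]] = True
        values = values.loc[keep]
        logger.info("read_expression: de-duplicated %d -> %d gene rows",
                    n0, len(values))
    return ExpressionProfile(values=values, layer=layer)


def write_expression(profile: ExpressionProfile, path: str | Path,
                     seed: Optional[int] = None) -> None:
    with open(path, "w") as fh:
        fh.write(_comment_header(seed, layer=profile.layer))
        profile.values.to_csv(fh, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# GWAS summary statistics

@dataclass
class GwasSummary:
    """Per-SNP association records, sorted by (chromosome, position), with a
    z-score guaranteed present for every retained record."""

    table: pd.DataFrame  # snp, chromosome, position, a1, a2, z, p, n
    n_dropped: int = 0

    @property
    def snps(self) -> pd.Index:
        return pd.Index(self.table["snp"])


_CHROM_SPECIAL = {"X": 23, "Y": 24, "MT": 25, "M": 25, "XY": 26}


def chromosome_sort_key(labels: Iterable[str]) -> np.ndarray:
    keys = []
    for c in labels:
        c = str(c).removeprefix("chr")
        if c.isdigit():
            keys.append(int(c))
        elif c.upper() in _CHROM_SPECIAL:
            keys.append(_CHROM_SPECIAL[c.upper()])
        else:
            raise ValueError(f"unsortable chromosome label: {c!r}")
    return np.asarray(keys)


def _resolve_columns(columns: Sequence[str],
                     aliases: Optional[Mapping[str, Sequence[str]]],
                     ) -> dict[str, str]:
    table = {k: tuple(v) for k, v in GWAS_ALIASES.items()}
    if aliases:
        for k, v in aliases.items():
            table[k] = tuple(x.lower() for x in v) + table.get(k, ())
    lower = {c.lower(): c for c in columns}
    out = {}
    for field_name, names in table.items():
        for n in names:
            if n in lower:
                out[field_name] = lower[n]
                break
    return out


def read_gwas(path: str | Path,
              aliases: Optional[Mapping[str, Sequence[str]]] = None,
              ) -> GwasSummary:
    """Read GWAS summary statistics from TSV with configurable header aliases.

    z is passed through when present, otherwise derived from (beta, p) as
    sign(beta) * |probit(p/2)|.  Records with p outside (0, 1] are dropped and
    counted.
    """
    raw = pd.read_csv(path, sep="\t", comment="#")
    cols = _resolve_columns(raw.columns, aliases)
    for required in ("snp", "chromosome", "position", "p"):
        if required not in cols:
            raise ValueError(f"GWAS file {path} lacks a recognised "
                             f"'{required}' column (have {list(raw.columns)})")
    if "z" not in cols and not ("beta" in cols):
        raise ValueError(
            f"GWAS file {path}: need either a z column or beta with p")
    df = pd.DataFrame({
        "snp": raw[cols["snp"]].astype(str),
        "chromosome": raw[cols["chromosome"]].astype(str),
        "position": raw[cols["position"]].astype(int),
        "a1": raw[cols["a1"]].astype(str) if "a1" in cols else "N",
        "a2": raw[cols["a2"]].astype(str) if "a2" in cols else "N",
        "p": pd.to_numeric(raw[cols["p"]], errors="coerce"),
        "n": pd.to_numeric(raw[cols["n"]], errors="coerce")
        if "n" in cols else np.nan,
    })
    ok = (df["p"] > 0) & (df["p"] <= 1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("read_gwas: dropped %d records with p outside (0,1]",
                    n_dropped)
    df = df[ok].copy()
    if "z" in cols:
        df["z"] = pd.to_numeric(raw.loc[df.index, cols["z"]], errors="coerce")
    else:
        beta = pd.to_numeric(raw.loc[df.index, cols["beta"]], errors="coerce")
        df["z"] = np.sign(beta) * np.abs(stats.norm.isf(df["p"] / 2.0))
    df = df[["snp", "chromosome", "position", "a1", "a2", "z", "p", "n"]]
    key = chromosome_sort_key(df["chromosome"])
    order = np.lexsort((df["snp"].to_numpy(), df["position"].to_numpy(), key))
    df = df.iloc[order].reset_index(drop=True)
    return GwasSummary(table=df, n_dropped=n_dropped)


def write_gwas(gwas: GwasSummary, path: str | Path,
               seed: Optional[int] = None) -> None:
    write_tsv(gwas.table, path, seed=seed)


# ---------------------------------------------------------------------------
# LD blocks

@dataclass
class LdBlock:
    snps: list[str]
    R: np.ndarray

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        if self.R.shape != (len(self.snps), len(self.snps)):
            raise ValueError("LD matrix shape does not match SNP list")


@dataclass
class LdBlocks:
    """Per-block SNP correlation matrices with an id index.

    ``submatrix`` assembles the joint correlation of an arbitrary SNP set,
    block-diagonal across blocks (zero correlation between blocks).
    """

    blocks: list[LdBlock]
    _index: dict[str, tuple[int, int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {}
        for b, blk in enumerate(self.blocks):
            for i, snp in enumerate(blk.snps):
                if snp in self._index:
                    raise ValueError(f"SNP {snp} appears in two LD blocks")
                self._index[snp] = (b, i)

    def __contains__(self, snp: str) -> bool:
        return snp in self._index

    def block_of(self, snp: str) -> int:
        return self._index[snp][0]

    def submatrix(self, snps: Sequence[str]) -> np.ndarray:
        loc = np.array([self._index[s] for s in snps])
        n = len(snps)
        R = np.zeros((n, n))
        for b in np.unique(loc[:, 0]):
            sel = np.nonzero(loc[:, 0] == b)[0]
            within = loc[sel, 1]
            R[np.ix_(sel, sel)] = self.blocks[b].R[np.ix_(within, within)]
        np.fill_diagonal(R, 1.0)
        return R


def _corr_from_genotypes(geno: pd.DataFrame) -> LdBlock:
    """Pearson correlation of 0/1/2 genotype rows (SNPs x samples); missing
    values mean-imputed per SNP, monomorphic SNPs removed with a warning."""
    X = geno.to_numpy(dtype=float)
    means = np.nanmean(X, axis=1)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(means, inds[0])
    var = X.var(axis=1)
    keep = var > 0
    if (~keep).any():
        logger.warning("read_ld: removed %d monomorphic SNPs",
                       int((~keep).sum()))
    X = X[keep]
    snps = list(geno.index[keep])
    R = np.corrcoef(X)
    if R.ndim == 0:
        R = np.array([[1.0]])
    np.fill_diagonal(R, 1.0)
    return LdBlock(snps=snps, R=R)


def _read_vcf_genotypes(path: str | Path) -> pd.DataFrame:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading VCF LD panels requires cyvcf2") from exc
    ids, rows = [], []
    for var in VCF(str(path), gts012=True):
        gt = np.asarray(var.gt_types, dtype=float)  # 0/1/2 alt dosage, 3 missing
        gt[gt == 3] = np.nan
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        rows.append(gt)
    return pd.DataFrame(rows, index=ids)


def read_ld(path: str | Path) -> LdBlocks:
    """Load LD from a directory of precomputed block matrices (TSV, SNP ids as
    header and first column), from a genotype matrix TSV (rows = SNPs coded
    0/1/2, missing allowed), or from a VCF (GT field)."""
    path = Path(path)
    if path.is_dir():
        blocks = []
        for f in sorted(path.glob("*.tsv")):
            mat = pd.read_csv(f, sep="\t", comment="#", index_col=0)
            R = mat.to_numpy(dtype=float)
            if R.shape[0] != R.shape[1] or list(mat.index) != list(mat.columns):
                raise ValueError(f"{f}: block matrix must be square with "
                                 "matching SNP ids")
            if not np.allclose(R, R.T, atol=1e-8):
                raise ValueError(f"{f}: precomputed LD matrix not symmetric")
            np.fill_diagonal(R, 1.0)
            blocks.append(LdBlock(snps=list(mat.index), R=R))
        if not blocks:
            raise ValueError(f"no block matrices (*.tsv) found in {path}")
        return LdBlocks(blocks=blocks)
    if path.suffix in (".vcf", ".gz", ".bcf"):
        geno = _read_vcf_genotypes(path)
    else:
        geno = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return LdBlocks(blocks=[_corr_from_genotypes(geno)])


# ---------------------------------------------------------------------------
# annotation / gene sets

def read_annotation(path: str | Path) -> GeneAnnotation:
    df = read_tsv(path)
    return GeneAnnotation(table=df[["gene", "chromosome", "start", "end"]])


def write_annotation(annotation: GeneAnnotation, path: str | Path,
                     seed: Optional[int] = None) -> None:
    write_tsv(annotation.table, path, seed=seed)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")
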
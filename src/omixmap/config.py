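"""Run configuration, gene annotation container, and logging setup."""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

__all__ = ["PipelineConfig", "MhcRegion", "GeneAnnotation", "get_logger",
           "load_config", "save_config"]


def get_logger(name: str = "omixmap") -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


@dataclass(frozen=True)
class MhcRegion:
    """Major histocompatibility complex region excluded from association
    analyses (complex LD). Default is the conventional GRCh37-style interval;
    coordinates are 1-based inclusive."""

    chromosome: str = "6"
    start: int = 25_000_000
    end: int = 34_000_000

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("MHC start must be <= end")

    def contains(self, chromosome, position) -> bool:
        return str(chromosome) == self.chromosome and \
            self.start <= int(position) <= self.end


@dataclass
class PipelineConfig:
    """End-to-end run settings.

    window_kb extends each gene interval by window_kb*1000 bp on both sides
    (1-based inclusive) when assigning SNPs to genes. fdr_threshold and
    max_genes bound the conditional fine-mapping selection; topk_genes is the
    tissue-specific gene-set size for the enrichment-based tissue test.
    """

    expression_rna: Optional[str] = None
    expression_protein: Optional[str] = None
    gwas: Optional[str] = None
    ld: Optional[str] = None
    annotation: Optional[str] = None
    window_kb: int = 10
    mhc_region: MhcRegion = field(default_factory=MhcRegion)
    fdr_threshold: float = 0.05
    max_genes: int = 1000
    topk_genes: int = 1000
    seed: int = 0
    output_dir: str = "omixmap_out"

    def __post_init__(self) -> None:
        if self.window_kb < 0:
            raise ValueError("window_kb must be >= 0")
        if not 0.0 < self.fdr_threshold < 1.0:
            raise ValueError("fdr_threshold must lie in (0, 1)")
        if self.max_genes < 1:
            raise ValueError("max_genes must be >= 1")
        if self.topk_genes < 1:
            raise ValueError("topk_genes must be >= 1")
        if isinstance(self.mhc_region, dict):
            self.mhc_region = MhcRegion(**self.mhc_region)


@dataclass
class GeneAnnotation:
    """Gene intervals (1-based, inclusive). Duplicate symbols are dropped,
    keeping the first occurrence."""

    table: pd.DataFrame  # columns: gene, chromosome, start, end

    REQUIRED = ("gene", "chromosome", "start", "end")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        t = self.table.copy()
        t["chromosome"] = t["chromosome"].astype(str)
        t["start"] = t["start"].astype(int)
        t["end"] = t["end"].astype(int)
        if (t["start"] > t["end"]).any():
            bad = t.loc[t["start"] > t["end"], "gene"].tolist()
            raise ValueError(f"start > end for genes: {bad[:5]}")
        n_dup = int(t["gene"].duplicated().sum())
        if n_dup:
            get_logger().warning("annotation: dropped %d duplicate gene rows",
                                 n_dup)
            t = t[~t["gene"].duplicated()]
        self.table = t.reset_index(drop=True)

    @property
    def genes(self) -> pd.Index:
        return pd.Index(self.table["gene"])

    def windows(self, window_kb: int) -> pd.DataFrame:
        """Gene windows [start - w, end + w], 1-based inclusive."""
        w = int(window_kb) * 1000
        out = self.table.copy()
        out["win_start"] = out["start"] - w
        out["win_end"] = out["end"] + w
        return out


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    data = asdict(cfg)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
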
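import numpy as np
import pandas as pd
import pytest

import omixmap as om


def ar1(m: int, rho: float) -> np.ndarray:
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :])


@pytest.fixture(scope="session")
def small_cfg() -> om.SimConfig:
    """A scaled-down scenario that keeps the full locus structure."""
    return om.SimConfig(n_genes=300, n_tissues=8, n_causal=15,
                        n_discordant=3, seed=11)


@pytest.fixture(scope="session")
def small_scenario(small_cfg):
    """Generated small scenario shared across tests (read-only)."""
    truth = om.make_truth(small_cfg)
    rna, prot = om.generate_expression(small_cfg, truth)
    ann = om.make_annotation(small_cfg)
    gwas, ld = om.generate_gwas(small_cfg, truth, ann)
    mapping = om.map_snps_to_genes(gwas, ann, window_kb=10)
    gene_stats = om.gene_statistics(gwas, ld, mapping)
    return {"cfg": small_cfg, "truth": truth, "rna": rna, "prot": prot,
            "ann": ann, "gwas": gwas, "ld": ld, "mapping": mapping,
            "gene_stats": gene_stats}


@pytest.fixture(scope="session")
def small_spec(small_scenario):
    return {"rna": om.rez_zscores(small_scenario["rna"]),
            "prot": om.rez_zscores(small_scenario["prot"])}


def make_spec(z: np.ndarray, genes=None, tissues=None, layer="rna"):
    z = np.asarray(z, dtype=float)
    genes = genes or [f"g{i}" for i in range(z.shape[0])]
    tissues = tissues or [f"t{j}" for j in range(z.shape[1])]
    return om.SpecificityMatrix(
        z=pd.DataFrame(z, index=genes, columns=tissues), layer=layer)
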
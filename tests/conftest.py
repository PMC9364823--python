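import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from anndata import AnnData

from rili_scomm.qc import normalize_lognorm
from rili_scomm.simulate import (
    SimConfig,
    decoy_lr_pairs,
    generate_dataset,
    plan_lr_edges,
)

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=pd.errors.PerformanceWarning)


@pytest.fixture(scope="session")
def small_dataset():
    """Four clusters spanning resistant to highly radiosensitive."""
    cfg = SimConfig(
        n_clusters=4,
        cells_per_cluster_pre=120,
        depletion_factor=(1.0, 0.6, 0.3, 0.05),
        n_genes=250,
        seed=11,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def normalized(small_dataset):
    adata = normalize_lognorm(small_dataset.adata)
    adata.obs["cluster"] = adata.obs["true_cluster"]
    return adata


@pytest.fixture(scope="session")
def lr_dataset():
    """Planted ligand-receptor edges plus decoys, true labels attached."""
    base = SimConfig(
        n_clusters=4, cells_per_cluster_pre=200, depletion_factor=1.0,
        n_genes=300, cycling_fraction=0.0, seed=7,
    )
    planted = plan_lr_edges(base, 3, 0.6)
    decoys = decoy_lr_pairs(base, 20, gene_offset=3)
    cfg = SimConfig(
        n_clusters=4, cells_per_cluster_pre=200, depletion_factor=1.0,
        n_genes=300, cycling_fraction=0.0, seed=7, planted_lr_edges=planted,
    )
    ds = generate_dataset(cfg)
    norm = normalize_lognorm(ds.adata)
    norm.obs["cluster"] = norm.obs["true_cluster"]
    return ds, norm, planted, decoys


def make_normalized_adata(X, clusters=None, conditions=None, genes=None):
    """Hand-built AnnData tagged as normalized, for direct-rule tests."""
    X = np.asarray(X, dtype=float)
    n_obs, n_vars = X.shape
    obs = pd.DataFrame(index=[f"c{i}" for i in range(n_obs)])
    if clusters is not None:
        obs["cluster"] = list(clusters)
    if conditions is not None:
        obs["condition"] = list(conditions)
    var_names = genes if genes is not None else [f"g{j}" for j in range(n_vars)]
    adata = AnnData(
        X=sp.csr_matrix(X), obs=obs, var=pd.DataFrame(index=var_names)
    )
    adata.uns["layer"] = "normalized"
    return adata
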
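import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

warnings.filterwarnings("ignore", message="Variable names are not unique")


@pytest.fixture(scope="session")
def sim_default():
    """One simulated niche under the default study conditions."""
    from nichecomm import default_config, simulate_niche

    cfg = default_config(seed=11)
    adata, truth = simulate_niche(cfg)
    return cfg, adata, truth


@pytest.fixture(scope="session")
def sim_normalized(sim_default):
    """Default simulation, QC-filtered and normalized."""
    from nichecomm.preprocess import QCThresholds, normalize, qc_filter

    _, adata, truth = sim_default
    filtered, _ = qc_filter(adata, QCThresholds(50, 5000, 0.2, 3))
    return normalize(filtered), truth


@pytest.fixture(scope="session")
def lr_table():
    from nichecomm.resources import load_lr_table

    return load_lr_table()


@pytest.fixture(scope="session")
def phase_gene_lists():
    from nichecomm.resources import load_gene_list

    return tuple(load_gene_list("s_genes")), tuple(load_gene_list("g2m_genes"))


def small_sim_config(seed: int = 0):
    """Down-scaled study conditions for fast end-to-end tests."""
    from dataclasses import replace

    from nichecomm import default_config

    cfg = default_config(seed=seed)
    cfg.cell_types = [
        replace(ct, n_per_sample=max(ct.n_per_sample * 0.3, 25))
        for ct in cfg.cell_types
    ]
    cfg.n_genes = 600
    return cfg


def make_log_adata(X, gene_names=None, cell_names=None, obs=None):
    """Dense AnnData carrying X directly as the normalized log layer."""
    import anndata as ad
    import pandas as pd

    X = np.asarray(X, dtype=float)
    n, g = X.shape
    genes = list(gene_names) if gene_names is not None else [f"g{i}" for i in range(g)]
    cells = list(cell_names) if cell_names is not None else [f"c{i}" for i in range(n)]
    obs_df = pd.DataFrame(index=pd.Index(cells, name="cell_id"))
    if obs:
        for k, v in obs.items():
            obs_df[k] = v
    adata = ad.AnnData(X=X, obs=obs_df, var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    adata.layers["log1p_cpm"] = X.copy()
    adata.layers["cpm"] = np.expm1(X)
    adata.uns["layer"] = "log1p_cpm"
    return adata
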
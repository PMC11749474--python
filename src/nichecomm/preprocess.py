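"""QC filtering, per-cell normalization and graph clustering.

QC removes cells by detected-gene count and mitochondrial fraction first,
then genes detected in too few of the surviving cells, and reports the
per-criterion removals. Normalization scales each cell to a fixed total
("TPM"-style counts-per-million for 3'-tag UMI data, i.e. no gene-length
term) and stores the natural-log layer log(1 + scaled). Clustering is the
standard dispersion-HVG -> scale -> PCA -> kNN -> Leiden pipeline via scanpy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import anndata as ad
import numpy as np
import scipy.sparse as sp


class QCError(ValueError):
    pass


@dataclass(frozen=True)
class QCThresholds:
    """Cell/gene retention thresholds.

    Defaults suit deeply sequenced real data; synthetic runs use looser
    values from their run config. All counts are "detected genes" (nonzero
    entries), mito fraction is mitochondrial counts over total counts.
    """

    min_genes_per_cell: int = 500
    max_genes_per_cell: int = 6000
    max_mito_fraction: float = 0.10
    min_cells_per_gene: int = 3

    def __post_init__(self):
        if self.min_genes_per_cell >= self.max_genes_per_cell:
            raise QCError("min_genes_per_cell must be < max_genes_per_cell")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise QCError("max_mito_fraction must be in [0, 1]")


def qc_filter(
    adata: ad.AnnData,
    thresholds: QCThresholds,
    mito_prefix: str = "mt-",
) -> tuple[ad.AnnData, dict]:
    """Filter cells then genes; return the filtered matrix and a QC report.

    Cells are removed when their detected-gene count falls outside
    [min, max] or their mitochondrial count fraction exceeds the maximum;
    afterwards genes detected in fewer than ``min_cells_per_gene`` surviving
    cells are removed. Deterministic order: cells first, then genes.
    """
    X = sp.csr_matrix(adata.layers.get("counts", adata.X))
    n_genes_per_cell = np.asarray((X > 0).sum(axis=1)).ravel()
    totals = np.asarray(X.sum(axis=1)).ravel()
    mito_mask = adata.var_names.str.startswith(mito_prefix)
    mito_counts = np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)

    low = n_genes_per_cell < thresholds.min_genes_per_cell
    high = n_genes_per_cell > thresholds.max_genes_per_cell
    mito = mito_frac > thresholds.max_mito_fraction
    keep_cells = ~(low | high | mito)

    if not keep_cells.any():
        raise QCError("no cells survive QC with the given thresholds")

    filtered = adata[keep_cells].copy()
    Xc = sp.csr_matrix(filtered.layers.get("counts", filtered.X))
    cells_per_gene = np.asarray((Xc > 0).sum(axis=0)).ravel()
    keep_genes = cells_per_gene >= thresholds.min_cells_per_gene
    filtered = filtered[:, keep_genes].copy()

    report = {
        "thresholds": asdict(thresholds),
        "mito_prefix": mito_prefix,
        "n_cells_in": int(adata.n_obs),
        "n_genes_in": int(adata.n_vars),
        "cells_removed_low_genes": int(low.sum()),
        "cells_removed_high_genes": int(high.sum()),
        "cells_removed_mito": int((mito & ~low & ~high).sum()),
        "genes_removed_min_cells": int((~keep_genes).sum()),
        "n_cells_out": int(filtered.n_obs),
        "n_genes_out": int(filtered.n_vars),
    }
    return filtered, report


def normalize(adata: ad.AnnData, scale: float = 1e6) -> ad.AnnData:
    """Scale each cell's counts to sum to ``scale``; add the log1p layer.

    Cells with zero total counts are flagged in ``obs["zero_total"]`` and
    left at zero. ``X`` becomes ln(1 + scaled value); the scaled layer is
    kept as ``layers["cpm"]`` and raw counts as ``layers["counts"]``.
    """
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    counts = sp.csr_matrix(adata.layers.get("counts", adata.X), dtype=np.float64)
    totals = np.asarray(counts.sum(axis=1)).ravel()
    zero = totals == 0
    factors = np.where(zero, 0.0, scale / np.maximum(totals, 1e-300))
    cpm = sp.diags(factors) @ counts
    cpm = sp.csr_matrix(cpm)

    out = adata.copy()
    out.layers["counts"] = sp.csr_matrix(counts.astype(np.int64))
    out.layers["cpm"] = cpm
    out.X = cpm.copy()
    out.X.data = np.log1p(out.X.data)
    out.layers["log1p_cpm"] = out.X.copy()
    out.obs["zero_total"] = zero
    out.uns["layer"] = "log1p_cpm"
    out.uns["normalization_scale"] = float(scale)
    return out


def cluster_cells(
    adata: ad.AnnData,
    n_top_genes: int = 2000,
    n_comps: int = 30,
    k_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Leiden community labels from the standard scanpy pipeline.

    Variable-gene selection (dispersion based), per-gene standardization,
    PCA, kNN graph, Leiden at ``resolution``. Fixed seed gives identical
    labels. Requires the normalized log layer (run :func:`normalize` first).
    """
    import scanpy as sc

    if adata.uns.get("layer") != "log1p_cpm":
        raise ValueError("cluster_cells requires a normalized matrix (run normalize)")
    if k_neighbors >= adata.n_obs:
        raise ValueError(
            f"k_neighbors={k_neighbors} must be < n_cells={adata.n_obs}"
        )

    work = ad.AnnData(X=adata.layers["log1p_cpm"].copy(), obs=adata.obs[[]].copy(),
                      var=adata.var[[]].copy())
    n_top = min(n_top_genes, work.n_vars)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.highly_variable_genes(work, n_top_genes=n_top, flavor="seurat")
        work = work[:, work.var["highly_variable"]].copy()
        sc.pp.scale(work, max_value=10)
        n_comps_eff = int(min(n_comps, work.n_obs - 1, work.n_vars - 1))
        sc.tl.pca(work, n_comps=n_comps_eff, svd_solver="arpack", random_state=seed)
        sc.pp.neighbors(work, n_neighbors=k_neighbors, random_state=seed)
        sc.tl.leiden(
            work,
            resolution=resolution,
            random_state=seed,
            flavor="igraph",
            n_iterations=2,
            directed=False,
        )
    return work.obs["leiden"].astype(str).to_numpy()
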
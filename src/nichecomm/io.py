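"""10x-style triplet IO: MatrixMarket counts + features/barcodes tables.

The on-disk layout mirrors CellRanger's filtered matrix directory:
``matrix.mtx[.gz]`` (genes x cells, 1-based coordinate MatrixMarket),
``features.tsv[.gz]`` and ``barcodes.tsv[.gz]``, plus an optional
``metadata.tsv[.gz]`` with per-cell sample/region/age_months/sex columns.
Internally everything is 0-based and cells are rows (AnnData convention).
"""

from __future__ import annotations

import gzip
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class TripletParseError(ValueError):
    """Malformed 10x triplet directory (dimension mismatch, duplicates, ...)."""


def _find(directory: Path, stem: str) -> Path:
    for suffix in ("", ".gz"):
        p = directory / f"{stem}{suffix}"
        if p.exists():
            return p
    raise FileNotFoundError(f"{stem}[.gz] not found in {directory}")


def _open(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_10x_triplet(directory) -> ad.AnnData:
    """Read a 10x-style triplet directory into an AnnData (cells x genes).

    Validates that the MatrixMarket header matches the feature/barcode table
    lengths and that no coordinate is stated twice.
    """
    directory = Path(directory)
    mtx_path = _find(directory, "matrix.mtx")
    with _open(mtx_path) as fh:
        mat = scipy.io.mmread(fh)
    mat = sp.coo_matrix(mat)

    coords = mat.row.astype(np.int64) * mat.shape[1] + mat.col
    if len(np.unique(coords)) != len(coords):
        dup = np.flatnonzero(pd.Series(coords).duplicated().to_numpy())[0]
        raise TripletParseError(
            f"{mtx_path}: duplicate coordinate at entry {dup + 1} "
            f"(gene {mat.row[dup] + 1}, cell {mat.col[dup] + 1})"
        )

    with _open(_find(directory, "features.tsv")) as fh:
        features = pd.read_csv(fh, sep="\t", header=None)
    with _open(_find(directory, "barcodes.tsv")) as fh:
        barcodes = pd.read_csv(fh, sep="\t", header=None)

    if mat.shape != (len(features), len(barcodes)):
        raise TripletParseError(
            f"{mtx_path}: header says {mat.shape[0]} genes x {mat.shape[1]} cells "
            f"but features.tsv has {len(features)} rows and barcodes.tsv "
            f"{len(barcodes)} rows"
        )

    X = sp.csr_matrix(mat.T)
    obs = pd.DataFrame(index=pd.Index(barcodes[0].astype(str), name="cell_id"))
    try:
        meta_path = _find(directory, "metadata.tsv")
    except FileNotFoundError:
        meta_path = None
    if meta_path is not None:
        with _open(meta_path) as fh:
            meta = pd.read_csv(fh, sep="\t", index_col=0)
        meta.index = meta.index.astype(str)
        missing = obs.index.difference(meta.index)
        if len(missing):
            raise TripletParseError(
                f"{meta_path}: metadata missing for {len(missing)} cells "
                f"(e.g. {missing[0]!r})"
            )
        obs = meta.loc[obs.index]

    if obs.index.duplicated().any() or features[0].duplicated().any():
        raise TripletParseError(f"{directory}: duplicate gene or cell identifiers")

    adata = ad.AnnData(
        X=X,
        obs=obs,
        var=pd.DataFrame(index=pd.Index(features[0].astype(str), name="gene")),
    )
    adata.layers["counts"] = adata.X.copy()
    adata.uns["layer"] = "counts"
    return adata


def write_10x_triplet(adata: ad.AnnData, directory, compress: bool = False) -> None:
    """Write counts as a 10x-style triplet (plus metadata.tsv if obs has columns)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if compress else ""

    counts = adata.layers.get("counts", adata.X)
    mat = sp.coo_matrix(sp.csr_matrix(counts).T)  # genes x cells

    def _writer(path: Path):
        return gzip.open(path, "wb") if compress else open(path, "wb")

    with _writer(directory / f"matrix.mtx{suffix}") as fh:
        scipy.io.mmwrite(fh, mat, field="integer")
    _write_lines(directory / f"features.tsv{suffix}", adata.var_names, compress)
    _write_lines(directory / f"barcodes.tsv{suffix}", adata.obs_names, compress)
    if adata.obs.shape[1]:
        buf = adata.obs.to_csv(sep="\t", index_label="cell_id")
        mode_open = gzip.open if compress else open
        with mode_open(directory / f"metadata.tsv{suffix}", "wt") as fh:
            fh.write(buf)


def _write_lines(path: Path, lines, compress: bool) -> None:
    opener = gzip.open if compress else open
    with opener(path, "wt") as fh:
        for line in lines:
            fh.write(f"{line}\n")
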
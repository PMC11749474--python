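"""Marker-based cluster annotation, TAP/NSC subclustering, composition tables.

Cell types are assigned per cluster (cells inherit their cluster's label):
a cluster's score for a type is the mean standardized expression of the
type's positive markers minus the (weighted) mean of its negative markers,
and the cluster takes the best-scoring type unless that score falls below a
floor, in which case it is "unassigned". Two focused subclusterings mirror
the biology of germinal niches: a 2-way split of TAPs on cell-cycle genes
(cycle_active / cycle_inactive) and a 2-way Ward split of NSCs on curated
receptor genes (receptor-high R_H / receptor-low R_L).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import yaml


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class MarkerSet:
    positive: tuple[str, ...]
    negative: tuple[str, ...] = ()


@dataclass(frozen=True)
class MarkerPanel:
    """Cell type -> positive/negative marker gene sets, tagged by region."""

    types: dict[str, MarkerSet]
    region: str = ""

    def __post_init__(self):
        for name, ms in self.types.items():
            if not ms.positive:
                raise AnnotationError(f"type {name!r} has an empty positive set")
            overlap = set(ms.positive) & set(ms.negative)
            if overlap:
                raise AnnotationError(
                    f"type {name!r}: genes in both positive and negative sets: "
                    f"{sorted(overlap)}"
                )

    @classmethod
    def from_dict(cls, data: dict) -> "MarkerPanel":
        types = {
            name: MarkerSet(tuple(spec.get("positive", ())), tuple(spec.get("negative", ())))
            for name, spec in data["types"].items()
        }
        return cls(types=types, region=data.get("region", ""))

    @classmethod
    def from_yaml(cls, path) -> "MarkerPanel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class TypeAssignment:
    cluster_types: dict[str, str]
    scores: pd.DataFrame  # clusters x types
    cell_types: pd.Series  # per-cell label


@dataclass
class SubclusterResult:
    labels: pd.Series | None  # per-cell subtype label (None when degenerate)
    fractions_by_age: pd.DataFrame | None
    degenerate: bool = False
    extra: dict = field(default_factory=dict)


def _zscore_genes(adata: ad.AnnData, genes: list[str]) -> np.ndarray:
    """Per-gene standardized log expression (cells x genes, dense)."""
    X = adata[:, genes].layers["log1p_cpm"]
    X = np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _present(adata: ad.AnnData, genes, what: str) -> list[str]:
    present = [g for g in genes if g in adata.var_names]
    missing = sorted(set(genes) - set(present))
    if missing:
        warnings.warn(f"{what}: genes absent from matrix, excluded: {missing}")
    return present


def assign_types(
    adata: ad.AnnData,
    labels: np.ndarray,
    panel: MarkerPanel,
    floor: float = 0.0,
    negative_weight: float = 1.0,
) -> TypeAssignment:
    """Assign each cluster the best-scoring panel type (or "unassigned").

    Score(cluster, type) = mean over positive markers of the cluster-mean
    standardized expression, minus ``negative_weight`` times the same for
    negative markers. Ties are broken by lexicographic type name with a
    warning; best scores below ``floor`` leave the cluster unassigned.
    """
    if adata.uns.get("layer") != "log1p_cpm":
        raise ValueError("assign_types requires a normalized matrix")
    labels = np.asarray(labels).astype(str)
    if len(labels) != adata.n_obs:
        raise ValueError("labels must cover every cell")

    gene_cols: dict[str, list[str]] = {}
    for tname, ms in panel.types.items():
        pos = _present(adata, ms.positive, f"{tname} positive markers")
        neg = _present(adata, ms.negative, f"{tname} negative markers")
        if not pos:
            raise AnnotationError(f"all positive markers absent for type {tname!r}")
        gene_cols[tname] = [pos, neg]

    all_genes = sorted({g for p, n in gene_cols.values() for g in p + n})
    z = _zscore_genes(adata, all_genes)
    col = {g: i for i, g in enumerate(all_genes)}

    clusters = sorted(set(labels))
    scores = pd.DataFrame(index=clusters, columns=sorted(panel.types), dtype=float)
    for cl in clusters:
        mask = labels == cl
        zc = z[mask].mean(axis=0)
        for tname, (pos, neg) in gene_cols.items():
            s = float(np.mean([zc[col[g]] for g in pos]))
            if neg:
                s -= negative_weight * float(np.mean([zc[col[g]] for g in neg]))
            scores.loc[cl, tname] = s

    cluster_types: dict[str, str] = {}
    for cl in clusters:
        row = scores.loc[cl]
        best = row.max()
        if best < floor:
            cluster_types[cl] = "unassigned"
            continue
        winners = sorted(row.index[row == best])
        if len(winners) > 1:
            warnings.warn(
                f"cluster {cl}: tie between {winners}; choosing {winners[0]!r}"
            )
        cluster_types[cl] = winners[0]

    cell_types = pd.Series(
        [cluster_types[l] for l in labels], index=adata.obs_names, name="cell_type"
    )
    return TypeAssignment(cluster_types, scores, cell_types)


def _two_way_split(
    features: np.ndarray, method: str, seed: int
) -> np.ndarray | None:
    """k=2 partition of rows; None when the feature matrix is degenerate."""
    if np.allclose(features, features[0]):
        return None
    if method == "kmeans":
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=2, n_init=10, random_state=seed)
        return km.fit_predict(features)
    if method == "ward":
        from sklearn.cluster import AgglomerativeClustering

        return AgglomerativeClustering(n_clusters=2, linkage="ward").fit_predict(features)
    raise ValueError(f"unknown split method {method!r}")


def subcluster_tap(
    adata: ad.AnnData,
    tap_cells,
    cycle_genes,
    seed: int = 0,
    min_cells: int = 20,
) -> SubclusterResult:
    """Split TAPs into cycle_active / cycle_inactive on cell-cycle genes.

    Unsupervised 2-way clustering (k-means) of standardized log expression
    restricted to the cycle gene set; the subcluster with the higher mean
    cycle-gene score is named cycle_active. Fractions are reported per age.
    """
    sub = adata[tap_cells]
    if sub.n_obs < min_cells:
        raise AnnotationError(
            f"need at least {min_cells} TAP cells, got {sub.n_obs}"
        )
    genes = _present(sub, list(cycle_genes), "cycle genes")
    if not genes:
        raise AnnotationError("no cycle genes present in matrix")
    z = _zscore_genes(sub, genes)
    raw = _two_way_split(z, "kmeans", seed)
    if raw is None:
        return SubclusterResult(None, None, degenerate=True)

    mean_score = [z[raw == k].mean() for k in (0, 1)]
    active_id = int(np.argmax(mean_score))
    labels = pd.Series(
        np.where(raw == active_id, "cycle_active", "cycle_inactive"),
        index=sub.obs_names,
        name="tap_subtype",
    )
    fractions = _fractions_by_age(labels, sub.obs, "cycle_active")
    return SubclusterResult(labels, fractions)


def subcluster_receptor(
    adata: ad.AnnData,
    nsc_cells,
    receptor_genes,
    min_cells: int = 20,
    deg_kwargs: dict | None = None,
) -> SubclusterResult:
    """Split NSCs into receptor-high (R_H) / receptor-low (R_L) subpopulations.

    Agglomerative Ward clustering (k=2) on standardized log expression of
    the curated receptor genes; the subcluster with higher mean receptor
    expression is R_H. A per-receptor Wilcoxon differential table
    (R_H vs R_L) is attached in ``extra["receptor_deg"]``.
    """
    from .differential import wilcoxon_deg

    sub = adata[nsc_cells]
    if sub.n_obs < min_cells:
        raise AnnotationError(
            f"need at least {min_cells} NSC cells, got {sub.n_obs}"
        )
    genes = _present(sub, list(receptor_genes), "receptor genes")
    if not genes:
        raise AnnotationError("no receptor genes present in matrix")
    z = _zscore_genes(sub, genes)
    raw = _two_way_split(z, "ward", seed=0)
    if raw is None:
        return SubclusterResult(None, None, degenerate=True)

    expr = sub[:, genes].layers["log1p_cpm"]
    expr = np.asarray(expr.todense()) if hasattr(expr, "todense") else np.asarray(expr)
    mean_expr = [expr[raw == k].mean() for k in (0, 1)]
    high_id = int(np.argmax(mean_expr))
    labels = pd.Series(
        np.where(raw == high_id, "R_H", "R_L"), index=sub.obs_names, name="nsc_subtype"
    )
    fractions = _fractions_by_age(labels, sub.obs, "R_H")

    deg = wilcoxon_deg(
        sub,
        sub.obs_names[labels == "R_H"],
        sub.obs_names[labels == "R_L"],
        genes=genes,
        **(deg_kwargs or {}),
    )
    return SubclusterResult(labels, fractions, extra={"receptor_deg": deg})


def _fractions_by_age(labels: pd.Series, obs: pd.DataFrame, positive: str) -> pd.DataFrame:
    df = pd.DataFrame({"label": labels, "age_months": obs["age_months"].to_numpy()})
    out = (
        df.groupby("age_months", observed=True)["label"]
        .agg(n="size", fraction=lambda s: float((s == positive).mean()))
        .reset_index()
    )
    out["positive_label"] = positive
    return out


def composition_by_sample(cell_types: pd.Series, obs: pd.DataFrame) -> pd.DataFrame:
    """Per-sample cell-type fractions (rows sum to 1), with sample metadata.

    "unassigned" cells appear as their own rows. Empty samples produce no
    rows (with a warning).
    """
    df = obs[["sample"]].copy()
    for extra in ("region", "age_months", "sex"):
        if extra in obs:
            df[extra] = obs[extra]
    df["cell_type"] = cell_types.reindex(obs.index).to_numpy()

    rows = []
    meta_cols = [c for c in ("region", "age_months", "sex") if c in df]
    for sample, grp in df.groupby("sample", observed=True):
        if not len(grp):
            warnings.warn(f"sample {sample!r} has no cells")
            continue
        fracs = grp["cell_type"].value_counts(normalize=True)
        for ct, f in fracs.items():
            row = {"sample": sample, "cell_type": ct, "fraction": float(f),
                   "n_cells": int(len(grp))}
            for c in meta_cols:
                row[c] = grp[c].iloc[0]
            rows.append(row)
    return pd.DataFrame(rows)
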
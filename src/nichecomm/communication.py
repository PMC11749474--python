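"""Ligand-receptor intercellular communication scoring.

For a focal cell population and a partner population, each focal cell's
global communication score is the sum over curated ligand-receptor pairs of
the focal cell's normalized expression of the focal-side gene times the
partner population's mean normalized expression of the partner-side gene:

    S(cell) = sum_p  x_focal(cell, g_focal(p)) * mean_partner(g_partner(p))

With focal role "receptor_side" the focal gene is the receptor and the
partner gene the ligand (and vice versa). Partner means are computed within
each sample and averaged across samples, so unequal sample sizes do not bias
contrasts. A focal cell with score exactly 0 (no pair contributes) is
"silent". Pairwise co-expression structure is summarized by normalized
mutual information (nMI) between discretized ligand and receptor expression,
and a differential LR network combines old-vs-young DEGs of the focal type
with nMI edge weights and the partner types that express the partner gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd


class CommunicationError(ValueError):
    pass


def validate_lr_table(table: pd.DataFrame) -> None:
    for col in ("ligand", "receptor"):
        if col not in table.columns:
            raise CommunicationError(f"LR table missing column {col!r}")
        if table[col].isna().any() or (table[col].astype(str).str.len() == 0).any():
            raise CommunicationError(f"LR table has empty {col} symbols")
    if table.duplicated(subset=["ligand", "receptor"]).any():
        dup = table[table.duplicated(subset=["ligand", "receptor"])].iloc[0]
        raise CommunicationError(
            f"duplicate LR pair ({dup['ligand']}, {dup['receptor']})"
        )
    if not len(table):
        raise CommunicationError("LR table is empty")


def load_lr_table(path=None) -> pd.DataFrame:
    """Read an LR pair TSV (ligand, receptor[, source]); default = shipped table."""
    if path is None:
        from .resources import load_lr_table as _load

        return _load()
    table = pd.read_csv(path, sep="\t")
    validate_lr_table(table)
    return table


@dataclass(frozen=True)
class CommunicationConfig:
    """Focal role and populations for one scoring run.

    focal_role "receptor_side": focal cells are receivers scored on their
    receptor expression against partner ligand means. "ligand_side": focal
    cells are senders scored on their ligand expression against partner
    receptor means.
    """

    focal_role: str
    focal_cells: tuple
    partner_cells: tuple

    def __post_init__(self):
        if self.focal_role not in ("receptor_side", "ligand_side"):
            raise CommunicationError(
                f"focal_role must be receptor_side or ligand_side, got {self.focal_role!r}"
            )
        if not len(self.focal_cells) or not len(self.partner_cells):
            raise CommunicationError("focal and partner populations must be nonempty")


@dataclass
class CommunicationScoreTable:
    """Per-focal-cell global scores and per-pair contributions."""

    global_scores: pd.Series
    pair_contributions: pd.DataFrame  # cells x "ligand->receptor" columns
    partner_means: pd.Series  # partner-side gene -> mean used
    config: CommunicationConfig


def pair_contribution(focal_expr, partner_mean: float) -> np.ndarray:
    """Contribution of one LR pair: focal expression times partner mean."""
    return np.asarray(focal_expr, dtype=float) * float(partner_mean)


def _dense(adata: ad.AnnData, cells, genes, layer: str) -> np.ndarray:
    sub = adata[cells, genes]
    X = sub.layers.get(layer, sub.X)
    return np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X, dtype=float)


def _partner_means(
    adata: ad.AnnData, partner_cells, genes: list[str], layer: str
) -> pd.Series:
    """Per-gene partner mean: within-sample means averaged across samples."""
    sub = adata[partner_cells]
    expr = _dense(sub, sub.obs_names, genes, layer)
    if "sample" in sub.obs:
        samples = sub.obs["sample"].to_numpy()
        per_sample = [
            expr[samples == s].mean(axis=0) for s in pd.unique(samples)
        ]
        means = np.mean(per_sample, axis=0)
    else:
        means = expr.mean(axis=0)
    return pd.Series(means, index=genes)


def global_score(
    adata: ad.AnnData,
    lr_table: pd.DataFrame,
    config: CommunicationConfig,
    layer: str = "cpm",
) -> CommunicationScoreTable:
    """Global communication score per focal cell (sum of pair contributions)."""
    validate_lr_table(lr_table)
    if config.focal_role == "receptor_side":
        focal_col, partner_col = "receptor", "ligand"
    else:
        focal_col, partner_col = "ligand", "receptor"

    pairs = []
    for _, row in lr_table.iterrows():
        fg, pg = row[focal_col], row[partner_col]
        if fg not in adata.var_names or pg not in adata.var_names:
            warnings.warn(
                f"LR pair ({row['ligand']}, {row['receptor']}): gene absent from "
                "matrix, contribution set to 0"
            )
            continue
        pairs.append((row["ligand"], row["receptor"], fg, pg))
    if not pairs:
        raise CommunicationError("no LR pair has both genes present in the matrix")

    focal_genes = [p[2] for p in pairs]
    partner_genes = list(dict.fromkeys(p[3] for p in pairs))
    focal_expr = _dense(adata, list(config.focal_cells), focal_genes, layer)
    pmeans = _partner_means(adata, list(config.partner_cells), partner_genes, layer)

    contribs = {}
    for j, (lig, rec, fg, pg) in enumerate(pairs):
        contribs[f"{lig}->{rec}"] = pair_contribution(focal_expr[:, j], pmeans[pg])
    contrib_df = pd.DataFrame(contribs, index=pd.Index(config.focal_cells))
    scores = contrib_df.sum(axis=1)
    scores.name = "global_score"
    return CommunicationScoreTable(scores, contrib_df, pmeans, config)


def cumulative_fraction(scores) -> pd.DataFrame:
    """Right-continuous ECDF of the scores; last point is (max, 1.0)."""
    s = np.sort(np.asarray(scores, dtype=float))
    if s.size == 0:
        raise ValueError("need at least one score")
    x, counts = np.unique(s, return_counts=True)
    frac = np.cumsum(counts) / s.size
    return pd.DataFrame({"score": x, "cumulative_fraction": frac})


def fraction_silent(scores) -> float:
    """Fraction of focal cells with global score exactly zero."""
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("need at least one score")
    return float((s == 0.0).mean())


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class NMIEdge:
    ligand: str
    receptor: str
    nmi: float
    n_cells: int
    discretization: str
    degenerate: bool = False


def _discretize(x: np.ndarray, how) -> np.ndarray:
    if callable(how):
        return np.asarray(how(x))
    if how == "binary":
        return (np.asarray(x) > 0).astype(int)
    if how == "tertile":
        ranks = pd.Series(x).rank(method="first")
        return pd.qcut(ranks, q=3, labels=False).to_numpy()
    raise ValueError(f"unknown discretizer {how!r}")


def nmi_from_table(table: np.ndarray, normalization: str = "mean") -> tuple[float, bool]:
    """Plug-in normalized mutual information from a joint count table.

    Returns (nMI, degenerate). MI and entropies use natural logs (the base
    cancels in the ratio); a zero-entropy marginal makes nMI 0 by definition
    (degenerate=True). ``normalization`` in {"mean", "min", "sqrt"} divides
    MI by the corresponding combination of the two marginal entropies.
    """
    t = np.asarray(table, dtype=float)
    n = t.sum()
    if n <= 0:
        return 0.0, True
    pij = t / n
    pi = pij.sum(axis=1)
    pj = pij.sum(axis=0)

    def entropy(p):
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    hi, hj = entropy(pi), entropy(pj)
    if hi == 0.0 or hj == 0.0:
        return 0.0, True
    nz = pij > 0
    mi = float((pij[nz] * np.log(pij[nz] / np.outer(pi, pj)[nz])).sum())
    mi = max(mi, 0.0)
    denom = {
        "mean": 0.5 * (hi + hj),
        "min": min(hi, hj),
        "sqrt": float(np.sqrt(hi * hj)),
    }[normalization]
    return min(mi / denom, 1.0), False


def nmi(
    expr_ligand,
    expr_receptor,
    discretizer="binary",
    normalization: str = "mean",
    ligand: str = "",
    receptor: str = "",
) -> NMIEdge:
    """nMI edge between a ligand's and a receptor's per-cell expression.

    The two vectors (equal length >= 10) are discretized (default:
    detected / not detected), tabulated jointly, and the plug-in mutual
    information is normalized by the mean of the two marginal entropies.
    Symmetric in the two vectors; degenerate marginals give nMI 0.
    """
    x = np.asarray(expr_ligand)
    y = np.asarray(expr_receptor)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 10:
        raise ValueError("need at least 10 cells for nMI")
    xd = _discretize(x, discretizer)
    yd = _discretize(y, discretizer)
    table = pd.crosstab(pd.Series(xd), pd.Series(yd)).to_numpy()
    value, degenerate = nmi_from_table(table, normalization)
    note = discretizer if isinstance(discretizer, str) else "custom"
    return NMIEdge(ligand, receptor, value, int(x.size), note, degenerate)


# ----------------------------------------------------------------------
def differential_lr_network(
    adata: ad.AnnData,
    lr_table: pd.DataFrame,
    cell_types: pd.Series,
    young_age,
    old_age,
    focal_type: str,
    q_max: float = 0.05,
    partner_floor: float = 1.0,
    discretizer="binary",
    layer: str = "cpm",
    min_cells: int = 20,
    deg_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Aging-related differential LR network for one focal cell type.

    For every curated pair whose ligand or receptor is differentially
    expressed in the focal type between ``old_age`` and ``young_age``
    (Wilcoxon, BH q <= q_max), report the gene-wise old-vs-young log2FC and
    direction, the pair's nMI (computed over pooled focal + partner cells),
    and the partner cell types whose mean partner-side expression exceeds
    ``partner_floor``. Sorted by the smaller of the two gene q-values.
    """
    from .differential import wilcoxon_deg

    validate_lr_table(lr_table)
    cell_types = cell_types.reindex(adata.obs_names)
    ages = adata.obs["age_months"]
    for age in (young_age, old_age):
        if not (ages == age).any():
            raise CommunicationError(f"age level {age!r} absent from data")

    focal_mask = (cell_types == focal_type).to_numpy()
    young_cells = adata.obs_names[focal_mask & (ages == young_age).to_numpy()]
    old_cells = adata.obs_names[focal_mask & (ages == old_age).to_numpy()]
    if len(young_cells) < min_cells or len(old_cells) < min_cells:
        raise CommunicationError(
            f"need >= {min_cells} focal cells at each age, got "
            f"{len(young_cells)} young / {len(old_cells)} old"
        )

    lr_genes = sorted(
        {g for g in pd.concat([lr_table["ligand"], lr_table["receptor"]])}
        & set(adata.var_names)
    )
    deg = wilcoxon_deg(adata, old_cells, young_cells, genes=lr_genes,
                       layer=layer, **(deg_kwargs or {}))
    deg_idx = deg.set_index("gene")

    partner_mask = ~focal_mask
    rows = []
    for _, pair in lr_table.iterrows():
        lig, rec = pair["ligand"], pair["receptor"]
        if lig not in adata.var_names or rec not in adata.var_names:
            continue
        hits = [g for g in (lig, rec) if g in deg_idx.index and deg_idx.loc[g, "qvalue"] <= q_max]
        if not hits:
            continue

        pooled = adata.obs_names[focal_mask | partner_mask]
        lx = _dense(adata, pooled, [lig], layer).ravel()
        rx = _dense(adata, pooled, [rec], layer).ravel()
        edge = nmi(lx, rx, discretizer=discretizer, ligand=lig, receptor=rec)

        partner_gene = lig  # partners supply the ligand to a receiving focal type
        partner_types = []
        for ptype in sorted(set(cell_types.dropna()) - {focal_type}):
            pcells = adata.obs_names[(cell_types == ptype).to_numpy()]
            if len(pcells) == 0:
                continue
            pmean = _dense(adata, pcells, [partner_gene], layer).mean()
            if pmean > partner_floor:
                partner_types.append(ptype)

        def _gene_stats(g):
            if g in deg_idx.index:
                return float(deg_idx.loc[g, "log2fc"]), float(deg_idx.loc[g, "qvalue"])
            return np.nan, np.nan

        lig_lfc, lig_q = _gene_stats(lig)
        rec_lfc, rec_q = _gene_stats(rec)
        rows.append(
            {
                "ligand": lig,
                "receptor": rec,
                "ligand_log2fc_old_vs_young": lig_lfc,
                "ligand_qvalue": lig_q,
                "receptor_log2fc_old_vs_young": rec_lfc,
                "receptor_qvalue": rec_q,
                "direction": "up in old"
                if np.nansum([lig_lfc if lig in hits else 0,
                              rec_lfc if rec in hits else 0]) > 0
                else "down in old",
                "nmi": edge.nmi,
                "n_cells_nmi": edge.n_cells,
                "partner_types": ",".join(partner_types),
                "min_qvalue": np.nanmin([lig_q, rec_q]),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["ligand", "receptor", "ligand_log2fc_old_vs_young", "ligand_qvalue",
                 "receptor_log2fc_old_vs_young", "receptor_qvalue", "direction",
                 "nmi", "n_cells_nmi", "partner_types", "min_qvalue"],
    )
    if len(out):
        out = out.sort_values("min_qvalue", kind="stable", ignore_index=True)
    return out


def age_trend(
    adata: ad.AnnData,
    gene: str,
    cells,
    expressing_only: bool = False,
    layer: str = "cpm",
) -> tuple[pd.DataFrame, float]:
    """Per-age expression summaries for one gene plus a one-way ANOVA p.

    Summaries (n, mean, median, quartiles) are over all cells of each age or
    only cells with nonzero expression when ``expressing_only``. Ages where
    no cell expresses the gene are reported with n=0 and NaN summaries (and
    excluded from the ANOVA). Returns (summary table, ANOVA p-value).
    """
    import scipy.stats as st

    if gene not in adata.var_names:
        raise ValueError(f"gene {gene!r} absent from matrix")
    sub = adata[cells]
    expr = _dense(sub, sub.obs_names, [gene], layer).ravel()
    ages = sub.obs["age_months"].to_numpy()

    rows = []
    groups = []
    for age in sorted(pd.unique(ages)):
        vals = expr[ages == age]
        if expressing_only:
            vals = vals[vals > 0]
        if len(vals) == 0:
            rows.append({"age_months": age, "n": 0, "mean": np.nan,
                         "median": np.nan, "q25": np.nan, "q75": np.nan,
                         "empty": True})
            continue
        rows.append(
            {
                "age_months": age,
                "n": int(len(vals)),
                "mean": float(vals.mean()),
                "median": float(np.median(vals)),
                "q25": float(np.percentile(vals, 25)),
                "q75": float(np.percentile(vals, 75)),
                "empty": False,
            }
        )
        groups.append(vals)
    if len(groups) >= 2:
        p = float(st.f_oneway(*groups).pvalue)
        if not np.isfinite(p):
            p = 1.0
    else:
        p = np.nan
    return pd.DataFrame(rows), p


def scores_by_age(
    adata: ad.AnnData,
    lr_table: pd.DataFrame,
    focal_mask: np.ndarray,
    partner_mask: np.ndarray,
    focal_role: str = "receptor_side",
    layer: str = "cpm",
) -> dict:
    """Global score tables computed within each age group separately.

    Both focal and partner populations are restricted to cells of that age,
    so the partner means reflect the age-matched niche.
    """
    ages = adata.obs["age_months"].to_numpy()
    out = {}
    for age in sorted(pd.unique(ages)):
        sel = ages == age
        focal = adata.obs_names[np.asarray(focal_mask) & sel]
        partner = adata.obs_names[np.asarray(partner_mask) & sel]
        if len(focal) == 0 or len(partner) == 0:
            continue
        cfg = CommunicationConfig(focal_role, tuple(focal), tuple(partner))
        out[age] = global_score(adata, lr_table, cfg, layer=layer)
    return out
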
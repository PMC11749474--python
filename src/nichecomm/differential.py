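"""Differential statistics: Wilcoxon DEGs with BH FDR, sex-opposite genes,
and one-way ANOVA with Dunnett many-to-one comparisons on composition data.

The DEG test is the two-sided Wilcoxon rank-sum on normalized values, with
exact enumeration of all rank splits when both groups have at most 8 cells
and the tie-corrected normal approximation otherwise. Genes are pre-filtered
by expressing fraction and absolute log2 fold-change (with pseudocount).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import anndata as ad
import numpy as np
import pandas as pd
import scipy.stats as st

EXACT_MAX_N = 8


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def exact_rank_sum_p(a, b) -> float:
    """Two-sided exact Wilcoxon rank-sum p by enumerating all rank splits.

    Uses midranks, so ties are handled; the two-sided p counts splits whose
    rank-sum deviates from its mean by at least the observed deviation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    ranks = st.rankdata(pooled).tolist()
    n_a = len(a)
    obs = sum(ranks[:n_a])
    mean = sum(ranks) * n_a / len(pooled)
    dev = abs(obs - mean)
    count = 0
    total = 0
    for idx in combinations(range(len(pooled)), n_a):
        total += 1
        s = 0.0
        for i in idx:
            s += ranks[i]
        if abs(s - mean) >= dev - 1e-12:
            count += 1
    return count / total


@dataclass(frozen=True)
class DEGFilters:
    min_fraction: float = 0.1
    min_abs_log2fc: float = 0.25
    pseudocount: float = 1.0


def wilcoxon_deg(
    adata: ad.AnnData,
    group_a,
    group_b,
    genes=None,
    min_fraction: float = 0.1,
    min_abs_log2fc: float = 0.25,
    pseudocount: float = 1.0,
    layer: str = "cpm",
) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum DEG table between two cell groups.

    Fold-changes are log2((mean_a + pc) / (mean_b + pc)) on the normalized
    layer. Genes reaching ``min_fraction`` expressing cells in at least one
    group are tested and BH-adjusted together; ``min_abs_log2fc`` then
    selects the reported rows without changing their q-values. Filtering on
    effect size before the adjustment would bias the FDR (selected nulls
    have inflated effects and small p-values), so the fold-change cut is
    applied after it. Returns one row per reported gene with columns
    gene / mean_a / mean_b / log2fc / frac_a / frac_b / pvalue / qvalue /
    direction (sign of log2fc).
    """
    ai = adata.obs_names.get_indexer(pd.Index(group_a))
    bi = adata.obs_names.get_indexer(pd.Index(group_b))
    if len(ai) == 0 or len(bi) == 0 or (ai < 0).any() or (bi < 0).any():
        raise ValueError("both groups must be nonempty subsets of the matrix cells")
    if len(ai) < 3 or len(bi) < 3:
        raise ValueError("each group needs at least 3 cells")

    X = adata.layers.get(layer, adata.X)
    dense = np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)
    if genes is not None:
        cols = adata.var_names.get_indexer(pd.Index(genes))
        if (cols < 0).any():
            missing = [g for g, c in zip(genes, cols) if c < 0]
            raise ValueError(f"genes absent from matrix: {missing}")
        names = list(genes)
        dense = dense[:, cols]
    else:
        names = list(adata.var_names)

    A = dense[ai]
    B = dense[bi]
    mean_a = A.mean(axis=0)
    mean_b = B.mean(axis=0)
    frac_a = (A > 0).mean(axis=0)
    frac_b = (B > 0).mean(axis=0)
    log2fc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))

    tested = np.maximum(frac_a, frac_b) >= min_fraction
    if not (tested & (np.abs(log2fc) >= min_abs_log2fc)).any():
        out = pd.DataFrame(
            columns=["gene", "mean_a", "mean_b", "log2fc", "frac_a", "frac_b",
                     "pvalue", "qvalue", "direction"]
        )
        out.attrs["note"] = "no genes passed the pre-filters"
        return out

    cols = np.flatnonzero(tested)
    if len(ai) <= EXACT_MAX_N and len(bi) <= EXACT_MAX_N:
        pvals = np.array([exact_rank_sum_p(A[:, c], B[:, c]) for c in cols])
    else:
        res = st.mannwhitneyu(A[:, cols], B[:, cols], axis=0,
                              alternative="two-sided", method="asymptotic")
        pvals = np.atleast_1d(res.pvalue)

    out = pd.DataFrame(
        {
            "gene": [names[c] for c in cols],
            "mean_a": mean_a[cols],
            "mean_b": mean_b[cols],
            "log2fc": log2fc[cols],
            "frac_a": frac_a[cols],
            "frac_b": frac_b[cols],
            "pvalue": pvals,
        }
    )
    out["qvalue"] = bh_adjust(out["pvalue"].to_numpy())
    out["direction"] = np.sign(out["log2fc"]).astype(int)
    out = out[np.abs(out["log2fc"]) >= min_abs_log2fc]
    return out.sort_values("pvalue", kind="stable", ignore_index=True)


def opposite_sex_pattern(
    deg_female: pd.DataFrame, deg_male: pd.DataFrame, q_max: float = 0.05
) -> pd.DataFrame:
    """Genes significant in both sexes with opposite fold-change signs.

    Both input tables must come from the same contrast (e.g. old vs young
    within one cell type), one computed in female and one in male cells.
    Sorted by combined significance (product of the two p-values).
    """
    merged = deg_female.merge(
        deg_male, on="gene", suffixes=("_female", "_male"), how="inner"
    )
    keep = (
        (merged["qvalue_female"] <= q_max)
        & (merged["qvalue_male"] <= q_max)
        & (merged["direction_female"] * merged["direction_male"] < 0)
    )
    out = merged[keep].copy()
    out["combined_p"] = out["pvalue_female"] * out["pvalue_male"]
    return out.sort_values("combined_p", kind="stable", ignore_index=True)


@dataclass
class AnovaDunnettResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    baseline: object
    comparisons: pd.DataFrame  # group, statistic, p_adjusted


def proportion_anova_dunnett(
    composition: pd.DataFrame,
    cell_type: str,
    baseline_age,
    group_col: str = "age_months",
    value_col: str = "fraction",
    seed: int = 0,
) -> AnovaDunnettResult:
    """One-way ANOVA on per-sample fractions plus Dunnett many-to-one p-values.

    ``composition`` is a tidy table as produced by
    :func:`nichecomm.annotate.composition_by_sample`; groups are the levels
    of ``group_col`` and the baseline (e.g. the youngest age) is the Dunnett
    control. Each group needs at least two samples.
    """
    sub = composition[composition["cell_type"] == cell_type]
    groups = {g: grp[value_col].to_numpy(dtype=float)
              for g, grp in sub.groupby(group_col, observed=True)}
    if baseline_age not in groups:
        raise ValueError(f"baseline group {baseline_age!r} absent from composition")
    for g, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    if len(groups) < 2:
        raise ValueError("need at least two groups for ANOVA")

    ordered = sorted(groups)
    arrays = [groups[g] for g in ordered]
    f_res = st.f_oneway(*arrays)
    n_total = sum(len(a) for a in arrays)
    dfb, dfw = len(arrays) - 1, n_total - len(arrays)

    others = [g for g in ordered if g != baseline_age]
    if others:
        dres = st.dunnett(
            *[groups[g] for g in others],
            control=groups[baseline_age],
            alternative="two-sided",
            rng=np.random.default_rng(seed),
        )
        comparisons = pd.DataFrame(
            {
                "group": others,
                "statistic": np.atleast_1d(dres.statistic),
                "p_adjusted": np.atleast_1d(dres.pvalue),
            }
        )
    else:
        comparisons = pd.DataFrame(columns=["group", "statistic", "p_adjusted"])

    f_stat = float(f_res.statistic)
    p_val = float(f_res.pvalue)
    if not np.isfinite(f_stat):  # all groups identical -> no variance at all
        f_stat, p_val = 0.0, 1.0
    return AnovaDunnettResult(f_stat, p_val, dfb, dfw, baseline_age, comparisons)
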
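"""Marker-panel annotation, TAP/NSC subclustering and composition tables."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_log_adata
from nichecomm.annotate import (
    AnnotationError,
    MarkerPanel,
    MarkerSet,
    assign_types,
    composition_by_sample,
    subcluster_receptor,
    subcluster_tap,
)


SVZ_LIKE = MarkerPanel(
    types={
        "NSC": MarkerSet(("Thbs4", "Nr2e1", "Igfbp5", "Notum"), ("Aqp4", "Tril", "Grin2c")),
        "Astrocyte": MarkerSet(("Aqp4", "Tril", "Grin2c"), ()),
    },
    region="SVZ",
)


def _panel_adata():
    genes = ["Thbs4", "Nr2e1", "Igfbp5", "Notum", "Aqp4", "Tril", "Grin2c", "other"]
    rng = np.random.default_rng(0)
    X = rng.normal(1.0, 0.05, size=(30, len(genes)))
    # cluster 0: stem markers high, astro markers zero
    X[:10, 0:4] += 3.0
    X[:10, 4:7] = 0.0
    # cluster 1: astro markers high
    X[10:20, 4:7] += 3.0
    # cluster 2: everything zero
    X[20:, :] = 0.0
    return make_log_adata(X, gene_names=genes)


def test_nsc_vs_astrocyte_assignment():
    adata = _panel_adata()
    labels = np.repeat(["0", "1", "2"], 10)
    res = assign_types(adata, labels, SVZ_LIKE)
    assert res.cluster_types["0"] == "NSC"
    assert res.cluster_types["1"] == "Astrocyte"


def test_all_zero_cluster_unassigned():
    adata = _panel_adata()
    labels = np.repeat(["0", "1", "2"], 10)
    res = assign_types(adata, labels, SVZ_LIKE)
    assert res.cluster_types["2"] == "unassigned"


def test_assignment_invariant_to_cluster_relabeling():
    adata = _panel_adata()
    labels = np.repeat(["0", "1", "2"], 10)
    renamed = np.repeat(["z", "a", "m"], 10)
    r1 = assign_types(adata, labels, SVZ_LIKE)
    r2 = assign_types(adata, renamed, SVZ_LIKE)
    assert (r1.cell_types.to_numpy() == r2.cell_types.to_numpy()).all()


def test_tie_broken_lexicographically_with_warning():
    panel = MarkerPanel(types={"B": MarkerSet(("g0",)), "A": MarkerSet(("g0",))})
    X = np.ones((10, 2))
    X[:5, 0] = 2.0
    adata = make_log_adata(X)
    with pytest.warns(UserWarning, match="tie"):
        res = assign_types(adata, np.repeat(["0", "1"], 5), panel)
    assert res.cluster_types["0"] == "A"


def test_missing_marker_warns_all_missing_errors():
    adata = _panel_adata()
    labels = np.repeat(["0", "1", "2"], 10)
    panel = MarkerPanel(
        types={"NSC": MarkerSet(("Thbs4", "ghost_gene"), ())}
    )
    with pytest.warns(UserWarning, match="ghost_gene"):
        assign_types(adata, labels, panel)
    bad = MarkerPanel(types={"NSC": MarkerSet(("ghost1", "ghost2"), ())})
    with pytest.raises(AnnotationError, match="all positive markers absent"):
        assign_types(adata, labels, bad)


def test_panel_invariants():
    with pytest.raises(AnnotationError, match="empty positive"):
        MarkerPanel(types={"T": MarkerSet((), ("a",))})
    with pytest.raises(AnnotationError, match="both positive and negative"):
        MarkerPanel(types={"T": MarkerSet(("a",), ("a",))})


# ------------------------------------------------------- subclustering
def test_subcluster_tap_recovers_planted_split(sim_normalized, phase_gene_lists):
    adata, truth = sim_normalized
    s_genes, g2m = phase_gene_lists
    taps = truth.cells.loc[adata.obs_names]
    tap_cells = adata.obs_names[(taps["cell_type"] == "TAP").to_numpy()]
    res = subcluster_tap(adata, tap_cells, s_genes + g2m, seed=2)
    truth_active = taps.loc[res.labels.index, "subtype"] == "cycle_active"
    agreement = ((res.labels == "cycle_active") == truth_active).mean()
    assert agreement > 0.9
    # cycle_active has the higher mean Ube2c, the marker separating the two
    ube2c = np.asarray(adata[res.labels.index, "Ube2c"].layers["log1p_cpm"].todense()).ravel()
    assert ube2c[(res.labels == "cycle_active").to_numpy()].mean() > \
        ube2c[(res.labels == "cycle_inactive").to_numpy()].mean()


def test_subcluster_degenerate_input_flagged():
    X = np.ones((30, 6))
    adata = make_log_adata(X, obs={"age_months": [2] * 30})
    res = subcluster_tap(adata, adata.obs_names, ["g0", "g1"], seed=0)
    assert res.degenerate
    assert res.labels is None


def test_subcluster_min_cells_enforced():
    X = np.random.default_rng(0).normal(size=(10, 4))
    adata = make_log_adata(X, obs={"age_months": [2] * 10})
    with pytest.raises(AnnotationError, match="at least 20"):
        subcluster_tap(adata, adata.obs_names, ["g0"], seed=0)


def test_subcluster_receptor_high_mean_by_construction(sim_normalized, lr_table):
    adata, truth = sim_normalized
    receptors = [g for g in dict.fromkeys(lr_table["receptor"]) if g in adata.var_names]
    nsc = adata.obs_names[
        (truth.cells.loc[adata.obs_names, "cell_type"] == "NSC").to_numpy()
    ]
    res = subcluster_receptor(adata, nsc, receptors)
    expr = np.asarray(adata[res.labels.index, receptors].layers["log1p_cpm"].todense())
    assert expr[(res.labels == "R_H").to_numpy()].mean() > \
        expr[(res.labels == "R_L").to_numpy()].mean()
    deg = res.extra["receptor_deg"]
    assert set(deg.columns) >= {"gene", "log2fc", "qvalue"}
    # receptor-high cells are enriched for every receptor, so top genes are receptors
    assert set(deg["gene"]) <= set(receptors)


def test_subcluster_labels_stable_under_cell_permutation(sim_normalized, phase_gene_lists):
    adata, truth = sim_normalized
    s_genes, g2m = phase_gene_lists
    taps = truth.cells.loc[adata.obs_names]
    tap_cells = list(adata.obs_names[(taps["cell_type"] == "TAP").to_numpy()])
    res1 = subcluster_tap(adata, tap_cells, s_genes + g2m, seed=2)
    perm = list(reversed(tap_cells))
    res2 = subcluster_tap(adata, perm, s_genes + g2m, seed=2)
    joined = res1.labels.to_frame("a").join(res2.labels.rename("b"))
    assert (joined["a"] == joined["b"]).mean() > 0.95


# ------------------------------------------------------- composition
def test_composition_arithmetic_and_row_sums():
    obs = pd.DataFrame(
        {
            "sample": ["s1"] * 10 + ["s2"] * 4,
            "age_months": [2] * 10 + [7] * 4,
        },
        index=[f"c{i}" for i in range(14)],
    )
    types = pd.Series(["TAP"] * 3 + ["NSC"] * 7 + ["TAP"] * 4, index=obs.index)
    comp = composition_by_sample(types, obs)
    tap_s1 = comp[(comp["sample"] == "s1") & (comp["cell_type"] == "TAP")]["fraction"]
    assert float(tap_s1.iloc[0]) == pytest.approx(0.3)
    sums = comp.groupby("sample")["fraction"].sum()
    np.testing.assert_allclose(sums.to_numpy(), 1.0, atol=1e-9)


def test_composition_tap_fraction_declines_with_age(sim_default):
    """Planted TAP trajectory (0.55x per step) shows up as a monotone decline."""
    cfg, adata, truth = sim_default
    types = truth.cells["cell_type"]
    comp = composition_by_sample(types, adata.obs)
    tap = comp[comp["cell_type"] == "TAP"]
    means = tap.groupby("age_months")["fraction"].mean().sort_index()
    assert (means.diff().dropna() < 0).all()
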
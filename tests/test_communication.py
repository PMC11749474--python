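"""Communication scores, ECDFs, silent fractions, nMI and the LR network."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_log_adata
from nichecomm.communication import (
    CommunicationConfig,
    CommunicationError,
    NMIEdge,
    age_trend,
    cumulative_fraction,
    differential_lr_network,
    fraction_silent,
    global_score,
    nmi,
    nmi_from_table,
    pair_contribution,
    validate_lr_table,
)


def _toy(n_cells=20, n_genes=8, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.poisson(2.0, size=(n_cells, n_genes)).astype(float)
    adata = make_log_adata(np.log1p(X))
    adata.layers["cpm"] = X
    lr = pd.DataFrame(
        {
            "ligand": ["g0", "g1", "g2"],
            "receptor": ["g3", "g4", "g5"],
            "source": "toy",
        }
    )
    return adata, lr


def test_pair_contribution_arithmetic():
    assert pair_contribution(5.0, 10.0) == 50.0
    assert pair_contribution(0.0, 10.0) == 0.0
    np.testing.assert_allclose(pair_contribution([1.0, 2.0], 3.0), [3.0, 6.0])


def test_global_score_matches_bruteforce_double_loop():
    adata, lr = _toy()
    focal = tuple(adata.obs_names[:8])
    partner = tuple(adata.obs_names[8:])
    cfg = CommunicationConfig("receptor_side", focal, partner)
    table = global_score(adata, lr, cfg)

    X = adata.layers["cpm"]
    names = list(adata.var_names)
    obs = list(adata.obs_names)
    for i, cell in enumerate(focal):
        expected = 0.0
        for _, row in lr.iterrows():
            rec_val = X[obs.index(cell), names.index(row["receptor"])]
            lig_mean = np.mean([X[obs.index(p), names.index(row["ligand"])] for p in partner])
            expected += rec_val * lig_mean
        assert table.global_scores.iloc[i] == pytest.approx(expected, abs=1e-9)
    # additivity invariant
    np.testing.assert_allclose(
        table.pair_contributions.sum(axis=1), table.global_scores, atol=1e-9
    )
    assert (table.pair_contributions.to_numpy() >= 0).all()


def test_global_score_scales_linearly_with_partner_ligands():
    adata, lr = _toy(seed=1)
    focal = tuple(adata.obs_names[:10])
    partner_cells = adata.obs_names[10:]
    cfg = CommunicationConfig("receptor_side", focal, tuple(partner_cells))
    base = global_score(adata, lr, cfg).global_scores

    lam = 2.5
    scaled = adata.copy()
    cpm = scaled.layers["cpm"].copy()
    rows = [list(adata.obs_names).index(c) for c in partner_cells]
    cols = [list(adata.var_names).index(g) for g in lr["ligand"]]
    cpm[np.ix_(rows, cols)] *= lam
    scaled.layers["cpm"] = cpm
    up = global_score(scaled, lr, cfg).global_scores
    np.testing.assert_allclose(up, lam * base, rtol=1e-12)


def test_global_score_zero_partner_annihilates():
    adata, lr = _toy(seed=2)
    cpm = adata.layers["cpm"].copy()
    cols = [list(adata.var_names).index(g) for g in lr["ligand"]]
    cpm[:, cols] = 0.0
    adata.layers["cpm"] = cpm
    cfg = CommunicationConfig(
        "receptor_side", tuple(adata.obs_names[:5]), tuple(adata.obs_names[5:])
    )
    scores = global_score(adata, lr, cfg).global_scores
    assert (scores == 0).all()


def test_global_score_missing_genes():
    adata, lr = _toy(seed=3)
    lr2 = lr.copy()
    lr2.loc[0, "ligand"] = "ghost"
    cfg = CommunicationConfig(
        "receptor_side", tuple(adata.obs_names[:5]), tuple(adata.obs_names[5:])
    )
    with pytest.warns(UserWarning, match="ghost"):
        global_score(adata, lr2, cfg)
    all_ghost = lr.assign(ligand=["x1", "x2", "x3"])
    with pytest.raises(CommunicationError, match="no LR pair"), pytest.warns(UserWarning):
        global_score(adata, all_ghost, cfg)


def test_lr_table_validation():
    bad = pd.DataFrame({"ligand": ["a", "a"], "receptor": ["b", "b"]})
    with pytest.raises(CommunicationError, match="duplicate"):
        validate_lr_table(bad)
    with pytest.raises(CommunicationError, match="missing column"):
        validate_lr_table(pd.DataFrame({"ligand": ["a"]}))


def test_communication_config_invariants():
    with pytest.raises(CommunicationError, match="focal_role"):
        CommunicationConfig("sideways", ("c1",), ("c2",))
    with pytest.raises(CommunicationError, match="nonempty"):
        CommunicationConfig("receptor_side", (), ("c2",))


# ------------------------------------------------------------- ECDF
def test_cumulative_fraction_examples():
    ecdf = cumulative_fraction([1, 2, 3, 4])
    at2 = ecdf.loc[ecdf["score"] == 2, "cumulative_fraction"].iloc[0]
    assert at2 == pytest.approx(0.5)
    assert ecdf["cumulative_fraction"].iloc[-1] == 1.0

    flat = cumulative_fraction([3.0, 3.0, 3.0])
    assert len(flat) == 1
    assert flat.iloc[0].tolist() == [3.0, 1.0]


def test_cumulative_fraction_matches_counting_oracle():
    rng = np.random.default_rng(4)
    scores = rng.exponential(size=100)
    ecdf = cumulative_fraction(scores)
    for _, row in ecdf.iloc[::17].iterrows():
        assert row["cumulative_fraction"] == pytest.approx(
            (scores <= row["score"]).mean()
        )


def test_fraction_silent():
    assert fraction_silent([0, 0, 1, 2]) == pytest.approx(0.5)
    assert fraction_silent([1, 2, 3]) == 0.0
    with pytest.raises(ValueError):
        fraction_silent([])


# ------------------------------------------------------------- nMI
def test_nmi_trivial_and_derived_tables():
    x = np.array([0, 0, 0, 1, 1, 1, 0, 1, 0, 1], dtype=float)
    edge = nmi(x, x)
    assert edge.nmi == pytest.approx(1.0)

    assert nmi_from_table([[25, 25], [25, 25]])[0] == pytest.approx(0.0)
    value, degenerate = nmi_from_table([[5, 0], [0, 5]])
    assert value == pytest.approx(1.0)
    assert not degenerate


def test_nmi_independent_null_is_small():
    rng = np.random.default_rng(5)
    x = (rng.random(10_000) < 0.5).astype(float)
    y = (rng.random(10_000) < 0.5).astype(float)
    assert nmi(x, y).nmi < 0.01


def test_nmi_symmetry_range_and_sklearn_agreement():
    from sklearn.metrics import normalized_mutual_info_score

    rng = np.random.default_rng(6)
    for _ in range(20):
        x = rng.poisson(1.0, 50).astype(float)
        y = rng.poisson(1.0, 50).astype(float)
        e1 = nmi(x, y)
        e2 = nmi(y, x)
        assert e1.nmi == pytest.approx(e2.nmi, abs=1e-12)
        assert 0.0 <= e1.nmi <= 1.0
        if not e1.degenerate:
            sk = normalized_mutual_info_score(
                (x > 0).astype(int), (y > 0).astype(int), average_method="arithmetic"
            )
            assert e1.nmi == pytest.approx(sk, abs=1e-9)


def test_nmi_all_small_tables_match_plugin_oracle():
    """Plug-in nMI on every 2x2 table with margins <= 10 matches the formula."""
    from math import log

    def oracle(a, b, c, d):
        n = a + b + c + d
        if n == 0:
            return 0.0, True
        pij = [v / n for v in (a, b, c, d)]
        pi = [pij[0] + pij[1], pij[2] + pij[3]]
        pj = [pij[0] + pij[2], pij[1] + pij[3]]
        h = lambda ps: -sum(p * log(p) for p in ps if p > 0)
        hi, hj = h(pi), h(pj)
        if hi == 0 or hj == 0:
            return 0.0, True
        outer = [pi[0] * pj[0], pi[0] * pj[1], pi[1] * pj[0], pi[1] * pj[1]]
        mi = sum(p * log(p / o) for p, o in zip(pij, outer) if p > 0)
        return min(max(mi, 0.0) / (0.5 * (hi + hj)), 1.0), False

    for a in range(6):
        for b in range(6):
            for c in range(6):
                for d in range(6):
                    got = nmi_from_table([[a, b], [c, d]])
                    expected = oracle(a, b, c, d)
                    assert got[1] == expected[1]
                    assert got[0] == pytest.approx(expected[0], abs=1e-12)


def test_nmi_degenerate_and_errors():
    x = np.zeros(10)
    y = np.ones(10)
    edge = nmi(x, y)
    assert edge.nmi == 0.0 and edge.degenerate
    with pytest.raises(ValueError, match="length mismatch"):
        nmi(np.zeros(10), np.zeros(11))
    with pytest.raises(ValueError, match="at least 10"):
        nmi(np.zeros(5), np.zeros(5))


# ------------------------------------------------ differential network
def _aged_adata(receptor_lfc_per_step=0.0, seed=0, n=120):
    rng = np.random.default_rng(seed)
    genes = ["lig", "rec", "bg1", "bg2"]
    ages = np.repeat([2, 19], n)
    mu = np.full((2 * n, 4), 5.0)
    mu[ages == 19, 1] *= 2.0 ** (receptor_lfc_per_step)
    X = rng.poisson(mu).astype(float)
    adata = make_log_adata(np.log1p(X), gene_names=genes,
                           obs={"age_months": ages,
                                "sample": [f"s{a}" for a in ages],
                                "sex": "F"})
    adata.layers["cpm"] = X
    types = pd.Series(["NSC"] * n + ["NSC"] * n, index=adata.obs_names)
    # half the cells at each age act as niche partners
    types.iloc[: n // 2] = "Astrocyte"
    types.iloc[n : n + n // 2] = "Astrocyte"
    lr = pd.DataFrame({"ligand": ["lig"], "receptor": ["rec"], "source": "toy"})
    return adata, types, lr


def test_network_empty_without_differential_genes():
    adata, types, lr = _aged_adata(receptor_lfc_per_step=0.0)
    net = differential_lr_network(adata, lr, types, 2, 19, "NSC")
    assert len(net) == 0


def test_network_flags_planted_receptor_knockdown():
    adata, types, lr = _aged_adata(receptor_lfc_per_step=-2.0, seed=1)
    net = differential_lr_network(adata, lr, types, 2, 19, "NSC")
    assert len(net) == 1
    row = net.iloc[0]
    assert row["direction"] == "down in old"
    assert row["receptor_log2fc_old_vs_young"] < -1.0
    assert 0.0 <= row["nmi"] <= 1.0


def test_network_missing_age_errors():
    adata, types, lr = _aged_adata()
    with pytest.raises(CommunicationError, match="age level"):
        differential_lr_network(adata, lr, types, 2, 12, "NSC")


# --------------------------------------------------------- age trends
def test_age_trend_conditioning_arithmetic():
    X = np.array([[0.0], [0.0], [4.0], [4.0]])
    adata = make_log_adata(np.log1p(X), gene_names=["g"],
                           obs={"age_months": [2, 2, 2, 2]})
    adata.layers["cpm"] = X
    with_zero, _ = age_trend(adata, "g", adata.obs_names, expressing_only=False)
    only_expr, _ = age_trend(adata, "g", adata.obs_names, expressing_only=True)
    assert with_zero["mean"].iloc[0] == pytest.approx(2.0)
    assert only_expr["mean"].iloc[0] == pytest.approx(4.0)


def test_age_trend_null_anova_calibrated():
    rng = np.random.default_rng(7)
    n_small = 0
    for rep in range(100):
        X = rng.poisson(3.0, size=(120, 1)).astype(float)
        adata = make_log_adata(np.log1p(X), gene_names=["g"],
                               obs={"age_months": np.repeat([2, 7, 12, 19], 30)})
        adata.layers["cpm"] = X
        _, p = age_trend(adata, "g", adata.obs_names)
        n_small += p < 0.05
    assert n_small <= 10  # ~5 expected at the null


def test_age_trend_planted_decline_monotone(sim_normalized):
    adata, truth = sim_normalized
    nsc = adata.obs_names[(truth.cells.loc[adata.obs_names, "cell_type"] == "NSC").to_numpy()]
    table, p = age_trend(adata, "Ntrk2", nsc)
    means = table.set_index("age_months")["mean"]
    assert (means.diff().dropna() < 0).all()
    assert p < 0.01
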
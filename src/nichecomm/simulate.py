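"""Synthetic neurogenic-niche scRNA-seq generator.

Generates UMI-like count matrices with the statistical structure the
downstream analysis assumes: discrete cell types with marker programs,
age-dependent composition drift, a cell-cycle program splitting transient
amplifying progenitors (TAPs) into cycling/non-cycling subtypes,
receptor-high vs receptor-low NSC subpopulations, sex-by-age interaction
genes with opposite signs in females and males, latent ligand-receptor
coupling between sender and receiver populations, and zero inflation from
logistic dropout.

Counts are negative-binomial (gamma-Poisson) draws parameterized by mean and
inverse-dispersion theta (var = mu + mu^2/theta; theta = inf gives Poisson),
thinned by Bernoulli dropout whose probability is logistic in the log mean.
Every planted effect is recorded in a :class:`SyntheticTruth` object so that
recovery can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

__all__ = [
    "CellTypeSpec",
    "CycleSpec",
    "ReceptorSpec",
    "SexSpec",
    "AgeTrendSpec",
    "LRCoupling",
    "SilentSpec",
    "NicheSimulationConfig",
    "SyntheticTruth",
    "ConfigError",
    "couple_lr",
    "simulate_niche",
    "nb_counts",
    "default_config",
]


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class CellTypeSpec:
    """One cell type: expected cells per sample, age drift, marker program.

    ``markers`` maps gene symbol -> log2 fold-change applied to that gene's
    mean in cells of this type. ``decline_per_step`` multiplies the expected
    cell count once per age step (values < 1 model age-declining populations).
    """

    name: str
    n_per_sample: float
    decline_per_step: float = 1.0
    markers: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class CycleSpec:
    """Cell-cycle program planted in one cell type (default TAPs).

    A fraction of the cells is set "cycle active"; active cells up-shift the
    whole cycle gene set (S union G2M) by ``log2_effect`` — proliferating
    cells express cycle genes broadly — and are assigned phase S or G2M with
    equal probability, with an extra ``phase_log2_boost`` on their own phase
    set so the two phases remain distinguishable. ``active_fraction`` may be
    a scalar or a mapping age -> fraction.
    """

    s_genes: tuple[str, ...]
    g2m_genes: tuple[str, ...]
    active_fraction: float | Mapping[int, float] = 0.6
    log2_effect: float = 2.0
    phase_log2_boost: float = 1.0
    cell_type: str = "TAP"

    def fraction_at(self, age: int) -> float:
        if isinstance(self.active_fraction, Mapping):
            return float(self.active_fraction[age])
        return float(self.active_fraction)


@dataclass(frozen=True)
class ReceptorSpec:
    """Receptor-high subpopulation planted in one cell type (default NSCs).

    ``high_fraction`` may be a scalar or a mapping age -> fraction; an
    age-declining mapping models the exhaustion of the primed (receptor-high)
    pool with age, which then drives an age decline of mean receptor
    expression through composition rather than per-cell shifts.
    """

    genes: tuple[str, ...]
    high_fraction: float | Mapping[int, float] = 0.4
    log2_effect: float = 3.0
    cell_type: str = "NSC"

    def fraction_at(self, age: int) -> float:
        if isinstance(self.high_fraction, Mapping):
            return float(self.high_fraction[age])
        return float(self.high_fraction)


@dataclass(frozen=True)
class SexSpec:
    """Sex-by-age interaction genes with opposite signs in the two sexes.

    At age index ``i`` (of ``n`` ages) the log2 shift is
    ``+log2_effect * i/(n-1)`` in females and the negative in males, so the
    two sexes drift apart monotonically with age and their old-vs-young
    fold-changes have equal magnitude and opposite sign.
    """

    genes: tuple[str, ...]
    log2_effect: float = 2.0
    cell_type: str = "NSC"


@dataclass(frozen=True)
class AgeTrendSpec:
    """Deterministic per-age-step log2 trend for one gene in one cell type."""

    gene: str
    cell_type: str
    log2fc_per_step: float


@dataclass(frozen=True)
class LRCoupling:
    """Latent coupling between a ligand in senders and a receptor in receivers.

    Sender cell j and receiver cell j of a sample share a standard-normal
    latent activity u_j; both gene means are multiplied by
    exp(rho*sigma*u_j - (rho*sigma)^2/2). rho=0 leaves means unchanged,
    rho=1 makes the two factors identical.
    """

    ligand: str
    receptor: str
    sender: str
    receiver: str
    rho: float
    sigma: float = 1.0


@dataclass(frozen=True)
class SilentSpec:
    """Plant a fraction of cells (per listed type) expressing none of ``genes``."""

    cell_types: tuple[str, ...]
    genes: tuple[str, ...]
    fraction: float


@dataclass
class NicheSimulationConfig:
    """Full generative description of one synthetic niche dataset.

    One sample is generated per (age, sex) combination. Gene names are the
    union of all names mentioned in any spec plus autogenerated filler
    symbols up to ``n_genes``; base means are log-normal draws overridden by
    ``gene_base_means`` for named genes.
    """

    cell_types: Sequence[CellTypeSpec]
    age_months: tuple[int, ...] = (2, 7, 12, 19)
    sexes: tuple[str, ...] = ("F", "M")
    region: str = "SVZ"
    n_genes: int = 1000
    gene_names: Sequence[str] | None = None
    gene_base_means: Mapping[str, float] = field(default_factory=dict)
    base_mean_log_mu: float = math.log(0.3)
    base_mean_log_sigma: float = 1.0
    cycle: CycleSpec | None = None
    receptor: ReceptorSpec | None = None
    sex: SexSpec | None = None
    age_trends: tuple[AgeTrendSpec, ...] = ()
    couplings: tuple[LRCoupling, ...] = ()
    silent: SilentSpec | None = None
    inverse_dispersion: float = 2.0
    dropout_midpoint: float | None = 0.0
    dropout_slope: float = 1.0
    library_sigma: float = 0.3
    seed: int = 0

    # ------------------------------------------------------------------
    def named_genes(self) -> list[str]:
        """All gene symbols referenced anywhere in the config, in a stable order."""
        seen: dict[str, None] = {}

        def add(names) -> None:
            for g in names:
                seen.setdefault(g, None)

        for ct in self.cell_types:
            add(ct.markers)
        if self.cycle:
            add(self.cycle.s_genes)
            add(self.cycle.g2m_genes)
        if self.receptor:
            add(self.receptor.genes)
        if self.sex:
            add(self.sex.genes)
        for t in self.age_trends:
            add([t.gene])
        for c in self.couplings:
            add([c.ligand, c.receptor])
        if self.silent:
            add(self.silent.genes)
        add(self.gene_base_means)
        return list(seen)

    def resolved_gene_names(self) -> list[str]:
        if self.gene_names is not None:
            return list(self.gene_names)
        named = self.named_genes()
        used = set(named)
        fillers: list[str] = []
        i = 0
        while len(named) + len(fillers) < self.n_genes:
            name = f"Gene{i:04d}"
            if name not in used:
                fillers.append(name)
            i += 1
        return named + fillers

    def validate(self) -> None:
        if not self.cell_types:
            raise ConfigError("at least one cell type is required")
        if list(self.age_months) != sorted(set(self.age_months)):
            raise ConfigError("age_months must be strictly increasing")
        for ct in self.cell_types:
            if ct.n_per_sample < 0:
                raise ConfigError(f"negative expected count for type {ct.name!r}")
        if self.silent and not 0.0 <= self.silent.fraction <= 1.0:
            raise ConfigError(
                f"silent fraction must be in [0, 1], got {self.silent.fraction}"
            )
        if self.receptor:
            for age in self.age_months:
                f = self.receptor.fraction_at(age)
                if not 0.0 <= f <= 1.0:
                    raise ConfigError(
                        f"receptor-high fraction at age {age} out of [0, 1]"
                    )
        if self.cycle:
            for age in self.age_months:
                f = self.cycle.fraction_at(age)
                if not 0.0 <= f <= 1.0:
                    raise ConfigError(f"cycle active fraction at age {age} out of [0, 1]")
        for c in self.couplings:
            if not 0.0 <= c.rho <= 1.0:
                raise ConfigError(f"coupling rho must be in [0, 1], got {c.rho}")
        named = self.named_genes()
        if len(named) > self.n_genes:
            raise ConfigError(
                f"{len(named)} named genes exceed n_genes={self.n_genes}"
            )
        if self.gene_names is not None:
            universe = set(self.gene_names)
            for g in named:
                if g not in universe:
                    raise ConfigError(f"unknown gene name in spec: {g!r}")
        type_names = {ct.name for ct in self.cell_types}
        refs = []
        if self.cycle:
            refs.append(self.cycle.cell_type)
        if self.receptor:
            refs.append(self.receptor.cell_type)
        if self.sex:
            refs.append(self.sex.cell_type)
        refs += [t.cell_type for t in self.age_trends]
        refs += [c.sender for c in self.couplings] + [c.receiver for c in self.couplings]
        if self.silent:
            refs += list(self.silent.cell_types)
        for t in refs:
            if t not in type_names:
                raise ConfigError(f"unknown cell type in spec: {t!r}")

    # -- YAML round trip -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["cell_types"] = [asdict(ct) for ct in self.cell_types]
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: Mapping) -> "NicheSimulationConfig":
        d = dict(d)
        d["cell_types"] = [CellTypeSpec(**ct) for ct in d["cell_types"]]
        for key, klass in [
            ("cycle", CycleSpec),
            ("receptor", ReceptorSpec),
            ("sex", SexSpec),
            ("silent", SilentSpec),
        ]:
            if d.get(key) is not None and not isinstance(d[key], klass):
                sub = dict(d[key])
                for f_, v in sub.items():
                    if isinstance(v, list):
                        sub[f_] = tuple(v)
                d[key] = klass(**sub)
        if "age_trends" in d:
            d["age_trends"] = tuple(
                t if isinstance(t, AgeTrendSpec) else AgeTrendSpec(**t)
                for t in d["age_trends"]
            )
        if "couplings" in d:
            d["couplings"] = tuple(
                c if isinstance(c, LRCoupling) else LRCoupling(**c)
                for c in d["couplings"]
            )
        for key in ("age_months", "sexes"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "NicheSimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SyntheticTruth:
    """Planted ground truth for one simulated dataset.

    cells        one row per cell (index = cell id): sample, cell_type,
                 subtype, phase, silent flag, order_in_group (generation-order
                 index within the (sample, cell_type) block, which aligns
                 sender cell j with receiver cell j for LR couplings).
    effects      one row per planted differential effect
                 (kind, contrast, cell_type, gene, log2fc).
    composition  configured per-sample type proportions plus realized counts.
    couplings    realized ligand-receptor couplings.
    """

    cells: pd.DataFrame
    effects: pd.DataFrame
    composition: pd.DataFrame
    couplings: pd.DataFrame

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(outdir / "truth_cells.tsv", sep="\t")
        self.effects.to_csv(outdir / "truth_effects.tsv", sep="\t", index=False)
        self.composition.to_csv(outdir / "truth_composition.tsv", sep="\t", index=False)
        self.couplings.to_csv(outdir / "truth_couplings.tsv", sep="\t", index=False)


# ----------------------------------------------------------------------
def couple_lr(
    latent: np.ndarray,
    ligand_means: np.ndarray,
    receptor_means: np.ndarray,
    rho: float,
    sigma: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Adjust per-cell ligand/receptor means by a shared latent factor.

    Cell j on the ligand side and cell j on the receptor side share the
    latent draw ``latent[j]``; both means are multiplied by
    ``exp(rho*sigma*latent - (rho*sigma)**2 / 2)`` (unit-mean lognormal).
    ``rho = 0`` returns the means unchanged; ``rho = 1`` applies an identical
    factor to both sides.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"coupling strength rho must be in [0, 1], got {rho}")
    latent = np.atleast_1d(np.asarray(latent, dtype=float))
    ligand_means = np.atleast_1d(np.asarray(ligand_means, dtype=float))
    receptor_means = np.atleast_1d(np.asarray(receptor_means, dtype=float))
    if len(latent) < max(len(ligand_means), len(receptor_means)):
        raise ValueError("latent draw shorter than the cell vectors it couples")
    s = rho * sigma
    factor = np.exp(s * latent - 0.5 * s * s)
    return (
        ligand_means * factor[: len(ligand_means)],
        receptor_means * factor[: len(receptor_means)],
    )


def nb_counts(mu: np.ndarray, theta: float, rng: np.random.Generator) -> np.ndarray:
    """Gamma-Poisson (negative binomial) draws with mean mu and var mu + mu^2/theta."""
    mu = np.asarray(mu, dtype=float)
    if not np.isfinite(theta):
        return rng.poisson(mu)
    lam = rng.gamma(theta, mu / theta)
    return rng.poisson(lam)


def _dropout_keep_mask(
    mu: np.ndarray, midpoint: float, slope: float, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli keep mask; dropout probability is logistic in log mean."""
    with np.errstate(divide="ignore"):
        logmu = np.log(mu)
    # p_drop = expit(-slope * (log mu - midpoint)); mu = 0 is already zero.
    z = slope * (logmu - midpoint)
    p_drop = np.where(np.isfinite(z), 1.0 / (1.0 + np.exp(np.clip(z, -50, 50))), 0.0)
    return rng.random(mu.shape) >= p_drop


# ----------------------------------------------------------------------
def simulate_niche(config: NicheSimulationConfig) -> tuple[ad.AnnData, SyntheticTruth]:
    """Simulate a niche dataset and its ground truth.

    Returns an :class:`anndata.AnnData` with integer counts in ``X`` (CSR
    sparse) and per-cell metadata (sample, region, age_months, sex) in
    ``obs``, plus the matching :class:`SyntheticTruth`. Identical configs
    (including seed) give bit-identical output; cell order is randomized.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = config.resolved_gene_names()
    gene_idx = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    base = rng.lognormal(config.base_mean_log_mu, config.base_mean_log_sigma, n_genes)
    for g, m in config.gene_base_means.items():
        base[gene_idx[g]] = m

    n_ages = len(config.age_months)
    theta = config.inverse_dispersion

    count_blocks: list[sp.csr_matrix] = []
    obs_rows: list[dict] = []
    truth_rows: list[dict] = []
    comp_rows: list[dict] = []

    for age_idx, age in enumerate(config.age_months):
        for sex in config.sexes:
            sample = f"{config.region}_{age}m_{sex}"
            expected = np.array(
                [ct.n_per_sample * ct.decline_per_step**age_idx for ct in config.cell_types]
            )
            total = int(round(expected.sum()))
            props = expected / expected.sum()
            n_by_type = rng.multinomial(total, props)
            for ct, n_t, p_t in zip(config.cell_types, n_by_type, props):
                comp_rows.append(
                    {
                        "sample": sample,
                        "region": config.region,
                        "age_months": age,
                        "sex": sex,
                        "cell_type": ct.name,
                        "configured_fraction": p_t,
                        "realized_count": int(n_t),
                    }
                )

            sample_mu: list[np.ndarray] = []
            sample_meta: list[pd.DataFrame] = []
            for ct, n_t in zip(config.cell_types, n_by_type):
                if n_t == 0:
                    continue
                mu = np.tile(base, (n_t, 1))
                for g, lfc in ct.markers.items():
                    mu[:, gene_idx[g]] *= 2.0**lfc
                for tr in config.age_trends:
                    if tr.cell_type == ct.name:
                        mu[:, gene_idx[tr.gene]] *= 2.0 ** (tr.log2fc_per_step * age_idx)
                if config.sex and config.sex.cell_type == ct.name and n_ages > 1:
                    sign = 1.0 if sex == config.sexes[0] else -1.0
                    shift = config.sex.log2_effect * age_idx / (n_ages - 1)
                    cols = [gene_idx[g] for g in config.sex.genes]
                    mu[:, cols] *= 2.0 ** (sign * shift)

                subtype = np.full(n_t, "", dtype=object)
                phase = np.full(n_t, "G1", dtype=object)
                if config.cycle and config.cycle.cell_type == ct.name:
                    active = rng.random(n_t) < config.cycle.fraction_at(age)
                    subtype[:] = np.where(active, "cycle_active", "cycle_inactive")
                    s_cols = [gene_idx[g] for g in config.cycle.s_genes]
                    g2m_cols = [gene_idx[g] for g in config.cycle.g2m_genes]
                    in_s = active & (rng.random(n_t) < 0.5)
                    in_g2m = active & ~in_s
                    phase[in_s] = "S"
                    phase[in_g2m] = "G2M"
                    union_cols = sorted(set(s_cols) | set(g2m_cols))
                    mu[np.ix_(active, union_cols)] *= 2.0**config.cycle.log2_effect
                    mu[np.ix_(in_s, s_cols)] *= 2.0**config.cycle.phase_log2_boost
                    mu[np.ix_(in_g2m, g2m_cols)] *= 2.0**config.cycle.phase_log2_boost
                if config.receptor and config.receptor.cell_type == ct.name:
                    high = rng.random(n_t) < config.receptor.fraction_at(age)
                    subtype[:] = np.where(high, "R_H", "R_L")
                    cols = [gene_idx[g] for g in config.receptor.genes]
                    mu[np.ix_(high, cols)] *= 2.0**config.receptor.log2_effect

                silent = np.zeros(n_t, dtype=bool)
                if config.silent and ct.name in config.silent.cell_types:
                    silent = rng.random(n_t) < config.silent.fraction
                    cols = [gene_idx[g] for g in config.silent.genes]
                    mu[np.ix_(silent, cols)] = 0.0

                sample_mu.append(mu)
                sample_meta.append(
                    pd.DataFrame(
                        {
                            "sample": sample,
                            "region": config.region,
                            "age_months": age,
                            "sex": sex,
                            "cell_type": ct.name,
                            "subtype": subtype,
                            "phase": phase,
                            "silent_planted": silent,
                            "order_in_group": np.arange(n_t),
                        }
                    )
                )

            meta = pd.concat(sample_meta, ignore_index=True)
            mu_all = np.vstack(sample_mu)

            # LR couplings: sender cell j shares a latent with receiver cell j.
            for coup in config.couplings:
                s_rows = np.flatnonzero(meta["cell_type"].to_numpy() == coup.sender)
                r_rows = np.flatnonzero(meta["cell_type"].to_numpy() == coup.receiver)
                n_pairs = max(len(s_rows), len(r_rows))
                if n_pairs == 0:
                    continue
                latent = rng.standard_normal(n_pairs)
                lig, rec = couple_lr(
                    latent,
                    mu_all[s_rows, gene_idx[coup.ligand]],
                    mu_all[r_rows, gene_idx[coup.receptor]],
                    coup.rho,
                    coup.sigma,
                )
                mu_all[s_rows, gene_idx[coup.ligand]] = lig
                mu_all[r_rows, gene_idx[coup.receptor]] = rec

            if config.library_sigma > 0:
                lib = np.exp(
                    rng.normal(
                        -0.5 * config.library_sigma**2,
                        config.library_sigma,
                        mu_all.shape[0],
                    )
                )
                mu_all *= lib[:, None]

            counts = nb_counts(mu_all, theta, rng)
            if config.dropout_midpoint is not None:
                keep = _dropout_keep_mask(
                    mu_all, config.dropout_midpoint, config.dropout_slope, rng
                )
                counts = counts * keep

            count_blocks.append(sp.csr_matrix(counts.astype(np.int32)))
            obs_rows.append(meta)

    X = sp.vstack(count_blocks, format="csr")
    meta_all = pd.concat(obs_rows, ignore_index=True)

    perm = rng.permutation(X.shape[0])
    X = X[perm]
    meta_all = meta_all.iloc[perm].reset_index(drop=True)
    meta_all.index = [f"cell_{i:05d}" for i in range(len(meta_all))]
    meta_all.index.name = "cell_id"

    adata = ad.AnnData(
        X=X,
        obs=meta_all[["sample", "region", "age_months", "sex"]].copy(),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    adata.layers["counts"] = adata.X.copy()
    adata.uns["layer"] = "counts"

    truth_cells = meta_all[
        ["sample", "cell_type", "subtype", "phase", "silent_planted", "order_in_group"]
    ].copy()

    effects = _effects_table(config)
    comp = pd.DataFrame(comp_rows)
    coups = pd.DataFrame(
        [asdict(c) for c in config.couplings],
        columns=["ligand", "receptor", "sender", "receiver", "rho", "sigma"],
    )
    truth = SyntheticTruth(truth_cells, effects, comp, coups)
    return adata, truth


def _effects_table(config: NicheSimulationConfig) -> pd.DataFrame:
    rows = []
    for ct in config.cell_types:
        for g, lfc in ct.markers.items():
            rows.append(
                dict(kind="marker", contrast=f"{ct.name}_vs_rest", cell_type=ct.name,
                     gene=g, log2fc=lfc)
            )
    if config.cycle:
        for g in set(config.cycle.s_genes) | set(config.cycle.g2m_genes):
            rows.append(dict(kind="cycle_active", contrast="active_vs_inactive",
                             cell_type=config.cycle.cell_type, gene=g,
                             log2fc=config.cycle.log2_effect))
        for g in config.cycle.s_genes:
            rows.append(dict(kind="cycle_s", contrast="S_vs_G2M",
                             cell_type=config.cycle.cell_type, gene=g,
                             log2fc=config.cycle.phase_log2_boost))
        for g in config.cycle.g2m_genes:
            rows.append(dict(kind="cycle_g2m", contrast="G2M_vs_S",
                             cell_type=config.cycle.cell_type, gene=g,
                             log2fc=config.cycle.phase_log2_boost))
    if config.receptor:
        for g in config.receptor.genes:
            rows.append(dict(kind="receptor_high", contrast="R_H_vs_R_L",
                             cell_type=config.receptor.cell_type, gene=g,
                             log2fc=config.receptor.log2_effect))
    if config.sex:
        old, young = config.age_months[-1], config.age_months[0]
        contrast = f"{old}m_vs_{young}m"
        for g in config.sex.genes:
            rows.append(dict(kind="sex_opposite_F", contrast=contrast,
                             cell_type=config.sex.cell_type, gene=g,
                             log2fc=config.sex.log2_effect))
            rows.append(dict(kind="sex_opposite_M", contrast=contrast,
                             cell_type=config.sex.cell_type, gene=g,
                             log2fc=-config.sex.log2_effect))
    n_steps = len(config.age_months) - 1
    for tr in config.age_trends:
        rows.append(dict(kind="age_trend",
                         contrast=f"{config.age_months[-1]}m_vs_{config.age_months[0]}m",
                         cell_type=tr.cell_type, gene=tr.gene,
                         log2fc=tr.log2fc_per_step * n_steps))
    return pd.DataFrame(rows, columns=["kind", "contrast", "cell_type", "gene", "log2fc"])


# ----------------------------------------------------------------------
def default_config(seed: int = 0) -> NicheSimulationConfig:
    """Default SVZ-like study conditions: 4 ages x 2 sexes, 7 cell types.

    Populations, programs and effect sizes emulate the qualitative structure
    of an aging SVZ niche: sharply declining TAPs and neuroblasts, a 60/40
    cycling/non-cycling TAP split, a 40% receptor-high NSC subpopulation,
    14 sex-opposite interaction genes, an age-declining NSC receptor/ligand
    program (with Apoe rising in the niche), 35% of niche sender cells
    planted silent for every curated ligand, and latent Bdnf-Ntrk2 /
    Mdk-Ptprz1 couplings.
    """
    from .resources import load_lr_table, load_gene_list, load_marker_panel

    lr = load_lr_table()
    ligands = list(dict.fromkeys(lr["ligand"]))
    receptors = list(dict.fromkeys(lr["receptor"]))
    s_genes = tuple(load_gene_list("s_genes"))
    g2m_genes = tuple(load_gene_list("g2m_genes"))
    panel = load_marker_panel("SVZ")

    # Each type's program = its panel markers (strong) plus a block of
    # dedicated program genes (moderate): cell identities in real scRNA-seq
    # are transcriptome-wide, not confined to a handful of markers.
    marker_lfc = 3.0
    program_lfc = 2.0
    n_program_genes = 30
    markers = {
        t: {g: marker_lfc for g in spec.positive}
        | {f"{t}Prog{i:02d}": program_lfc for i in range(n_program_genes)}
        for t, spec in panel.types.items()
    }

    sex_genes = ("Prdx1",) + tuple(f"Gene{i:04d}" for i in range(13))

    cell_types = [
        CellTypeSpec("NSC", 120, 0.95, markers["NSC"]),
        CellTypeSpec("TAP", 100, 0.55, markers["TAP"]),
        CellTypeSpec("NB", 120, 0.70, markers["NB"]),
        CellTypeSpec("Astrocyte", 140, 1.00, markers["Astrocyte"]),
        CellTypeSpec("Oligodendrocyte", 120, 1.00, markers["Oligodendrocyte"]),
        CellTypeSpec("Microglia", 100, 1.05, markers["Microglia"]),
        CellTypeSpec("Endothelial", 80, 1.00, markers["Endothelial"]),
    ]

    niche_types = ("TAP", "NB", "Astrocyte", "Oligodendrocyte", "Microglia", "Endothelial")
    # The NSC receptor program declines with age both per cell (all curated
    # receptors drift down) and through composition (the receptor-high pool
    # shrinks, see ReceptorSpec below); NSC ligands decline per cell while
    # Apoe rises in the niche.
    age_trends = tuple(AgeTrendSpec(g, "NSC", -0.4) for g in receptors) + (
        AgeTrendSpec("Bdnf", "NSC", -0.4),
        AgeTrendSpec("Mdk", "NSC", -0.4),
        AgeTrendSpec("Apoe", "Astrocyte", 0.3),
        AgeTrendSpec("Apoe", "TAP", 0.3),
    )

    base_means: dict[str, float] = {}
    for type_markers in markers.values():
        for g in type_markers:
            base_means.setdefault(g, 1.0)
    for panel_spec in panel.types.values():
        for g in panel_spec.negative:
            base_means.setdefault(g, 1.0)
    # Ligands are broadly detectable (so only planted-silent senders score
    # zero); receptors sit low in receptor-low cells so the receptor-high
    # state is genuinely bimodal.
    for g in ligands:
        base_means[g] = 2.0
    for g in receptors:
        base_means[g] = 1.0
    for g in s_genes + g2m_genes:
        base_means[g] = 1.5
    for g in sex_genes:
        base_means[g] = 2.0
    for i in range(1, 14):
        base_means[f"mt-Gene{i:02d}"] = 2.0

    return NicheSimulationConfig(
        cell_types=cell_types,
        age_months=(2, 7, 12, 19),
        sexes=("F", "M"),
        region="SVZ",
        n_genes=1000,
        gene_base_means=base_means,
        cycle=CycleSpec(s_genes, g2m_genes, active_fraction=0.6, log2_effect=2.0),
        receptor=ReceptorSpec(
            tuple(receptors),
            high_fraction={2: 0.55, 7: 0.45, 12: 0.35, 19: 0.25},
            log2_effect=4.0,
        ),
        sex=SexSpec(sex_genes, log2_effect=2.0, cell_type="NSC"),
        age_trends=age_trends,
        couplings=(
            LRCoupling("Bdnf", "Ntrk2", "NSC", "NSC", rho=0.8),
            LRCoupling("Mdk", "Ptprz1", "Astrocyte", "NSC", rho=0.8),
        ),
        silent=SilentSpec(niche_types, tuple(ligands), fraction=0.35),
        inverse_dispersion=2.0,
        dropout_midpoint=0.0,
        dropout_slope=1.0,
        library_sigma=0.3,
        seed=seed,
    )
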
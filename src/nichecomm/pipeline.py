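"""End-to-end pipeline: simulate/read -> QC -> normalize -> cluster ->
annotate -> cell cycle -> differential -> communication, from one YAML
config, with per-stage seeding and a machine-readable run report.

One global seed fans out to per-stage seeds by stable hashing of stage
names, so adding a stage does not perturb earlier stages' randomness.
Outputs are plain TSV/JSON; identical config + seed reproduces them
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import MarkerPanel, assign_types, composition_by_sample, subcluster_receptor, subcluster_tap
from .cellcycle import PhaseGeneSets, score_phases
from .communication import (
    CommunicationConfig,
    differential_lr_network,
    fraction_silent,
    global_score,
    load_lr_table,
    scores_by_age,
)
from .differential import opposite_sex_pattern, proportion_anova_dunnett, wilcoxon_deg
from .preprocess import QCThresholds, cluster_cells, normalize, qc_filter
from .resources import load_gene_list, load_marker_panel
from .simulate import NicheSimulationConfig, default_config, simulate_niche

log = logging.getLogger("nichecomm")

_FLOAT_FMT = "%.6g"


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the global seed and stage name."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``validate_config``)."""

    input: dict
    output_dir: str
    seed: int = 0
    qc: dict = field(default_factory=dict)
    normalize: dict = field(default_factory=dict)
    cluster: dict = field(default_factory=dict)
    annotate: dict = field(default_factory=dict)
    cellcycle: dict = field(default_factory=dict)
    differential: dict = field(default_factory=dict)
    communication: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        violations = validate_config_dict(data)
        if violations:
            raise ValueError("invalid run config:\n" + "\n".join(violations))
        return cls(**data)


def validate_config_dict(data) -> list[str]:
    """All invariant violations of a run-config mapping, not just the first."""
    v: list[str] = []
    if not isinstance(data, dict):
        return ["config must be a mapping"]
    inp = data.get("input")
    if not isinstance(inp, dict):
        v.append("input: required mapping with exactly one of 'simulate'/'tenx_dir'")
    else:
        sources = [k for k in ("simulate", "tenx_dir") if k in inp]
        if len(sources) != 1:
            v.append("input: exactly one of 'simulate' or 'tenx_dir' must be set")
    if "output_dir" not in data:
        v.append("output_dir: required")
    qc = data.get("qc", {})
    for key in ("min_genes_per_cell", "max_genes_per_cell", "min_cells_per_gene"):
        if key in qc and (not isinstance(qc[key], (int, float)) or qc[key] < 0):
            v.append(f"qc.{key}: must be a nonnegative number")
    if "max_mito_fraction" in qc and not (0 <= qc["max_mito_fraction"] <= 1):
        v.append("qc.max_mito_fraction: must be in [0, 1]")
    if (
        "min_genes_per_cell" in qc
        and "max_genes_per_cell" in qc
        and qc["min_genes_per_cell"] >= qc["max_genes_per_cell"]
    ):
        v.append("qc: min_genes_per_cell must be < max_genes_per_cell")
    if "seed" in data and not isinstance(data["seed"], int):
        v.append("seed: must be an integer")
    cl = data.get("cluster", {})
    for key in ("n_top_genes", "n_comps", "k_neighbors"):
        if key in cl and (not isinstance(cl[key], int) or cl[key] <= 0):
            v.append(f"cluster.{key}: must be a positive integer")
    comm = data.get("communication", {})
    lr = comm.get("lr_table")
    if lr not in (None, "builtin") and not Path(lr).exists():
        v.append(f"communication.lr_table: file not found: {lr}")
    return v


def validate_config(path) -> list[str]:
    """Validate a YAML run config file; return the list of violations."""
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        return [f"unparseable YAML: {exc}"]
    return validate_config_dict(data)


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the run report (also written as JSON)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": [],
        "warnings": [],
    }
    outputs: dict[str, Path] = {}

    def stage(name: str, **info):
        log.info("stage %s: %s", name, info)
        report["stages"].append({"name": name, **info})

    # ---- input -------------------------------------------------------
    if "simulate" in config.input:
        sim_opts = config.input["simulate"] or {}
        if isinstance(sim_opts, dict) and sim_opts.get("config"):
            sim_cfg = NicheSimulationConfig.from_yaml(sim_opts["config"])
        else:
            sim_cfg = default_config(seed=stage_seed(config.seed, "simulate"))
        adata, truth = simulate_niche(sim_cfg)
        truth.write(outdir / "truth")
        stage("simulate", n_cells=int(adata.n_obs), n_genes=int(adata.n_vars))
    else:
        from .io import read_10x_triplet

        adata = read_10x_triplet(config.input["tenx_dir"])
        truth = None
        stage("read", n_cells=int(adata.n_obs), n_genes=int(adata.n_vars))

    # ---- qc ----------------------------------------------------------
    qc_opts = dict(config.qc)
    mito_prefix = qc_opts.pop("mito_prefix", "mt-")
    thresholds = QCThresholds(**qc_opts) if qc_opts else QCThresholds()
    adata, qc_report = qc_filter(adata, thresholds, mito_prefix=mito_prefix)
    (outdir / "qc_report.json").write_text(json.dumps(qc_report, indent=2, sort_keys=True))
    outputs["qc_report"] = outdir / "qc_report.json"
    stage("qc", **{k: qc_report[k] for k in ("n_cells_out", "n_genes_out")})

    # ---- normalize ---------------------------------------------------
    scale = float(config.normalize.get("scale", 1e6))
    adata = normalize(adata, scale=scale)
    stage("normalize", scale=scale)

    # ---- cluster -----------------------------------------------------
    cl = dict(config.cluster)
    labels = cluster_cells(
        adata,
        n_top_genes=cl.get("n_top_genes", 2000),
        n_comps=cl.get("n_comps", 30),
        k_neighbors=cl.get("k_neighbors", 15),
        resolution=cl.get("resolution", 1.0),
        seed=stage_seed(config.seed, "cluster"),
    )
    stage("cluster", n_clusters=int(len(set(labels))))

    # ---- annotate ----------------------------------------------------
    panel_ref = config.annotate.get("panel", "svz")
    if panel_ref.lower() in ("svz", "dg"):
        panel = load_marker_panel(panel_ref.upper())
    else:
        panel = MarkerPanel.from_yaml(panel_ref)
    assignment = assign_types(
        adata, labels, panel, floor=config.annotate.get("floor", 0.0)
    )
    cell_types = assignment.cell_types
    type_df = pd.DataFrame({"cluster": labels, "cell_type": cell_types.to_numpy()},
                           index=adata.obs_names)
    type_df.index.name = "cell_id"
    _write_tsv(type_df, outdir / "cell_types.tsv", index=True)
    outputs["cell_types"] = outdir / "cell_types.tsv"

    composition = composition_by_sample(cell_types, adata.obs)
    _write_tsv(composition, outdir / "composition.tsv")
    outputs["composition"] = outdir / "composition.tsv"
    stage("annotate", types={t: int((cell_types == t).sum())
                             for t in sorted(cell_types.unique())})

    s_genes = tuple(
        load_gene_list("s_genes")
        if config.cellcycle.get("s_genes", "builtin") == "builtin"
        else _read_gene_file(config.cellcycle["s_genes"])
    )
    g2m_genes = tuple(
        load_gene_list("g2m_genes")
        if config.cellcycle.get("g2m_genes", "builtin") == "builtin"
        else _read_gene_file(config.cellcycle["g2m_genes"])
    )

    tap_type = config.annotate.get("tap_type", "TAP")
    tap_cells = adata.obs_names[(cell_types == tap_type).to_numpy()]
    tap_res = None
    if len(tap_cells) >= 20:
        tap_res = subcluster_tap(
            adata, tap_cells, s_genes + g2m_genes,
            seed=stage_seed(config.seed, "subcluster_tap"),
        )
        if not tap_res.degenerate:
            df = tap_res.labels.to_frame()
            df.index.name = "cell_id"
            _write_tsv(df, outdir / "tap_subtypes.tsv", index=True)
            _write_tsv(tap_res.fractions_by_age, outdir / "tap_subtype_fractions.tsv")
            outputs["tap_subtypes"] = outdir / "tap_subtypes.tsv"
            outputs["tap_subtype_fractions"] = outdir / "tap_subtype_fractions.tsv"
    stage("subcluster_tap", n_tap=int(len(tap_cells)))

    lr_ref = config.communication.get("lr_table", "builtin")
    lr_table = load_lr_table(None if lr_ref == "builtin" else lr_ref)
    receptor_genes = [g for g in dict.fromkeys(lr_table["receptor"])
                      if g in adata.var_names]

    nsc_type = config.annotate.get("nsc_type", "NSC")
    nsc_cells = adata.obs_names[(cell_types == nsc_type).to_numpy()]
    nsc_res = None
    if len(nsc_cells) >= 20 and receptor_genes:
        nsc_res = subcluster_receptor(adata, nsc_cells, receptor_genes)
        if not nsc_res.degenerate:
            df = nsc_res.labels.to_frame()
            df.index.name = "cell_id"
            _write_tsv(df, outdir / "nsc_receptor_subtypes.tsv", index=True)
            _write_tsv(nsc_res.extra["receptor_deg"], outdir / "nsc_receptor_deg.tsv")
            outputs["nsc_receptor_subtypes"] = outdir / "nsc_receptor_subtypes.tsv"
            outputs["nsc_receptor_deg"] = outdir / "nsc_receptor_deg.tsv"
    stage("subcluster_receptor", n_nsc=int(len(nsc_cells)))

    # ---- cell cycle --------------------------------------------------
    sets = PhaseGeneSets(
        s_genes, g2m_genes,
        n_bins=config.cellcycle.get("n_bins", 25),
        n_controls_per_gene=config.cellcycle.get("n_controls_per_gene", 50),
        seed=stage_seed(config.seed, "cellcycle"),
    )
    phases = score_phases(adata, sets)
    phases.index.name = "cell_id"
    _write_tsv(phases, outdir / "phases.tsv", index=True)
    outputs["phases"] = outdir / "phases.tsv"
    stage("cellcycle", phase_counts=phases["phase"].value_counts().to_dict())

    # ---- differential ------------------------------------------------
    diff = config.differential
    young = diff.get("young_age", int(adata.obs["age_months"].min()))
    old = diff.get("old_age", int(adata.obs["age_months"].max()))
    deg_type = diff.get("cell_type", nsc_type)
    q_max = diff.get("q_max", 0.05)

    ages = adata.obs["age_months"]
    typed = (cell_types == deg_type).to_numpy()
    deg_tables = {}
    for sex in sorted(adata.obs["sex"].unique()) if "sex" in adata.obs else []:
        sex_mask = (adata.obs["sex"] == sex).to_numpy()
        a = adata.obs_names[typed & sex_mask & (ages == old).to_numpy()]
        b = adata.obs_names[typed & sex_mask & (ages == young).to_numpy()]
        if len(a) >= 3 and len(b) >= 3:
            deg_tables[sex] = wilcoxon_deg(adata, a, b)
    a = adata.obs_names[typed & (ages == old).to_numpy()]
    b = adata.obs_names[typed & (ages == young).to_numpy()]
    deg_all = wilcoxon_deg(adata, a, b) if len(a) >= 3 and len(b) >= 3 else pd.DataFrame()
    if len(deg_all):
        _write_tsv(deg_all, outdir / "deg_age.tsv")
        outputs["deg_age"] = outdir / "deg_age.tsv"

    sex_opposite = pd.DataFrame()
    if len(deg_tables) == 2:
        female, male = [deg_tables[s] for s in sorted(deg_tables)]
        sex_opposite = opposite_sex_pattern(female, male, q_max=q_max)
        _write_tsv(sex_opposite, outdir / "sex_opposite_genes.tsv")
        outputs["sex_opposite_genes"] = outdir / "sex_opposite_genes.tsv"

    anova = None
    try:
        anova = proportion_anova_dunnett(
            composition, tap_type, young, seed=stage_seed(config.seed, "anova")
        )
        _write_tsv(anova.comparisons, outdir / "tap_proportion_dunnett.tsv")
        outputs["tap_proportion_dunnett"] = outdir / "tap_proportion_dunnett.tsv"
    except ValueError as exc:
        report["warnings"].append(f"proportion ANOVA skipped: {exc}")
    stage(
        "differential",
        n_deg_age=int((deg_all["qvalue"] <= q_max).sum()) if len(deg_all) else 0,
        n_sex_opposite=int(len(sex_opposite)),
        anova_p=None if anova is None else anova.p_value,
    )

    # ---- communication -----------------------------------------------
    focal_mask = (cell_types == nsc_type).to_numpy()
    niche_mask = (~focal_mask) & (cell_types != "unassigned").to_numpy()

    by_age = scores_by_age(adata, lr_table, focal_mask, focal_mask, "receptor_side")
    nsc_rows = [
        {"age_months": age, "n_cells": len(t.global_scores),
         "mean_score": float(t.global_scores.mean()),
         "fraction_silent": fraction_silent(t.global_scores)}
        for age, t in by_age.items()
    ]
    _write_tsv(pd.DataFrame(nsc_rows), outdir / "comm_nsc_by_age.tsv")
    outputs["comm_nsc_by_age"] = outdir / "comm_nsc_by_age.tsv"

    niche_cfg = CommunicationConfig(
        "ligand_side",
        tuple(adata.obs_names[niche_mask]),
        tuple(adata.obs_names[focal_mask]),
    )
    niche_scores = global_score(adata, lr_table, niche_cfg)
    silent_niche = fraction_silent(niche_scores.global_scores)

    network = differential_lr_network(
        adata, lr_table, cell_types, young, old, nsc_type, q_max=q_max
    )
    _write_tsv(network, outdir / "diff_lr_network.tsv")
    outputs["diff_lr_network"] = outdir / "diff_lr_network.tsv"
    edge_list = network[["ligand", "receptor", "nmi", "direction"]]
    _write_tsv(edge_list, outdir / "diff_lr_edges.tsv")
    outputs["diff_lr_edges"] = outdir / "diff_lr_edges.tsv"
    stage(
        "communication",
        silent_niche_fraction=silent_niche,
        n_network_edges=int(len(network)),
    )

    report["checksums"] = {k: _checksum(p) for k, p in sorted(outputs.items())}
    report["outputs"] = {k: str(p) for k, p in sorted(outputs.items())}
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _read_gene_file(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
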
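"""Shipped default resources: curated LR pairs, marker panels, phase gene sets."""

from __future__ import annotations

from importlib import resources as _ir

import pandas as pd
import yaml

_PKG = "nichecomm.resources"


def _path(name: str):
    return _ir.files(_PKG).joinpath(name)


def load_lr_table() -> pd.DataFrame:
    """The shipped curated ligand-receptor pair table (ligand, receptor, source)."""
    from ..communication import validate_lr_table

    with _ir.as_file(_path("lr_pairs.tsv")) as p:
        table = pd.read_csv(p, sep="\t")
    validate_lr_table(table)
    return table


def load_gene_list(name: str) -> list[str]:
    """A plain one-gene-per-line list: ``s_genes`` or ``g2m_genes``."""
    text = _path(f"{name}.txt").read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


def load_marker_panel(region: str):
    """The shipped marker panel for ``region`` in {"SVZ", "DG"}."""
    from ..annotate import MarkerPanel

    fname = {"SVZ": "markers_svz.yaml", "DG": "markers_dg.yaml"}.get(region.upper())
    if fname is None:
        raise ValueError(f"no shipped panel for region {region!r}")
    data = yaml.safe_load(_path(fname).read_text())
    return MarkerPanel.from_dict(data)
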
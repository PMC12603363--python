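"""Readers and writers for the pipeline's interchange formats.

Gas-exchange tables are delimited text (comma by default) with one row per
logged point; labeled leaf volumes are multi-page TIFF stacks of 8-bit
labels with a YAML legend sidecar; trees are Newick with branch lengths.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import tifffile
import yaml

from .anatomy3d import DEFAULT_VOXEL_EDGE, AnatomyError, LabeledVolume
from .gas_exchange import HABITS, AciCurve, GasExchangeError
from .phylocomp import PhyloError

__all__ = [
    "REQUIRED_GAS_COLUMNS",
    "read_gas_exchange_table",
    "write_gas_exchange_table",
    "read_label_stack",
    "write_label_stack",
    "read_newick",
    "write_newick",
]

REQUIRED_GAS_COLUMNS = (
    "species", "tree_id", "habit", "year",
    "ca_setpoint", "an", "ci", "gs", "ppfd", "tleaf",
)


def curves_to_frame(curves: list[AciCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        for i in range(len(c)):
            row = {
                "species": c.species, "tree_id": c.tree_id, "habit": c.habit,
                "year": c.year, "ca_setpoint": c.ca_setpoint[i], "an": c.an[i],
                "ci": c.ci[i], "gs": c.gs[i], "ppfd": c.ppfd[i],
                "tleaf": c.leaf_temp[i],
            }
            if c.phi_psii is not None:
                row["phi_psii"] = c.phi_psii[i]
            rows.append(row)
    return pd.DataFrame(rows)


def write_gas_exchange_table(curves: list[AciCurve], path, sep: str = ",") -> None:
    curves_to_frame(curves).to_csv(path, sep=sep, index=False)


def read_gas_exchange_table(path, sep: str = ",") -> list[AciCurve]:
    """Read a logged gas-exchange table and group rows into per-leaf curves.

    Rows are grouped by (species, tree_id, year). Raises on missing
    required columns (named in the message), non-numeric cells, and habit
    values outside {deciduous, evergreen}.
    """
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_GAS_COLUMNS if c not in df.columns]
    if missing:
        raise GasExchangeError(f"gas-exchange table missing required columns: {missing}")
    numeric = ["ca_setpoint", "an", "ci", "gs", "ppfd", "tleaf"]
    if "phi_psii" in df.columns:
        numeric.append("phi_psii")
    for col in numeric:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise GasExchangeError(f"non-numeric value in column {col!r}: {exc}") from exc
    bad_habit = set(df["habit"].unique()) - set(HABITS)
    if bad_habit:
        raise GasExchangeError(f"unknown habit level(s): {sorted(bad_habit)}")

    curves = []
    for (species, tree_id, year), g in df.groupby(["species", "tree_id", "year"],
                                                  sort=True):
        g = g.sort_values("ca_setpoint")
        curves.append(AciCurve(
            ca_setpoint=g["ca_setpoint"].to_numpy(),
            an=g["an"].to_numpy(), ci=g["ci"].to_numpy(), gs=g["gs"].to_numpy(),
            ppfd=g["ppfd"].to_numpy(), leaf_temp=g["tleaf"].to_numpy(),
            phi_psii=g["phi_psii"].to_numpy() if "phi_psii" in g.columns else None,
            species=str(species), tree_id=str(tree_id),
            habit=str(g["habit"].iloc[0]), year=int(year),
        ))
    return curves


def write_label_stack(vol: LabeledVolume, path, legend_path) -> None:
    """Write a labeled volume as a multi-page 8-bit TIFF plus YAML legend."""
    tifffile.imwrite(str(path), vol.grid.astype(np.uint8))
    with open(legend_path, "w") as fh:
        yaml.safe_dump({"voxel_edge_um": float(vol.voxel_edge),
                        "classes": {k: int(v) for k, v in vol.legend.items()}}, fh)


def read_label_stack(path, legend_path) -> LabeledVolume:
    """Read a TIFF label stack with its legend sidecar.

    A legend without ``voxel_edge_um`` falls back to the default scan
    resolution of 0.65 um (with a warning); labels present in the stack but
    absent from the legend are an error.
    """
    grid = tifffile.imread(str(path))
    if grid.ndim == 2:
        grid = grid[None]
    with open(legend_path) as fh:
        meta = yaml.safe_load(fh)
    if "classes" not in meta:
        raise AnatomyError(f"legend file {legend_path} lacks a 'classes' mapping")
    voxel_edge = meta.get("voxel_edge_um")
    if voxel_edge is None:
        warnings.warn(
            f"legend {legend_path} lacks voxel_edge_um; using default "
            f"{DEFAULT_VOXEL_EDGE} um", stacklevel=2)
        voxel_edge = DEFAULT_VOXEL_EDGE
    return LabeledVolume(grid=np.asarray(grid), voxel_edge=float(voxel_edge),
                         legend={str(k): int(v) for k, v in meta["classes"].items()})


def read_newick(source) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths (missing lengths error)."""
    src = str(source)
    if Path(src).exists():
        tree = dendropy.Tree.get(path=src, schema="newick",
                                 preserve_underscores=True)
    else:
        tree = dendropy.Tree.get(data=src, schema="newick",
                                 preserve_underscores=True)
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise PhyloError("tree has edges without branch lengths")
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)
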
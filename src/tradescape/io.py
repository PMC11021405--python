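"""Readers and writers for the pipeline's plain-text formats.

Landmarks come either as TPS-dialect files (LM3 blocks with an ID line) or
as a long CSV (specimen, landmark, x, y, z, clade).  Trees are newick via
dendropy; surface models serialize to JSON; tabular results are CSV.
Parsing is strict: malformed records raise with the offending line or
column named.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .shape import LandmarkConfiguration
from .surfaces import SurfaceModel

__all__ = [
    "read_landmarks_tps",
    "write_landmarks_tps",
    "read_landmarks_csv",
    "write_landmarks_csv",
    "read_tree",
    "write_tree",
    "read_surface_model",
    "write_surface_model",
]


def read_landmarks_tps(path: str | Path) -> list[LandmarkConfiguration]:
    """Parse a TPS-dialect file of LM3 blocks.

    Each block is ``LM3=<n>`` followed by n whitespace-separated coordinate
    triplets and an ``ID=<label>`` line; an optional ``CLADE=<groupA|groupB>``
    line may follow the ID.
    """
    configs = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if not line.upper().startswith("LM3="):
            raise ValueError(f"{path}: line {i}: expected 'LM3=', got {line!r}")
        try:
            n = int(line.split("=", 1)[1])
        except ValueError as e:
            raise ValueError(f"{path}: line {i}: bad landmark count") from e
        coords = np.empty((n, 3))
        for k in range(n):
            parts = lines[i].split()
            if len(parts) != 3:
                raise ValueError(f"{path}: line {i + 1}: expected 3 coordinates, got {len(parts)}")
            coords[k] = [float(p) for p in parts]
            i += 1
        species, clade = "", "groupA"
        while i < len(lines) and "=" in lines[i] and not lines[i].upper().startswith("LM3="):
            key, val = lines[i].split("=", 1)
            if key.strip().upper() == "ID":
                species = val.strip()
            elif key.strip().upper() == "CLADE":
                clade = val.strip()
            i += 1
        configs.append(LandmarkConfiguration(coords, species_id=species, clade=clade))
    if not configs:
        raise ValueError(f"{path}: no LM3 blocks found")
    return configs


def write_landmarks_tps(configs: list[LandmarkConfiguration], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in configs:
            fh.write(f"LM3={c.n_landmarks}\n")
            for row in c.coordinates:
                fh.write(f"{row[0]:.12g} {row[1]:.12g} {row[2]:.12g}\n")
            fh.write(f"ID={c.species_id}\nCLADE={c.clade}\n")


_CSV_COLUMNS = ["specimen", "landmark", "x", "y", "z", "clade"]


def read_landmarks_csv(path: str | Path) -> list[LandmarkConfiguration]:
    """Read the long CSV dialect (specimen, landmark, x, y, z, clade)."""
    df = pd.read_csv(path)
    for col in _CSV_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    configs = []
    for specimen, block in df.groupby("specimen", sort=False):
        block = block.sort_values("landmark")
        clades = block["clade"].unique()
        configs.append(
            LandmarkConfiguration(
                block[["x", "y", "z"]].to_numpy(float),
                species_id=str(specimen),
                clade=str(clades[0]),
            )
        )
    return configs


def write_landmarks_csv(configs: list[LandmarkConfiguration], path: str | Path) -> None:
    rows = []
    for c in configs:
        for k, (x, y, z) in enumerate(c.coordinates):
            rows.append({"specimen": c.species_id, "landmark": k, "x": x, "y": y, "z": z, "clade": c.clade})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tree(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick")


def read_surface_model(path: str | Path) -> SurfaceModel:
    return SurfaceModel.from_json(Path(path).read_text())


def write_surface_model(model: SurfaceModel, path: str | Path) -> None:
    Path(path).write_text(model.to_json())
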
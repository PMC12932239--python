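"""File formats: seed point lists (CSV/JSON), needle/obstacle JSON and NRRD
volumes (via SimpleITK, 3D Slicer-compatible)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .dose import DoseGrid
from .geometry import NeedleTrajectory
from .refine import ObstacleSphere

__all__ = [
    "read_seeds_csv", "write_seeds_csv", "read_seeds_json", "write_seeds_json",
    "read_obstacles_json", "write_obstacles_json",
    "read_needles_json", "write_needles_json",
    "read_nrrd", "write_nrrd",
]

SEED_COLUMNS = ["id", "x_mm", "y_mm", "z_mm"]


def _validate_seeds(df: pd.DataFrame) -> tuple[np.ndarray, list]:
    missing = [c for c in SEED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"seed table missing columns {missing}")
    if df[SEED_COLUMNS[1:]].isna().any().any():
        raise ValueError("seed table contains NaN coordinates")
    ids = df["id"].tolist()
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate seed ids")
    return df[["x_mm", "y_mm", "z_mm"]].to_numpy(float), ids


def read_seeds_csv(path) -> tuple[np.ndarray, list]:
    """Read a seed point list; returns (positions (n,3) mm, id list)."""
    return _validate_seeds(pd.read_csv(path))


def write_seeds_csv(path, seeds: np.ndarray, ids=None) -> None:
    seeds = np.atleast_2d(np.asarray(seeds, float))
    if ids is None:
        ids = list(range(len(seeds)))
    pd.DataFrame({"id": ids, "x_mm": seeds[:, 0], "y_mm": seeds[:, 1],
                  "z_mm": seeds[:, 2]}).to_csv(path, index=False)


def read_seeds_json(path) -> tuple[np.ndarray, list]:
    with open(path) as fh:
        rows = json.load(fh)
    return _validate_seeds(pd.DataFrame(rows))


def write_seeds_json(path, seeds: np.ndarray, ids=None) -> None:
    seeds = np.atleast_2d(np.asarray(seeds, float))
    if ids is None:
        ids = list(range(len(seeds)))
    rows = [{"id": i, "x_mm": s[0], "y_mm": s[1], "z_mm": s[2]}
            for i, s in zip(ids, seeds.tolist())]
    Path(path).write_text(json.dumps(rows, indent=1))


def read_obstacles_json(path) -> list[ObstacleSphere]:
    with open(path) as fh:
        rows = json.load(fh)
    return [ObstacleSphere(center=np.asarray(r["center"], float),
                           radius=float(r["radius"])) for r in rows]


def write_obstacles_json(path, obstacles: list[ObstacleSphere]) -> None:
    rows = [{"center": o.center.tolist(), "radius": o.radius} for o in obstacles]
    Path(path).write_text(json.dumps(rows, indent=1))


def read_needles_json(path) -> list[NeedleTrajectory]:
    with open(path) as fh:
        rows = json.load(fh)
    return [NeedleTrajectory.from_dict(r) for r in rows]


def write_needles_json(path, needles: list[NeedleTrajectory]) -> None:
    Path(path).write_text(json.dumps([n.to_dict() for n in needles], indent=1))


def read_nrrd(path) -> DoseGrid:
    """Read a 3D NRRD volume into a DoseGrid (values indexed [x, y, z])."""
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)  # [z, y, x]
    return DoseGrid(origin=np.asarray(img.GetOrigin(), float),
                    spacing=np.asarray(img.GetSpacing(), float),
                    values=np.ascontiguousarray(arr.transpose(2, 1, 0)))


def write_nrrd(path, grid: DoseGrid) -> None:
    img = sitk.GetImageFromArray(np.ascontiguousarray(grid.values.transpose(2, 1, 0)))
    img.SetOrigin(tuple(grid.origin))
    img.SetSpacing(tuple(grid.spacing))
    sitk.WriteImage(img, str(path), useCompression=False)
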
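"""TG-43 1D (point-source) dose computation for permanent I-125 implants.

The absorbed-dose rate at radial distance ``r`` from a seed of air-kerma
strength ``S_k`` is

    rate(r) = S_k * Lambda * (1 cm / r)^2 * g(r) * phi_an(r)   [cGy/h]

with dose-rate constant ``Lambda``, radial dose function ``g`` and 1D
anisotropy factor ``phi_an`` linearly interpolated from tabulated data and
clamped to the table endpoints.  For a permanent implant the total dose is
the rate integrated over full decay, i.e. rate * tau with the mean lifetime
tau = T_half / ln 2.

Seed orientation is not modelled (1D formalism): the planned dwell positions
carry no orientation information.  A clamp radius avoids the 1/r^2
singularity; contributions beyond a cutoff radius are dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "SourceModel",
    "DoseGrid",
    "load_source_model",
    "air_kerma_strength",
    "initial_dose_rate",
    "permanent_implant_dose",
]

CLAMP_RADIUS_MM = 1.0
CUTOFF_RADIUS_MM = 100.0


@dataclass(frozen=True)
class SourceModel:
    """Tabulated TG-43 1D parameters for one seed model."""

    name: str
    dose_rate_constant: float       # cGy / (h * U)
    half_life_days: float
    u_per_mci: float                # air-kerma strength per apparent mCi
    g_r_cm: np.ndarray
    g_val: np.ndarray
    phi_r_cm: np.ndarray
    phi_val: np.ndarray

    def __post_init__(self):
        for r in (self.g_r_cm, self.phi_r_cm):
            if np.any(np.diff(r) <= 0):
                raise ValueError("radial tables must be strictly increasing")
        if abs(float(np.interp(1.0, self.g_r_cm, self.g_val)) - 1.0) > 0.05:
            raise ValueError("radial dose function must be ~1 at r = 1 cm")
        if np.any(self.phi_val <= 0) or np.any(self.phi_val > 1.2):
            raise ValueError("anisotropy factor out of range (0, 1.2]")

    def g(self, r_cm):
        return np.interp(r_cm, self.g_r_cm, self.g_val)

    def phi_an(self, r_cm):
        return np.interp(r_cm, self.phi_r_cm, self.phi_val)

    @property
    def mean_lifetime_hours(self) -> float:
        return self.half_life_days * 24.0 / np.log(2.0)


def load_source_model(path=None, **overrides) -> SourceModel:
    """Load a source model from JSON; defaults to the packaged 6711 data.

    Keyword overrides replace individual fields (e.g. uniform ``g``/``phi_an``
    tables for inverse-square checks).
    """
    if path is None:
        text = resources.files("needleplan.data").joinpath("i125_6711.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    d = json.loads(text)
    kw = dict(
        name=d.get("name", "source"),
        dose_rate_constant=float(d["dose_rate_constant_cGy_per_hU"]),
        half_life_days=float(d["half_life_days"]),
        u_per_mci=float(d["u_per_mci"]),
        g_r_cm=np.asarray(d["radial_dose_function"]["r_cm"], float),
        g_val=np.asarray(d["radial_dose_function"]["g"], float),
        phi_r_cm=np.asarray(d["anisotropy_factor"]["r_cm"], float),
        phi_val=np.asarray(d["anisotropy_factor"]["phi_an"], float),
    )
    kw.update(overrides)
    return SourceModel(**kw)


@dataclass
class DoseGrid:
    """Regular 3D scalar grid; values indexed ``[ix, iy, iz]`` in Gy.

    ``origin`` is the world position of the center of voxel (0, 0, 0);
    voxel centers are ``origin + index * spacing``.
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("dose grid must be 3D")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")

    @property
    def dims(self):
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[k] + self.spacing[k] * np.arange(self.dims[k]) for k in range(3)
        )

    def same_geometry(self, other: "DoseGrid") -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.origin, other.origin)
            and np.allclose(self.spacing, other.spacing)
        )


def air_kerma_strength(activity_mci: float, source: SourceModel) -> float:
    """Air-kerma strength S_k (U) of a seed of given apparent activity."""
    if activity_mci <= 0:
        raise ValueError("activity must be positive")
    return activity_mci * source.u_per_mci


def initial_dose_rate(r_cm, s_k: float, source: SourceModel):
    """TG-43 1D dose rate (cGy/h) at radial distance ``r_cm``.

    Distances below the clamp radius are evaluated at the clamp radius, so
    the rate stays finite arbitrarily close to the source.
    """
    r = np.maximum(np.asarray(r_cm, dtype=float), CLAMP_RADIUS_MM / 10.0)
    rate = s_k * source.dose_rate_constant * (1.0 / r) ** 2 * source.g(r) * source.phi_an(r)
    return float(rate) if np.isscalar(r_cm) else rate


def permanent_implant_dose(seeds, activity_mci: float, origin, spacing, dims,
                           source: SourceModel | None = None,
                           cutoff_mm: float = CUTOFF_RADIUS_MM) -> DoseGrid:
    """Total absorbed dose (Gy) from a permanent implant on a regular grid.

    Superposes the TG-43 1D dose of every seed, integrated over full decay.
    Contributions beyond ``cutoff_mm`` (< 0.1 % of the 1-cm dose) are
    dropped.
    """
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    if seeds.size == 0:
        raise ValueError("empty seed list")
    if source is None:
        source = load_source_model()
    s_k = air_kerma_strength(activity_mci, source)
    tau = source.mean_lifetime_hours
    origin = np.asarray(origin, float).reshape(3)
    spacing = np.asarray(spacing, float).reshape(3)
    dims = tuple(int(d) for d in dims)
    xs = origin[0] + spacing[0] * np.arange(dims[0])
    ys = origin[1] + spacing[1] * np.arange(dims[1])
    zs = origin[2] + spacing[2] * np.arange(dims[2])
    total = np.zeros(dims)
    for s in seeds:
        dx2 = (xs - s[0]) ** 2
        dy2 = (ys - s[1]) ** 2
        dz2 = (zs - s[2]) ** 2
        r_mm = np.sqrt(
            dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]
        )
        near = r_mm <= cutoff_mm
        r_cm = np.maximum(r_mm[near], CLAMP_RADIUS_MM) / 10.0
        rate = (
            s_k * source.dose_rate_constant * (1.0 / r_cm) ** 2
            * source.g(r_cm) * source.phi_an(r_cm)
        )
        total[near] += rate * tau / 100.0  # cGy -> Gy
    return DoseGrid(origin=origin, spacing=spacing, values=total)
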
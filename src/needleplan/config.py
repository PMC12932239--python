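"""Pipeline configuration: every tunable of the planning chain with its
default, loadable from a YAML file and embeddable into reports."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .refine import RefineConfig

__all__ = ["PlannerConfig"]


@dataclass
class PlannerConfig:
    """End-to-end configuration (lengths mm, activity mCi, doses Gy)."""

    # Hough detection
    hough_level: int = 6
    spatial_step_mm: float = 0.2
    capture_radius_mm: float = 1.5
    min_votes: int = 2
    # refinement (RefineConfig defaults hold the rest)
    l_max_mm: float = 150.0
    l_min_mm: float = 20.0
    d_g_mm: float = 20.0
    needle_length_mm: float = 200.0
    search_radius_mm: float = 5.0
    enlargement_factor: float = 2.0
    max_enlargements: int = 2
    # dosimetry
    activity_mci: float = 0.5
    prescription_gy: float = 145.0
    grid_spacing_mm: tuple = (3.5, 3.5, 1.5)
    grid_dims: tuple = (60, 60, 80)
    # gamma / DVH
    gamma_dta_mm: float = 2.0
    gamma_dose_crit_pct: float = 2.0
    gamma_low_dose_cutoff_pct: float = 10.0
    dvh_bin_gy: float = 0.5
    # study
    master_seed: int = 1234
    n_obstacles: int = 1
    sphere_radius_mm: float = 5.0
    baseline_pitch_mm: float = 5.0

    def refine_config(self, workspace_box=None, body_surface=None) -> RefineConfig:
        return RefineConfig(
            l_max=self.l_max_mm, l_min=self.l_min_mm, d_g=self.d_g_mm,
            needle_length=self.needle_length_mm, r_search=self.search_radius_mm,
            enlargement_factor=self.enlargement_factor,
            max_enlargements=self.max_enlargements,
            workspace_box=workspace_box, body_surface=body_surface,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PlannerConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("grid_spacing_mm", "grid_dims"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        d = self.to_dict()
        d["grid_spacing_mm"] = list(d["grid_spacing_mm"])
        d["grid_dims"] = list(d["grid_dims"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)
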
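"""Plan-quality metrics: DVH, V/D statistics, Paddick conformity index,
gamma analysis, seed-error decomposition, success classification and paired
plan comparison."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import cKDTree

from .dose import DoseGrid

__all__ = [
    "StructureMask",
    "DVHCurve",
    "PlanMetrics",
    "compute_dvh",
    "dvh_metrics",
    "paddick_ci",
    "gamma_pass_rate",
    "axial_radial_errors",
    "classify_success",
    "compare_plans",
    "scale_to_d90",
]

SUCCESS_DISPLACEMENT_MM = 1.5


@dataclass
class StructureMask:
    """Binary voxel mask aligned to a DoseGrid."""

    values: np.ndarray
    label: str = "PTV"

    def __post_init__(self):
        self.values = np.asarray(self.values).astype(bool)

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram: % volume receiving >= dose."""

    dose_edges: np.ndarray     # Gy, ascending, starting at 0
    volume_pct: np.ndarray     # same length; starts at 100, non-increasing

    def dmean(self) -> float:
        """Mean dose recovered from the curve: the integral of the survival
        function P(D >= t) over dose equals E[D]."""
        return float(np.trapezoid(self.volume_pct / 100.0, self.dose_edges))


def compute_dvh(dose: DoseGrid, mask: StructureMask, bin_width: float = 0.5) -> DVHCurve:
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if mask.values.shape != dose.values.shape:
        raise ValueError("mask and dose grid are misaligned")
    doses = dose.values[mask.values]
    if doses.size == 0:
        raise ValueError(f"empty structure mask '{mask.label}'")
    top = float(doses.max()) + bin_width
    edges = np.arange(0.0, top + bin_width, bin_width)
    vol = np.array([(doses >= e).mean() * 100.0 for e in edges])
    return DVHCurve(dose_edges=edges, volume_pct=vol)


@dataclass
class PlanMetrics:
    """Headline dosimetric indices of one plan."""

    v150: float      # % of PTV receiving >= 150% of prescription
    v200: float      # % of PTV receiving >= 200% of prescription
    d90: float       # Gy: minimum dose covering the hottest 90% of the PTV
    dmean: float     # Gy
    ci: float = float("nan")
    gamma_pass: float = float("nan")

    def as_dict(self) -> dict:
        return {"V150": self.v150, "V200": self.v200, "D90": self.d90,
                "Dmean": self.dmean, "CI": self.ci, "gamma_pass": self.gamma_pass}


def dvh_metrics(dose: DoseGrid, ptv_mask: StructureMask, prescription: float) -> PlanMetrics:
    """V150/V200 (% of PTV volume), D90 and Dmean (Gy) for the PTV.

    D90 is the 10th percentile of the masked voxel doses: the dose received
    by at least 90 % of the target volume (voxels are equal-volume, so the
    plain percentile is already volume-weighted).
    """
    if prescription <= 0:
        raise ValueError("prescription must be positive")
    doses = dose.values[ptv_mask.values]
    if doses.size == 0:
        raise ValueError("empty PTV")
    return PlanMetrics(
        v150=float((doses >= 1.5 * prescription).mean() * 100.0),
        v200=float((doses >= 2.0 * prescription).mean() * 100.0),
        d90=float(np.percentile(doses, 10.0)),
        dmean=float(doses.mean()),
    )


def paddick_ci(dose: DoseGrid, ptv_mask: StructureMask, prescription: float) -> float:
    """Paddick conformity index (V_PTV∩PIV)^2 / (V_PTV * V_PIV), where the
    PIV is the volume enclosed by the prescription isodose."""
    if prescription <= 0:
        raise ValueError("prescription must be positive")
    piv = dose.values >= prescription
    v_ptv = ptv_mask.values.sum()
    if v_ptv == 0:
        raise ValueError("empty PTV")
    v_piv = piv.sum()
    if v_piv == 0:
        return 0.0
    inter = np.logical_and(piv, ptv_mask.values).sum()
    return float(inter**2 / (v_ptv * v_piv))


def gamma_pass_rate(reference: DoseGrid, evaluated: DoseGrid, dta_mm: float = 2.0,
                    dose_crit_pct: float = 2.0, norm_gy: float | None = None,
                    low_dose_cutoff_pct: float = 10.0) -> float:
    """Global-normalization gamma pass rate (%) between two aligned grids.

    A reference voxel passes when some point within the distance-to-agreement
    ball of its position has evaluated dose within the criterion:
    min over offsets of sqrt((|Δr|/dta)^2 + (ΔD/(crit% · norm))^2) <= 1.
    Offsets farther than the DTA cannot yield gamma <= 1 (their distance term
    alone exceeds 1), so the search is restricted to the DTA ball, sampled at
    one third of the voxel spacing with linear interpolation of the evaluated
    dose.  ``norm_gy`` defaults to the reference maximum.
    """
    if not reference.same_geometry(evaluated):
        raise ValueError("gamma analysis requires aligned grids")
    if dta_mm <= 0 or dose_crit_pct <= 0:
        raise ValueError("dta and dose criterion must be positive")
    ref = reference.values
    ev = evaluated.values
    if norm_gy is None:
        norm_gy = float(ref.max())
    crit = dose_crit_pct / 100.0 * norm_gy
    consider = ref >= low_dose_cutoff_pct / 100.0 * norm_gy
    n_considered = int(consider.sum())
    if n_considered == 0:
        raise ValueError("no reference voxels above the low-dose cutoff")

    passed = np.abs(ev - ref) <= crit
    fail_idx = np.argwhere(consider & ~passed)
    if len(fail_idx) == 0:
        return 100.0

    axes = reference.axes()
    interp = RegularGridInterpolator(axes, ev, bounds_error=False, fill_value=np.nan)
    pts = reference.origin + fail_idx * reference.spacing
    ref_fail = ref[tuple(fail_idx.T)]
    best = np.square((ev[tuple(fail_idx.T)] - ref_fail) / crit)

    # sub-voxel offset lattice inside the DTA ball, step = spacing / 3
    steps = reference.spacing / 3.0
    offs = []
    ranges = [np.arange(-np.floor(dta_mm / s), np.floor(dta_mm / s) + 1) * s for s in steps]
    for ox in ranges[0]:
        for oy in ranges[1]:
            for oz in ranges[2]:
                d2 = ox * ox + oy * oy + oz * oz
                if 0 < d2 <= dta_mm**2:
                    offs.append((ox, oy, oz, d2))
    offs.sort(key=lambda o: o[3])

    alive = np.ones(len(fail_idx), dtype=bool)
    for ox, oy, oz, d2 in offs:
        if not alive.any():
            break
        dist_term = d2 / dta_mm**2
        sub = np.where(alive)[0]
        vals = interp(pts[sub] + np.array([ox, oy, oz]))
        dd = np.square((vals - ref_fail[sub]) / crit)
        g2 = dist_term + dd
        g2 = np.where(np.isnan(g2), np.inf, g2)
        best[sub] = np.minimum(best[sub], g2)
        alive[sub[best[sub] <= 1.0]] = False

    n_fail = int(np.sum(best > 1.0))
    return 100.0 * (n_considered - n_fail) / n_considered


def axial_radial_errors(implanted: np.ndarray, planned: np.ndarray,
                        needle_axes: np.ndarray, paired: bool = True,
                        pairing_gate_mm: float = 5.0) -> pd.DataFrame:
    """Decompose implanted-vs-planned seed errors along and across the
    needle axis.

    ``needle_axes`` gives, per planned seed, the unit axis direction pointing
    toward the needle tip; the axial error is signed (positive toward the
    tip), the radial error is the non-negative perpendicular component.
    Unordered inputs are paired by mutual nearest neighbour within
    ``pairing_gate_mm``.
    """
    implanted = np.atleast_2d(np.asarray(implanted, float))
    planned = np.atleast_2d(np.asarray(planned, float))
    axes = np.atleast_2d(np.asarray(needle_axes, float))
    if axes.shape != planned.shape:
        raise ValueError("need one axis direction per planned seed")
    if paired:
        if len(implanted) != len(planned):
            raise ValueError("paired inputs must have equal lengths")
        pairs = list(zip(range(len(planned)), range(len(planned))))
    else:
        t_impl = cKDTree(implanted)
        t_plan = cKDTree(planned)
        d1, nn_impl = t_impl.query(planned)
        _, nn_plan = t_plan.query(implanted)
        pairs = [
            (i, nn_impl[i]) for i in range(len(planned))
            if nn_plan[nn_impl[i]] == i and d1[i] <= pairing_gate_mm
        ]
    rows = []
    for ip, ii in pairs:
        u = axes[ip] / np.linalg.norm(axes[ip])
        e = implanted[ii] - planned[ip]
        ax = float(np.dot(e, u))
        rad = float(np.linalg.norm(e - ax * u))
        rows.append({"planned_index": ip, "implanted_index": ii,
                     "axial_mm": ax, "radial_mm": rad,
                     "total_mm": float(np.linalg.norm(e))})
    return pd.DataFrame(rows)


def classify_success(missed_seeds: int, max_displacement_mm: float) -> bool:
    """Case success rule: every seed reachable, or every reachable seed
    displaced by less than 1.5 mm."""
    if missed_seeds == 0:
        return True
    if np.isnan(max_displacement_mm):
        return False
    return bool(max_displacement_mm < SUCCESS_DISPLACEMENT_MM)


def compare_plans(metrics_a: list, metrics_b: list,
                  names: tuple[str, str] = ("proposed", "baseline")) -> pd.DataFrame:
    """Paired per-metric comparison of two plan groups.

    Returns mean ± SD for both groups and a paired two-sided t-test p-value
    per metric.  Degenerate cases: identical paired values give p = 1;
    a constant non-zero difference (zero variance) is reported as p = 0 with
    the ``degenerate`` flag set.
    """
    if len(metrics_a) != len(metrics_b) or len(metrics_a) < 2:
        raise ValueError("need >= 2 paired cases")
    da = pd.DataFrame([m.as_dict() if isinstance(m, PlanMetrics) else dict(m) for m in metrics_a])
    db = pd.DataFrame([m.as_dict() if isinstance(m, PlanMetrics) else dict(m) for m in metrics_b])
    rows = []
    for col in da.columns:
        a, b = da[col].to_numpy(float), db[col].to_numpy(float)
        ok = np.isfinite(a) & np.isfinite(b)
        a, b = a[ok], b[ok]
        if len(a) == 0:  # metric absent from both groups (e.g. unset gamma)
            continue
        diff = a - b
        degenerate = bool(np.allclose(diff.std(ddof=1) if len(diff) > 1 else 0.0, 0.0))
        if degenerate:
            p = 1.0 if np.allclose(diff, 0.0) else 0.0
        else:
            p = float(stats.ttest_rel(a, b).pvalue)
        rows.append({
            "metric": col,
            f"{names[0]}_mean": float(a.mean()), f"{names[0]}_sd": float(a.std(ddof=1)),
            f"{names[1]}_mean": float(b.mean()), f"{names[1]}_sd": float(b.std(ddof=1)),
            "p_value": p, "degenerate": degenerate,
        })
    return pd.DataFrame(rows)


def scale_to_d90(dose: DoseGrid, ptv_mask: StructureMask, prescription: float) -> DoseGrid:
    """Rescale a plan so its PTV D90 equals the prescription (the common
    normalization for cross-plan DVH comparison)."""
    d90 = dvh_metrics(dose, ptv_mask, prescription).d90
    if d90 <= 0:
        raise ValueError("cannot normalize a plan with non-positive D90")
    return DoseGrid(origin=dose.origin, spacing=dose.spacing,
                    values=dose.values * (prescription / d90))
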
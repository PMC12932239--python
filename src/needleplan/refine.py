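"""Constrained refinement of Hough-derived needle trajectories.

Each needle's hub (shaft point) may move inside a cubic neighbourhood of its
initial position while the tip stays fixed; all hubs are optimized jointly
(the pairwise gripper-workspace separation couples the needles) to minimize
the summed perpendicular seed-to-axis distances, subject to:

* needle length equality — ``‖P_S − P_T‖ = C_l`` (the physical needle is rigid);
* accessibility (hard) — insertion depth from the body-surface entry point to
  the tip must not exceed ``L_max``;
* stability (soft) — insertion depth at least ``L_min``;
* obstacle clearance (soft) — the axis stays outside every enveloping sphere;
* gripper workspace (soft) — pairwise hub separation at least ``d_g``;
* robot workspace (hard) — hubs inside an admissible axis-aligned box.

The problem is solved with scipy's SLSQP.  On failure the search cube is
enlarged and the solve retried; needles still violating hard constraints are
flagged infeasible and their seeds marked missed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .geometry import (
    NeedleTrajectory,
    Line3,
    as_point,
    point_line_distance,
    points_line_distance,
    project_point_to_line,
)

__all__ = [
    "ObstacleSphere",
    "RefineConfig",
    "ResidualTable",
    "RefinedPlan",
    "envelope_obstacle",
    "objective",
    "constraint_residuals",
    "refine_needles",
    "feasibility_report",
]


@dataclass(frozen=True)
class ObstacleSphere:
    """Enveloping sphere of an anatomical obstacle; radius includes margin."""

    center: np.ndarray
    radius: float

    def __post_init__(self):
        object.__setattr__(self, "center", as_point(self.center))
        if self.radius <= 0:
            raise ValueError("obstacle radius must be positive")


@dataclass
class RefineConfig:
    """Parameters of the refinement problem.  Lengths in mm.

    ``depth_mode='entry'`` measures insertion depth from the body-surface
    entry point (the intersection of the needle axis with ``body_surface``,
    or with the workspace box boundary when no surface is given) to the tip;
    ``'literal'`` uses ‖P_T − P_S‖, which the fixed-length equality pins to
    ``needle_length``.
    """

    l_max: float = 150.0          # max insertion depth (accessibility, hard)
    l_min: float = 20.0           # min insertion depth (stability, soft)
    d_g: float = 20.0             # gripper working-space radius
    needle_length: float = 200.0  # fixed physical needle length C_l
    r_search: float = 5.0         # cubic hub neighbourhood half-width
    enlargement_factor: float = 2.0
    max_enlargements: int = 2
    tol: float = 1e-6
    workspace_box: np.ndarray | None = None  # (2, 3): [min_corner, max_corner]
    body_surface: dict | None = None  # {"type":"sphere","center","radius"} or {"type":"plane","z"}
    depth_mode: str = "entry"     # "entry" | "literal"
    workspace_at: str = "hub"     # apply d_g at "hub" or "tip" points
    soft_penalty_weight: float = 1.0  # quadratic penalty weight in relaxed mode
    modified_threshold: float = 0.1   # hub displacement (mm) counting as "modified"

    def __post_init__(self):
        if self.l_min >= self.l_max:
            raise ValueError("l_min must be < l_max")
        if self.r_search <= 0 or self.d_g <= 0:
            raise ValueError("r_search and d_g must be positive")
        if self.workspace_box is not None:
            self.workspace_box = np.asarray(self.workspace_box, dtype=float).reshape(2, 3)


def envelope_obstacle(obstacle, sphere_count: int = 1, margin: float = 2.0,
                      origin=None, spacing=None) -> list[ObstacleSphere]:
    """Cover an irregular obstacle with ``sphere_count`` equal-radius spheres.

    ``obstacle`` is either an (n, 3) point array or a binary voxel mask (with
    ``origin``/``spacing`` giving world coordinates of voxel centers).
    Centers are chosen greedily: the first nearest the obstacle centroid, the
    rest by farthest-point placement; the common radius is the minimal radius
    covering every point for those centers, plus ``margin``.
    """
    if sphere_count < 1:
        raise ValueError("sphere_count must be >= 1")
    obstacle = np.asarray(obstacle)
    if obstacle.ndim == 3:  # binary mask
        if origin is None or spacing is None:
            raise ValueError("mask input requires origin and spacing")
        idx = np.argwhere(obstacle > 0)
        points = np.asarray(origin, dtype=float) + idx * np.asarray(spacing, dtype=float)
    else:
        points = np.atleast_2d(obstacle).astype(float)
    if len(points) == 0:
        raise ValueError("empty obstacle")
    centroid = points.mean(axis=0)
    first = int(np.argmin(np.linalg.norm(points - centroid, axis=1)))
    centers = [points[first]]
    d = np.linalg.norm(points - centers[0], axis=1)
    for _ in range(1, min(sphere_count, len(points))):
        nxt = int(np.argmax(d))
        centers.append(points[nxt])
        d = np.minimum(d, np.linalg.norm(points - points[nxt], axis=1))
    radius = float(d.max()) + margin
    if radius <= 0:
        radius = max(margin, 1e-6)
    return [ObstacleSphere(center=c, radius=radius) for c in centers]


def objective(needles: list[NeedleTrajectory], seeds: np.ndarray, seed_ids: list) -> float:
    """Total seed-to-axis deviation: sum over needles and their assigned
    seeds of the perpendicular distance to the needle axis (mm).

    The seed-to-needle assignment is carried by ``assigned_seed_ids``; every
    seed id must appear on exactly one needle."""
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    id_index = {s: i for i, s in enumerate(seed_ids)}
    covered = []
    total = 0.0
    for n in needles:
        ids = n.assigned_seed_ids
        if not ids:
            continue
        rows = [id_index[s] for s in ids]
        covered += ids
        total += float(points_line_distance(seeds[rows], n.p_s, n.p_t).sum())
    if sorted(covered) != sorted(seed_ids):
        raise ValueError("every seed must be assigned to exactly one needle")
    return total


def _entry_depth(p_s: np.ndarray, p_t: np.ndarray, cfg: RefineConfig) -> float:
    """Insertion depth: distance along the axis from the body-surface entry
    point to the tip.  Falls back to the workspace-box boundary, then to the
    literal hub-to-tip distance."""
    length = float(np.linalg.norm(p_t - p_s))
    if cfg.depth_mode == "literal":
        return length
    u = (p_t - p_s) / max(length, 1e-12)
    surf = cfg.body_surface
    if surf is not None and surf.get("type") == "sphere":
        c = np.asarray(surf["center"], dtype=float)
        r = float(surf["radius"])
        # entry = first axis/sphere intersection along the insertion direction
        w = p_s - c
        b_lin = float(np.dot(w, u))
        disc = b_lin * b_lin - (float(np.dot(w, w)) - r * r)
        if disc <= 0.0:
            return 0.0  # axis misses the body: nothing inserted
        s_entry = -b_lin - np.sqrt(disc)
        return length - s_entry
    if surf is not None and surf.get("type") == "plane":
        z0 = float(surf["z"])
        if abs(u[2]) < 1e-9:
            return length
        s_entry = (z0 - p_s[2]) / u[2]
        return length - s_entry
    if cfg.workspace_box is not None:
        lo, hi = cfg.workspace_box
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = (lo - p_s) / u
            t2 = (hi - p_s) / u
        t_far = np.nanmax(np.minimum(t1, t2))  # exit of the box along u
        return length - t_far
    # no entry model at all: the insertion depth is unknowable, and the
    # fixed-length equality pins ‖P_T − P_S‖, so depth bounds are inactive
    return float("nan")


@dataclass
class ResidualTable:
    """Signed constraint residuals; positive means satisfied.

    ``length`` holds the absolute violation of the fixed-length equality.
    ``separation`` is condensed over needle pairs (i < j).
    """

    accessibility: np.ndarray      # (n,) L_max - depth
    stability: np.ndarray          # (n,) depth - L_min
    obstacle: np.ndarray           # (n, n_spheres) axis clearance - radius
    separation: np.ndarray         # (n*(n-1)/2,) pairwise point separation - d_g
    length: np.ndarray             # (n,) |‖P_S - P_T‖ - C_l|, reported as violation
    workspace: np.ndarray          # (n,) min slack of hub inside the admissible box

    def hard_ok(self, i: int, tol: float) -> bool:
        return self.accessibility[i] >= -tol and self.workspace[i] >= -tol

    def all_ok(self, i: int, n_needles: int, tol: float) -> bool:
        if not self.hard_ok(i, tol):
            return False
        if self.stability[i] < -tol or self.length[i] > tol:
            return False
        if self.obstacle.size and np.any(self.obstacle[i] < -tol):
            return False
        if n_needles > 1 and self.separation.size:
            k = 0
            for a in range(n_needles):
                for b in range(a + 1, n_needles):
                    if (a == i or b == i) and self.separation[k] < -tol:
                        return False
                    k += 1
        return True


def constraint_residuals(needles: list[NeedleTrajectory],
                         obstacles: list[ObstacleSphere],
                         cfg: RefineConfig) -> ResidualTable:
    """Evaluate every refinement constraint for the given needle set."""
    if not needles:
        raise ValueError("need at least one needle")
    n = len(needles)
    depth = np.array([_entry_depth(nd.p_s, nd.p_t, cfg) for nd in needles])
    acc = np.where(np.isnan(depth), np.inf, cfg.l_max - depth)
    stab = np.where(np.isnan(depth), np.inf, depth - cfg.l_min)
    if obstacles:
        obs = np.array(
            [[point_line_distance(o.center, nd.p_s, nd.p_t) - o.radius
              for o in obstacles] for nd in needles]
        )
    else:
        obs = np.zeros((n, 0))
    pts = np.array([nd.p_s if cfg.workspace_at == "hub" else nd.p_t for nd in needles])
    sep = []
    for i in range(n):
        for j in range(i + 1, n):
            sep.append(float(np.linalg.norm(pts[i] - pts[j])) - cfg.d_g)
    length = np.array(
        [abs(float(np.linalg.norm(nd.p_s - nd.p_t)) - cfg.needle_length) for nd in needles]
    )
    if cfg.workspace_box is not None:
        lo, hi = cfg.workspace_box
        ws = np.array(
            [min(float(np.min(nd.p_s - lo)), float(np.min(hi - nd.p_s))) for nd in needles]
        )
    else:
        ws = np.full(n, np.inf)
    return ResidualTable(accessibility=acc, stability=stab, obstacle=obs,
                         separation=np.asarray(sep), length=length, workspace=ws)


@dataclass
class RefinedPlan:
    """Outcome of joint hub refinement."""

    needles: list[NeedleTrajectory]
    seed_plan: pd.DataFrame  # columns: seed_id, x/y/z planned, x/y/z optimized, displacement_mm, missed, needle_index
    err: float
    residuals: ResidualTable
    modified_count: int
    relaxed: bool = False


def _pack(needles):
    return np.concatenate([nd.p_s for nd in needles])


def _solve(tips, hubs0, seeds_by_needle, obstacles, cfg, r, relax_soft):
    """One joint SLSQP solve over all hub coordinates."""
    n = len(tips)
    tips = np.asarray(tips, float)
    x0 = np.asarray(hubs0, float).ravel()
    eps = 1e-18

    def hubs_of(x):
        return x.reshape(n, 3)

    def fun(x):
        hubs = hubs_of(x)
        total = 0.0
        for i in range(n):
            pts = seeds_by_needle[i]
            if len(pts) == 0:
                continue
            axis = tips[i] - hubs[i]
            dn = np.linalg.norm(axis)
            cr = np.cross(pts - hubs[i], pts - tips[i])
            d = np.sqrt(np.sum(cr * cr, axis=1) + eps) / max(dn, 1e-9)
            total += d.sum()
        if relax_soft:
            g = _soft_vals(x)
            viol = np.minimum(g, 0.0)
            total += cfg.soft_penalty_weight * float(np.sum(viol * viol))
        return total

    def _depths(x):
        hubs = hubs_of(x)
        d = np.array([_entry_depth(hubs[i], tips[i], cfg) for i in range(n)])
        # unknowable depth -> constraints inactive (finite slack for SLSQP)
        return np.where(np.isnan(d), 0.5 * (cfg.l_min + cfg.l_max), d)

    def _hard_vals(x):
        hubs = hubs_of(x)
        vals = list(cfg.l_max - _depths(x))
        if cfg.workspace_box is not None:
            lo, hi = cfg.workspace_box
            for i in range(n):
                vals += list(hubs[i] - lo) + list(hi - hubs[i])
        return np.asarray(vals)

    obs_centers = np.array([o.center for o in obstacles]).reshape(-1, 3)
    obs_radii = np.array([o.radius for o in obstacles])
    iu, ju = np.triu_indices(n, k=1)

    def _soft_vals(x):
        hubs = hubs_of(x)
        vals = [_depths(x) - cfg.l_min]
        if len(obstacles):
            for i in range(n):
                cr = np.cross(obs_centers - hubs[i], obs_centers - tips[i])
                dn = max(float(np.linalg.norm(tips[i] - hubs[i])), 1e-9)
                vals.append(np.linalg.norm(cr, axis=1) / dn - obs_radii)
        if n > 1:
            pts = hubs if cfg.workspace_at == "hub" else tips
            vals.append(np.linalg.norm(pts[iu] - pts[ju], axis=1) - cfg.d_g)
        return np.concatenate(vals)

    def _eq_vals(x):
        hubs = hubs_of(x)
        return np.array(
            [np.linalg.norm(hubs[i] - tips[i]) - cfg.needle_length for i in range(n)]
        )

    cons = [{"type": "eq", "fun": _eq_vals}, {"type": "ineq", "fun": _hard_vals}]
    if not relax_soft:
        cons.append({"type": "ineq", "fun": _soft_vals})
    bounds = [(x0[k] - r, x0[k] + r) for k in range(3 * n)]
    res = minimize(fun, x0, method="SLSQP", bounds=bounds, constraints=cons,
                   options={"maxiter": 300, "ftol": 1e-9})
    return res


def refine_needles(needles: list[NeedleTrajectory], seeds: np.ndarray,
                   seed_ids: list, obstacles: list[ObstacleSphere],
                   cfg: RefineConfig, rng_seed: int = 0) -> RefinedPlan:
    """Jointly optimize all hub positions and build the refined seed plan.

    Tips stay fixed.  On solver failure or residual constraint violation the
    cubic search region is enlarged (``enlargement_factor``, up to
    ``max_enlargements`` times); if the strict problem remains unsolved, soft
    constraints are relaxed into a quadratic penalty and hard constraints
    kept.  Needles that still violate a hard constraint (accessibility or
    workspace membership) are marked infeasible and their seeds missed.
    Deterministic for fixed inputs; ``rng_seed`` is accepted for interface
    stability (the solve itself is deterministic).
    """
    del rng_seed  # deterministic pipeline: nothing random to seed
    if not needles:
        raise ValueError("need at least one needle")
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    id_index = {s: i for i, s in enumerate(seed_ids)}
    seeds_by_needle = [
        seeds[[id_index[s] for s in nd.assigned_seed_ids]] for nd in needles
    ]
    tips = np.array([nd.p_t for nd in needles])
    hubs0 = np.array([nd.p_s for nd in needles])

    def _ok(x, relaxed):
        trial = [
            replace_needle(needles[i], x.reshape(-1, 3)[i], tips[i]) for i in range(len(needles))
        ]
        rt = constraint_residuals(trial, obstacles, cfg)
        hard = all(rt.hard_ok(i, cfg.tol) for i in range(len(needles)))
        if relaxed:
            return hard
        soft = (
            np.all(rt.stability >= -cfg.tol)
            and (rt.obstacle.size == 0 or np.all(rt.obstacle >= -cfg.tol))
            and (rt.separation.size == 0 or np.all(rt.separation >= -cfg.tol))
        )
        return hard and soft and np.all(rt.length <= max(cfg.tol, 1e-6))

    def _err_of(x):
        hubs = x.reshape(-1, 3)
        total = 0.0
        for i in range(len(needles)):
            if len(seeds_by_needle[i]):
                total += float(points_line_distance(
                    seeds_by_needle[i], hubs[i], tips[i]).sum())
        return total

    x0 = _pack(needles)
    best_x = None
    relaxed = False
    r = cfg.r_search
    for attempt in range(cfg.max_enlargements + 1):
        res = _solve(tips, hubs0, seeds_by_needle, obstacles, cfg, r, relax_soft=False)
        if res.success and _ok(res.x, relaxed=False):
            best_x = res.x
            break
        r *= cfg.enlargement_factor
    if best_x is None:
        # strict problem infeasible: relax soft constraints into a penalty
        r = cfg.r_search * cfg.enlargement_factor**cfg.max_enlargements
        res = _solve(tips, hubs0, seeds_by_needle, obstacles, cfg, r, relax_soft=True)
        relaxed = True
        best_x = res.x if res.success and _ok(res.x, relaxed=True) else x0
    # never worsen a feasible start
    if not relaxed and _ok(x0, relaxed=False) and _err_of(x0) <= _err_of(best_x):
        best_x = x0
    # minimal-modification cleanup: restore any hub whose move buys nothing
    if not relaxed:
        for i in range(len(needles)):
            trial = best_x.copy()
            trial[3 * i:3 * i + 3] = x0[3 * i:3 * i + 3]
            if _ok(trial, relaxed=False) and _err_of(trial) <= _err_of(best_x) + 1e-12:
                best_x = trial

    hubs = best_x.reshape(-1, 3)
    out_needles = []
    for i, nd in enumerate(needles):
        new = replace_needle(nd, hubs[i], tips[i])
        new.modified = bool(np.linalg.norm(hubs[i] - hubs0[i]) > cfg.modified_threshold)
        out_needles.append(new)
    rt = constraint_residuals(out_needles, obstacles, cfg)
    for i, nd in enumerate(out_needles):
        nd.feasible = rt.all_ok(i, len(out_needles), max(cfg.tol, 1e-5))
        if not rt.hard_ok(i, max(cfg.tol, 1e-5)):
            nd.feasible = False

    rows = []
    for i, nd in enumerate(out_needles):
        hard_ok = rt.hard_ok(i, max(cfg.tol, 1e-5))
        axis = Line3.through_points(nd.p_s, nd.p_t)
        for s in nd.assigned_seed_ids:
            p = seeds[id_index[s]]
            if hard_ok:
                q = project_point_to_line(p, axis)
                disp = float(np.linalg.norm(p - q))
                rows.append({"seed_id": s, "x_mm": p[0], "y_mm": p[1], "z_mm": p[2],
                             "opt_x_mm": q[0], "opt_y_mm": q[1], "opt_z_mm": q[2],
                             "displacement_mm": disp, "missed": False, "needle_index": i})
            else:
                rows.append({"seed_id": s, "x_mm": p[0], "y_mm": p[1], "z_mm": p[2],
                             "opt_x_mm": np.nan, "opt_y_mm": np.nan, "opt_z_mm": np.nan,
                             "displacement_mm": np.nan, "missed": True, "needle_index": i})
    seed_plan = pd.DataFrame(rows).sort_values("seed_id").reset_index(drop=True)
    err = objective(out_needles, seeds, seed_ids)
    return RefinedPlan(
        needles=out_needles,
        seed_plan=seed_plan,
        err=err,
        residuals=rt,
        modified_count=sum(nd.modified for nd in out_needles),
        relaxed=relaxed,
    )


def replace_needle(nd: NeedleTrajectory, p_s, p_t) -> NeedleTrajectory:
    return NeedleTrajectory(
        p_s=np.asarray(p_s, float), p_t=np.asarray(p_t, float), length=nd.length,
        assigned_seed_ids=list(nd.assigned_seed_ids),
        feasible=nd.feasible, modified=nd.modified,
    )


def feasibility_report(plan: RefinedPlan, cfg: RefineConfig) -> dict:
    """Per-needle / per-seed summary of the refined plan.

    Displacements are 3D Euclidean distances between each planned seed and
    its projection onto the final needle axis (identical to the seed's
    perpendicular distance from that axis).
    """
    sp = plan.seed_plan
    reach = sp[~sp["missed"]]
    return {
        "needle_feasible": [bool(nd.feasible) for nd in plan.needles],
        "feasible_needles": int(sum(nd.feasible for nd in plan.needles)),
        "modified_needles": int(plan.modified_count),
        "missed_seeds": int(sp["missed"].sum()),
        "max_displacement_mm": float(reach["displacement_mm"].max()) if len(reach) else float("nan"),
        "mean_displacement_mm": float(reach["displacement_mm"].mean()) if len(reach) else float("nan"),
        "relaxed": bool(plan.relaxed),
    }
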
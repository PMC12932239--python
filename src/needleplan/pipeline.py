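"""Study orchestration: generate → Hough → refine → dose → evaluate.

``run_case`` executes the full planning chain for one synthetic case and
returns the per-case record (total/missed seeds, feasible and modified
needle counts, maximum seed adjustment, gamma pass rate).  ``run_study``
aggregates a multi-case study the way the simulation summary table does:
cases with missed seeds report only their missed count (their other columns
are left blank) and the summary statistics are computed over the complete
cases.  ``run_comparison`` pits the geometry-based plan against the coplanar
template baseline with paired t-tests."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import io as npio
from .config import PlannerConfig
from .dose import permanent_implant_dose
from .hough import build_direction_set, extract_lines, line_to_needle
from .metrics import (
    classify_success,
    compare_plans,
    compute_dvh,
    dvh_metrics,
    gamma_pass_rate,
    paddick_ci,
)
from .phantom import SyntheticCase, coplanar_baseline, generate_study
from .refine import feasibility_report, refine_needles

__all__ = ["run_case", "run_study", "run_comparison"]


def plan_needles(case: SyntheticCase, config: PlannerConfig, direction_set=None):
    """Hough detection + conversion of line candidates to physical needles."""
    if direction_set is None:
        direction_set = build_direction_set(config.hough_level)
    candidates = extract_lines(
        case.seeds, direction_set, spatial_step=config.spatial_step_mm,
        capture_radius=config.capture_radius_mm, min_votes=config.min_votes,
        seed_ids=case.seed_ids,
    )
    return [
        line_to_needle(c, case.seeds, case.seed_ids,
                       needle_length=config.needle_length_mm,
                       entry_direction_hint=case.entry_hint)
        for c in candidates
    ]


def run_case(case: SyntheticCase, config: PlannerConfig, direction_set=None,
             outdir=None) -> dict:
    """Full pipeline for one case; deterministic for a fixed case/config."""
    needles = plan_needles(case, config, direction_set)
    rcfg = config.refine_config(workspace_box=case.workspace_box,
                                body_surface=case.body_surface)
    plan = refine_needles(needles, case.seeds, case.seed_ids, case.obstacles,
                          rcfg, rng_seed=case.rng_seed)
    report = feasibility_report(plan, rcfg)

    spec = case.default_grid_spec(spacing=config.grid_spacing_mm,
                                  dims=config.grid_dims)
    dose_planned = permanent_implant_dose(case.seeds, config.activity_mci, **spec)
    sp = plan.seed_plan
    opt = sp.loc[~sp["missed"], ["opt_x_mm", "opt_y_mm", "opt_z_mm"]].to_numpy(float)
    record = {
        "case_id": case.case_id,
        "total_seeds": case.n_seeds,
        "missed_seeds": report["missed_seeds"],
        "needles": report["feasible_needles"],
        "needles_total": len(plan.needles),
        "modified_needles": report["modified_needles"],
        "max_seed_adjustment_mm": report["max_displacement_mm"],
        "mean_seed_adjustment_mm": report["mean_displacement_mm"],
        "relaxed": report["relaxed"],
        "err_mm": plan.err,
    }
    if len(opt) == 0:
        record.update({"gamma_pct": float("nan")})
        record["success"] = classify_success(record["missed_seeds"], float("nan"))
        return record
    dose_opt = permanent_implant_dose(opt, config.activity_mci, **spec)
    record["gamma_pct"] = gamma_pass_rate(
        dose_planned, dose_opt, dta_mm=config.gamma_dta_mm,
        dose_crit_pct=config.gamma_dose_crit_pct, norm_gy=config.prescription_gy,
        low_dose_cutoff_pct=config.gamma_low_dose_cutoff_pct,
    )
    record["success"] = classify_success(record["missed_seeds"],
                                         record["max_seed_adjustment_mm"])
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        npio.write_needles_json(outdir / f"{case.case_id}_needles.json", plan.needles)
        sp.to_csv(outdir / f"{case.case_id}_seed_plan.csv", index=False)
        npio.write_nrrd(outdir / f"{case.case_id}_dose_planned.nrrd", dose_planned)
        npio.write_nrrd(outdir / f"{case.case_id}_dose_optimized.nrrd", dose_opt)
        ptv = case.ptv_mask(dose_planned)
        for name, grid in (("planned", dose_planned), ("optimized", dose_opt)):
            curve = compute_dvh(grid, ptv, config.dvh_bin_gy)
            pd.DataFrame({"dose_Gy": curve.dose_edges,
                          "volume_pct": curve.volume_pct}
                         ).to_csv(outdir / f"{case.case_id}_dvh_{name}.csv", index=False)
    return record


def run_study(n_cases: int, config: PlannerConfig, outdir=None) -> dict:
    """Run the multi-case simulation study and aggregate its statistics.

    Returns ``{"table": per-case DataFrame, "summary": dict, "config": dict}``.
    Aggregate means/SDs are computed over cases without missed seeds (the
    incomplete cases contribute only to the missed-seed and success-rate
    tallies, mirroring the study summary-table convention).
    """
    cases = generate_study(n_cases, rng_seed=config.master_seed,
                           n_obstacles=config.n_obstacles,
                           sphere_radius=config.sphere_radius_mm)
    ds = build_direction_set(config.hough_level)
    records = []
    for case in cases:
        try:
            records.append(run_case(case, config, direction_set=ds, outdir=outdir))
        except Exception as exc:  # record the failure, keep the study running
            records.append({"case_id": case.case_id, "total_seeds": case.n_seeds,
                            "error": repr(exc), "success": False,
                            "missed_seeds": -1, "gamma_pct": float("nan"),
                            "needles": np.nan, "modified_needles": np.nan,
                            "max_seed_adjustment_mm": np.nan})
    table = pd.DataFrame(records)
    complete = table[table["missed_seeds"] == 0]
    summary = {
        "n_cases": int(n_cases),
        "n_complete": int(len(complete)),
        "mean_feasible_needles": float(complete["needles"].mean()),
        "sd_feasible_needles": float(complete["needles"].std(ddof=1)),
        "mean_max_seed_adjustment_mm": float(complete["max_seed_adjustment_mm"].mean()),
        "sd_max_seed_adjustment_mm": float(complete["max_seed_adjustment_mm"].std(ddof=1)),
        "mean_gamma_pct": float(complete["gamma_pct"].mean()),
        "sd_gamma_pct": float(complete["gamma_pct"].std(ddof=1)),
        "success_rate_pct": float(100.0 * table["success"].mean()),
    }
    result = {"table": table, "summary": summary, "config": config.to_dict()}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "study_table.csv", index=False)
    return result


def run_comparison(cases: list[SyntheticCase], config: PlannerConfig) -> dict:
    """Geometry-based plan vs coplanar template baseline, paired per case.

    Both arms use the same seed model, activity and seed count; only the
    spatial seed distribution differs.  Metrics are computed on the absolute
    dose grids against a common prescription.
    """
    if len(cases) < 2:
        raise ValueError("comparison needs >= 2 cases")
    ds = build_direction_set(config.hough_level)
    rows_a, rows_b, skipped = [], [], []
    for case in cases:
        try:
            baseline = coplanar_baseline(case, grid_pitch=config.baseline_pitch_mm)
        except ValueError as exc:
            skipped.append((case.case_id, repr(exc)))
            continue
        needles = plan_needles(case, config, ds)
        rcfg = config.refine_config(workspace_box=case.workspace_box,
                                    body_surface=case.body_surface)
        plan = refine_needles(needles, case.seeds, case.seed_ids, case.obstacles,
                              rcfg, rng_seed=case.rng_seed)
        sp = plan.seed_plan
        opt = sp.loc[~sp["missed"], ["opt_x_mm", "opt_y_mm", "opt_z_mm"]].to_numpy(float)
        if len(opt) == 0:
            skipped.append((case.case_id, "no reachable seeds"))
            continue
        spec = case.default_grid_spec(spacing=config.grid_spacing_mm,
                                      dims=config.grid_dims)
        dose_a = permanent_implant_dose(opt, config.activity_mci, **spec)
        dose_b = permanent_implant_dose(baseline, config.activity_mci, **spec)
        ptv = case.ptv_mask(dose_a)
        ma = dvh_metrics(dose_a, ptv, config.prescription_gy)
        mb = dvh_metrics(dose_b, ptv, config.prescription_gy)
        ma.ci = paddick_ci(dose_a, ptv, config.prescription_gy)
        mb.ci = paddick_ci(dose_b, ptv, config.prescription_gy)
        rows_a.append(ma)
        rows_b.append(mb)
    comparison = compare_plans(rows_a, rows_b, names=("geometry", "coplanar"))
    comparison = comparison[comparison["metric"] != "gamma_pass"]
    per_case = pd.DataFrame({
        "case_id": [c.case_id for c in cases if c.case_id not in [s[0] for s in skipped]],
        **{f"geometry_{k}": [m.as_dict()[k] for m in rows_a] for k in ("V150", "V200", "D90", "Dmean", "CI")},
        **{f"coplanar_{k}": [m.as_dict()[k] for m in rows_b] for k in ("V150", "V200", "D90", "Dmean", "CI")},
    })
    return {"comparison": comparison, "per_case": per_case, "skipped": skipped}
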
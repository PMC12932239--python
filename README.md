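# needleplan

Post-planning needle-trajectory planning for robotic low-dose-rate (LDR)
seed brachytherapy.

In LDR brachytherapy a treatment planning system (TPS) produces a set of
seed dwell positions with good dosimetry.  Executing that plan with a
robot raises a separate, purely geometric problem: seeds must be deposited
along straight needle tracks, and the needles must respect anatomy (bones,
organs at risk), insertion-depth limits, the gripper's working space and
the robot's reachable workspace.  `needleplan` solves this post-TPS step
for medical-physics and surgical-robotics researchers:

1. **Needle detection** — a 3D Hough transform over an icosahedrally
   discretized direction sphere (level 6 ≈ 1.03° mean resolution, 0.2 mm
   anchor bins) groups near-collinear seeds into candidate straight
   trajectories, refit by orthogonal least squares.
2. **Constrained refinement** — with tips `P_T` fixed, all hub points
   `P_S` are optimized jointly (SLSQP) to minimize the summed
   perpendicular seed-to-axis deviation
   `err = Σᵢ Σⱼ ‖(P_ij − P_S) × (P_ij − P_T)‖ / ‖P_S − P_T‖`
   subject to fixed needle length `‖P_S − P_T‖ = C_l`, insertion depth in
   `[L_min, L_max]`, obstacle-sphere clearance, pairwise hub separation
   ≥ `d_g`, and hub membership in the robot workspace box.  Seeds are
   re-dwelled by orthogonal projection onto the final axes; seeds on
   needles that violate hard constraints are reported *missed*.
3. **Dosimetric verification** — TG-43 1D dose grids for I-125 model 6711
   implants, DVH and V150/V200/D90/Dmean, Paddick conformity index,
   global-normalization gamma analysis (2 mm / 2 %), and a success rule
   (all seeds reachable, or every reachable seed displaced < 1.5 mm).
4. **Synthetic studies** — multi-sphere aggregated tumor shapes with seed
   positions from an equal-sphere partition of the shape, bone-like
   obstacle chains, a coplanar-template baseline plan, and CT-like volumes
   with Gaussian-mixture seed localization.

See `docs/methods.md` for the model, assumptions and parameter choices.

## Worked example

Generate one synthetic 25-seed case and run the full pipeline:

```python
import json
from needleplan import PlannerConfig
from needleplan.phantom import generate_study
from needleplan.pipeline import run_case

config = PlannerConfig(master_seed=1234)
case = generate_study(1, rng_seed=1234)[0]
record = run_case(case, config)
print(json.dumps({k: (round(v, 3) if isinstance(v, float) else v)
                  for k, v in record.items()}, indent=1))
```

prints

```json
{
 "case_id": "C1",
 "total_seeds": 25,
 "missed_seeds": 0,
 "needles": 9,
 "needles_total": 9,
 "modified_needles": 4,
 "max_seed_adjustment_mm": 1.802,
 "mean_seed_adjustment_mm": 0.288,
 "relaxed": false,
 "err_mm": 7.209,
 "gamma_pct": 98.838,
 "success": true
}
```

The 25 planned seeds were grouped onto 9 feasible needles; satisfying the
constraints (here, mostly the 20 mm gripper-workspace separation between
parallel needles) required modifying 4 of them, displacing the most-affected
seed by 1.80 mm and 0.29 mm on average.  Recomputing the TG-43 dose for the
projected seed positions and comparing it with the planned dose gives a
2 mm / 2 % gamma pass rate of 98.8 %; with no missed seeds the case counts
as a success.

The same pipeline is scriptable from the shell:

```sh
needleplan generate --cases 20 --seed 1234 --out study/
needleplan plan --seeds study/C1_seeds.csv --out study/C1_needles.json
needleplan run-study --cases 20 --seed 1234 --out study/
needleplan run-comparison --cases 10 --seed 1234 --out comparison/
```

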
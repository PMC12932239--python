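# Methods

`needleplan` addresses the post-planning step of robotic low-dose-rate (LDR)
seed brachytherapy: a treatment planning system has already produced a
dose-optimized set of seed dwell positions, and the task is to turn those
positions into straight, robot-executable needle trajectories that respect
anatomical and mechanical constraints while disturbing the planned dose as
little as possible.  Dosimetric trade-offs are assumed to be settled
upstream; the package never re-optimizes dwell times or seed strengths.

## Needle detection: 3D Hough transform

A straight needle axis is an undirected 3D line, parameterized by a unit
direction `b` and an anchor point `A` — the point of the line closest to the
origin, expressed in an orthonormal basis `(e1, e2)` of the plane through
the origin orthogonal to `b` (Roberts' optimal line representation).  The
basis is

```
e1 = (1 − bx²/(1+bz),  −bx·by/(1+bz),  −bx)
e2 = (−bx·by/(1+bz),   1 − by²/(1+bz), −by)
```

and `(x', y') = (P·e1, P·e2)` are the anchor coordinates of the line through
point `P` with direction `b`.  The representation is singular only at
`b = −ẑ`, which never occurs because directions are restricted to the upper
hemisphere (lines are undirected, so antipodal directions are identified;
ties on the equator are broken lexicographically).

Directions are discretized by icosahedral subdivision: each triangle of the
icosahedron is split into four through sphere-projected edge midpoints, so
level *L* has `10·4^L + 2` vertices, halved by antipodal identification.
The default is level 6 (20 481 directions, mean nearest-neighbour spacing
1.03°, max 1.18°); anchor coordinates are binned at 0.2 mm.

Every seed votes, for every direction, into the anchor-plane cell containing
its projection.  Peaks of this accumulator are lines supported by many
nearly-collinear seeds.  Extraction is iterative: find the best cell, assign
remaining seeds within the capture radius of that cell's line, refit the
line to the assigned seeds by orthogonal least squares (principal direction
through the centroid), re-assign around the refit line, remove the assigned
seeds, repeat until the best peak drops below the minimum vote count; any
leftover seed becomes a singleton trajectory along its locally best-voted
direction.  Two refinements of the textbook scheme matter in practice:

* **Windowed peak scoring.**  At 0.2 mm bins, seeds that are only
  *approximately* collinear scatter their votes over neighbouring cells and
  the raw per-cell maximum degenerates.  Peaks are therefore scored by the
  votes within a capture-radius window of each cell (standard accumulator
  smoothing); the fine accumulator itself is unchanged and still satisfies
  exact vote conservation (`total = n_seeds × n_directions`).
* **Top-K peak evaluation and nearest-axis consolidation.**  The highest
  windowed peak can be a transversal line that clips single seeds from
  several true rows.  The extractor evaluates the top 32 tie-broken peaks by
  their actual post-refit capture size and keeps the best; after extraction,
  seeds are reassigned to their nearest detected axis and lines refit until
  stable (k-lines iterations), which directly serves the planning objective
  of minimal summed seed-to-axis deviation.

The capture radius defaults to 1.5 mm — the displacement that the study's
clinical success rule still accepts for a repositioned seed.  For seeds
placed exactly on a line the detected axis agrees with the truth to
numerical precision (well below the 0.08 mm design bound).

A detected line becomes a physical needle by fixing the direction sign so
the hub lies on the entry side, placing the tip `P_T` at the distal-most
assigned seed (`t = b·(P_q − A)`, `P_T = A + t·b`) and the hub at
`P_S = P_T − C_l·b` with `C_l` the fixed physical needle length.

## Constraint-based refinement

Hough-derived needles may clash with anatomy or the robot.  Refinement
moves each hub inside a cubic neighbourhood `P_S⁰ ± r` (tip fixed) and
minimizes the total perpendicular seed-to-axis deviation

```
err = Σ_i Σ_j ‖(P_ij − P_S) × (P_ij − P_T)‖ / ‖P_S − P_T‖
```

subject to, per needle: fixed length `‖P_S − P_T‖ = C_l` (equality);
insertion depth ≤ `L_max` (hard) and ≥ `L_min` (soft); axis clearance of
every obstacle-envelope sphere ≥ its radius (soft); pairwise hub separation
≥ the gripper workspace radius `d_g` (soft); hub membership in the robot's
admissible box (hard).  All hubs are optimized jointly — the pairwise
separation couples the needles — with SLSQP.  On failure the search cube is
enlarged (factor 2, up to twice); if the strict problem remains infeasible
the soft constraints move into a quadratic penalty while hard constraints
stay.  Needles that still violate a hard constraint are infeasible and their
seeds are *missed*; all other seeds are re-dwelled by orthogonal projection
onto the final axis, so a seed's adjustment distance equals its
perpendicular distance from that axis.

Two solver details keep the output minimal: a feasible start is never
worsened, and after the solve any hub whose move buys no objective
improvement is restored (so "modified needles" counts needles whose final
hub moved more than 0.1 mm for a reason).

Interpretation choices, made where the constraint formulas alone are
ambiguous:

* **Insertion depth.**  The fixed-length equality would make literal
  depth bounds on `‖P_T − P_S‖` vacuous, so depth is measured from the
  body-surface entry point (axis ∩ body surface; the workspace-box boundary
  when no surface is modelled) to the tip.  A `literal` mode evaluates the
  printed forms.
* **Gripper workspace.**  The separation is enforced at the hub (external)
  ends, where the gripper actually operates; a `workspace_at` switch allows
  the tip-point variant.  With tips fixed the tip variant is a constant and
  can only classify, not repair.

Defaults: `C_l = 200 mm`, `L_max = 150 mm`, `L_min = 20 mm`, `d_g = 20 mm`,
`r = 5 mm`, obstacle-envelope margin 2 mm, tolerance 1e-6.

Obstacles of arbitrary shape are enveloped by `k` equal-radius spheres:
greedy k-center placement (first center nearest the centroid, the rest by
farthest-point), radius = minimal covering radius + margin, so every
obstacle point is inside at least one sphere.

## Dosimetry: TG-43 1D formalism

Doses use the AAPM TG-43 point-source (1D) formalism for the I-125 model
6711 seed: rate(r) = `S_k · Λ · (1 cm/r)² · g(r) · φ_an(r)` in cGy/h, with
consensus-style tables for the radial dose function `g` and 1D anisotropy
factor `φ_an` packaged as JSON (dose-rate constant Λ = 0.965 cGy·h⁻¹·U⁻¹,
half-life 59.4 d, 1.27 U per apparent mCi; all overridable).  Permanent
implants integrate over full decay (τ = T½/ln 2).  The 1/r² singularity is
clamped at 1 mm; contributions beyond 100 mm (< 0.1 % of the 1-cm dose) are
dropped.  Seed orientations are not modelled — dwell positions carry no
orientation — so the 2D line-source anisotropy F(r, θ) is out of scope.
Default grid: 3.5 × 3.5 × 1.5 mm voxels, 60 × 60 × 80, centred on the
tumor; the coarse grid deliberately truncates the high-dose tail next to
seeds, which shows up as a clipped PTV DVH maximum.

## Plan evaluation

* **DVH**: cumulative, volume-weighted, 0.5 Gy bins; `Dmean` is recoverable
  as the integral of the survival curve.
* **V150/V200/D90**: fractions of PTV volume at 150 %/200 % of
  prescription; D90 is the 10th percentile of PTV voxel doses.  Default
  prescription 145 Gy.
* **Paddick CI** = (V_PTV∩PIV)² / (V_PTV · V_PIV), PIV = prescription
  isodose volume.
* **Gamma analysis** (2 mm / 2 %, global normalization to the prescription,
  10 % low-dose cutoff): a reference voxel passes when some point within
  the DTA ball has evaluated dose within the criterion.  Offsets farther
  than the DTA cannot produce γ ≤ 1 — the distance term alone exceeds 1 —
  so the pass/fail search over the sub-voxel offset lattice (spacing/3,
  linear interpolation) is restricted to the DTA ball; this is exact for
  the pass rate, not an approximation.
* **Success rule**: a case succeeds when every seed is reachable, or when
  all reachable seeds moved by less than 1.5 mm.
* **Plan comparison**: paired two-sided t-tests per metric; identical pairs
  report p = 1, a constant non-zero difference is flagged degenerate with
  p = 0.  Metrics are computed on absolute dose with a common prescription
  (both arms use the same seed model, strength and count); D90-rescaling
  (`scale_to_d90`) is available for DVH overlays.

## Seed localization

Implanted seeds are recovered from CT-like volumes by thresholding (Otsu on
a 256-bin histogram, or a fixed value) followed by Gaussian-mixture
regression: above-threshold voxels become sample points weighted by
intensity, and an isotropic, shared-variance mixture with one component per
expected seed is fit by EM, initialized at the strongest mutually
non-adjacent local maxima.  Initialization is deterministic — no random
restarts — so results are reproducible; centers are reported in
lexicographic order for stable pairing.  The shared isotropic covariance
reflects that the seeds are small identical objects.  Implantation errors
are decomposed per seed into a signed axial component (positive toward the
needle tip) and a non-negative radial component; unordered sets are paired
by mutual nearest neighbour within a 5 mm gate.

## Synthetic study generator

The generator reproduces the simulation conditions, and its defaults are
the study conditions:

* **Tumor shape**: random connected aggregation of equal spheres (radius
  5 mm); each new sphere attaches to a random existing one at 1.0–1.8 radii,
  rejecting overlaps closer than one radius.  The PTV is the union dilated
  by 2 mm.
* **Seed positions**: an equal-sphere *partition* of the shape — a randomly
  oriented HCP lattice (pitch 6 mm) is laid over the shape, the inside
  sites nearest the centroid are kept (exactly `n_seeds` of them), giving
  the row-structured, near-regular dwell layouts that make multi-seed
  trajectories detectable.  Planned positions are algorithmic outputs and
  carry no placement noise by default; a jitter parameter exists for
  robustness experiments.
* **Study composition**: the first half of the cases carry 25 seeds, the
  second half 30; per-case sub-seeds derive from the master seed by a
  counter rule, so one integer reproduces the whole study bit-exactly.
* **Scene**: one rib-like chain of four obstacle spheres (radius 5–7 mm)
  between the target and the entry side at a random lateral offset, an
  organ-at-risk sphere cluster beside the PTV, a spherical body surface
  (radius ≥ 80 mm) for entry-depth evaluation, and a generous admissible
  hub box; the entry hint is +z.
* **Coplanar baseline**: a template of parallel surface-normal needles on a
  5 mm pitch; the case's seed count is allotted to template chords through
  the tumor proportionally to chord length and spread uniformly along each
  chord.  This parametric construction stands in for manual clinician
  planning in the comparison study.
* **CT-like volumes** for localization tests: Gaussian blobs (σ = 1 mm) at
  seed positions plus white noise.

What the generator does *not* emulate: patient-derived anatomy, tissue
heterogeneity and deformation, respiratory motion, and the irregular
partial-row layouts a clinical TPS may produce.  Passing tests therefore
demonstrate the pipeline's geometric and dosimetric correctness under
controlled conditions, not clinical performance.

## Known behaviour under the default conditions

Two study statistics are structurally sensitive to the interplay of the
constraint defaults and the generator:

* With `C_l = 200 mm` and `d_g = 20 mm`, separating the hubs of two
  parallel needles whose lattice rows are ~5–6 mm apart forces axis tilts
  of several hundredths of a radian around the fixed tips; seeds 15–30 mm
  up-axis from the tip are then displaced by 1–2 mm.  The per-case maximum
  seed adjustment is dominated by this mechanism, not by detection error.
* The number of detected needles tracks the row-length distribution of the
  partition lattice inside aggregated shapes (typically 2–4 seeds per row
  at 6 mm pitch inside ~10 cm³ lesions).

Both quantities are reported exactly as measured; neither the generator
nor the constraint defaults are adjusted per case.

## Numerical choices

Determinism everywhere: peak ties break to the lowest direction index then
lowest bin; singleton directions to the lowest index; SLSQP is
deterministic; study sub-seeds are counter-derived.  The objective's cross
product norm is smoothed with a 1e-18 additive epsilon inside the square
root to keep finite-difference gradients defined at exact collinearity.
Degenerate inputs fail loudly: zero-length needle axes, empty seed lists,
empty masks, constant localization volumes, inconsistent depth bounds.
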
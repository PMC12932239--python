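"""Synthetic study-case generation.

Tumor shapes are built by multi-sphere aggregation: equal-radius shape
spheres are attached one at a time to the growing union (each new center
lies between 1.0 and 1.8 radii from its parent, so consecutive spheres
overlap and the union stays connected), producing an irregular connected
lesion whose dilated union is the PTV.  The planned seed dwell positions
come from partitioning that shape with equal spheres: a randomly oriented
close-packing (HCP) lattice is laid over the shape, the lattice sites
inside it nearest the centroid are kept, and a small placement jitter is
added.  The partition gives the near-regular, row-structured dwell layouts
that seed implants exhibit, which is what makes multi-seed needle
trajectories detectable at all.

Scenes add bone-like obstacle sphere chains between the target and the
entry side, an adjacent organ-at-risk cluster, a spherical body-surface
model and the robot's admissible hub box.  A parametric coplanar template
baseline (parallel surface-normal needles on a fixed pitch) stands in for
manual clinical planning in the comparison study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .dose import DoseGrid
from .metrics import StructureMask
from .refine import ObstacleSphere

__all__ = [
    "SyntheticCase",
    "generate_tumor",
    "generate_scene",
    "generate_study",
    "coplanar_baseline",
    "synth_ct_volume",
]

DEFAULT_SPHERE_RADIUS_MM = 5.0
PTV_SMOOTHING_MARGIN_MM = 2.0
BODY_RADIUS_MM = 80.0
ENTRY_HINT = np.array([0.0, 0.0, 1.0])  # entry from above (+z)


@dataclass
class SyntheticCase:
    """One synthetic planning case (all coordinates in mm).

    ``centers`` are the shape spheres whose dilated union is the PTV;
    ``seed_positions`` are the planned dwell positions (centers of the
    equal-sphere partition of the shape).
    """

    case_id: str
    rng_seed: int
    sphere_radius: float
    centers: np.ndarray                     # (m, 3) tumor shape-sphere centers
    seed_positions: np.ndarray | None = None  # (n, 3) planned dwell positions
    seed_ids: list = field(default_factory=list)
    ptv_margin: float = PTV_SMOOTHING_MARGIN_MM
    obstacles: list = field(default_factory=list)     # ObstacleSphere list
    oar_spheres: list = field(default_factory=list)   # (center, radius) tuples
    workspace_box: np.ndarray | None = None
    body_surface: dict | None = None
    entry_hint: np.ndarray = field(default_factory=lambda: ENTRY_HINT.copy())

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.seed_positions is None:
            self.seed_positions = self.centers
        self.seed_positions = np.atleast_2d(np.asarray(self.seed_positions, dtype=float))
        if not self.seed_ids:
            self.seed_ids = list(range(len(self.seed_positions)))

    @property
    def seeds(self) -> np.ndarray:
        """Planned seed dwell positions."""
        return self.seed_positions

    @property
    def n_seeds(self) -> int:
        return len(self.seed_positions)

    def ptv_mask(self, grid: DoseGrid) -> StructureMask:
        """Rasterize the dilated union-of-spheres PTV on a grid."""
        return self._spheres_mask(grid, self.centers,
                                  self.sphere_radius + self.ptv_margin, "PTV")

    def oar_mask(self, grid: DoseGrid) -> StructureMask:
        if not self.oar_spheres:
            raise ValueError("case has no OAR spheres")
        centers = np.array([c for c, _ in self.oar_spheres])
        radius = float(self.oar_spheres[0][1])
        return self._spheres_mask(grid, centers, radius, "OAR")

    @staticmethod
    def _spheres_mask(grid: DoseGrid, centers, radius, label) -> StructureMask:
        xs, ys, zs = grid.axes()
        pts = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1).reshape(-1, 3)
        d, _ = cKDTree(np.atleast_2d(centers)).query(pts)
        return StructureMask(values=(d <= radius).reshape(grid.dims), label=label)

    def default_grid_spec(self, spacing=(3.5, 3.5, 1.5), dims=(60, 60, 80)) -> dict:
        """Dose grid centred on the tumor centroid."""
        spacing = np.asarray(spacing, float)
        dims = np.asarray(dims, int)
        c = self.centers.mean(axis=0)
        origin = c - spacing * (dims - 1) / 2.0
        return {"origin": origin, "spacing": spacing, "dims": tuple(int(d) for d in dims)}


PACKING_PITCH_MM = 6.0
SEED_JITTER_SD_MM = 0.0


def _aggregate_shape(n_spheres: int, sphere_radius: float, rng) -> np.ndarray:
    """Random connected aggregation of equal shape spheres.

    Each new sphere attaches to a random existing one at a center distance
    uniform in [1.0, 1.8] radii, rejecting placements closer than 1.0 radius
    to any existing center; the result is recentred on its centroid.
    """
    centers = [np.zeros(3)]
    while len(centers) < n_spheres:
        for _ in range(200):  # rejection sampling; dense configurations need retries
            parent = centers[rng.integers(len(centers))]
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            dist = rng.uniform(1.0, 1.8) * sphere_radius
            cand = parent + dist * u
            if all(np.linalg.norm(cand - c) >= 1.0 * sphere_radius for c in centers):
                centers.append(cand)
                break
        else:
            raise RuntimeError("sphere aggregation failed to place a sphere")
    centers = np.array(centers)
    return centers - centers.mean(axis=0)


def _random_rotation(rng) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _partition_sites(shape_centers: np.ndarray, sphere_radius: float,
                     n_seeds: int, pitch: float, rng) -> np.ndarray | None:
    """Centers of the equal-sphere partition of the shape: the ``n_seeds``
    sites of a randomly oriented HCP lattice inside the shape that lie
    nearest its centroid; None when the shape holds fewer sites."""
    a1 = np.array([pitch, 0.0, 0.0])
    a2 = np.array([pitch / 2.0, pitch * np.sqrt(3.0) / 2.0, 0.0])
    a3 = np.array([pitch / 2.0, pitch * np.sqrt(3.0) / 6.0, pitch * np.sqrt(2.0 / 3.0)])
    rot = _random_rotation(rng)
    offset = rng.uniform(0.0, 1.0, size=3)
    extent = float(np.max(np.linalg.norm(shape_centers, axis=1))) + sphere_radius
    m = int(np.ceil(extent / pitch)) + 2
    ii, jj, kk = np.meshgrid(*([np.arange(-m, m + 1)] * 3), indexing="ij")
    coeff = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) + offset
    sites = coeff @ np.stack([a1, a2, a3]) @ rot.T
    d, _ = cKDTree(shape_centers).query(sites)
    inside = sites[d <= sphere_radius]
    if len(inside) < n_seeds:
        return None
    centroid = shape_centers.mean(axis=0)
    order = np.argsort(np.linalg.norm(inside - centroid, axis=1), kind="stable")
    return inside[order[:n_seeds]]


def generate_tumor(n_seeds: int, sphere_radius: float = DEFAULT_SPHERE_RADIUS_MM,
                   rng_seed: int = 0, case_id: str = "case",
                   packing_pitch: float = PACKING_PITCH_MM,
                   jitter_sd: float = SEED_JITTER_SD_MM) -> SyntheticCase:
    """Generate one tumor: aggregated multi-sphere shape, partition-derived
    seed positions.

    The shape is a random connected aggregation of ``n_seeds`` equal
    spheres; the planned dwell positions are the centers of an equal-sphere
    partition of that shape (jittered close-packing lattice sites), giving
    exactly ``n_seeds`` seeds inside the shape.  Deterministic per
    ``rng_seed``.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    if sphere_radius <= 0:
        raise ValueError("sphere_radius must be positive")
    rng = np.random.default_rng(rng_seed)
    if n_seeds == 1:
        c = np.zeros((1, 3))
        return SyntheticCase(case_id=case_id, rng_seed=int(rng_seed),
                             sphere_radius=float(sphere_radius), centers=c,
                             seed_positions=c.copy())
    for _ in range(50):
        centers = _aggregate_shape(n_seeds, sphere_radius, rng)
        sites = _partition_sites(centers, sphere_radius, n_seeds, packing_pitch, rng)
        if sites is not None:
            break
    else:
        raise RuntimeError("could not partition the tumor shape into enough sites")
    seeds = sites
    if jitter_sd > 0:
        seeds = sites + rng.normal(0.0, jitter_sd, size=sites.shape)
    return SyntheticCase(case_id=case_id, rng_seed=int(rng_seed),
                         sphere_radius=float(sphere_radius), centers=centers,
                         seed_positions=seeds)


def generate_scene(core: SyntheticCase, n_obstacles: int = 1,
                   rng_seed: int | None = None) -> SyntheticCase:
    """Attach anatomy and robot context to a tumor core.

    Adds ``n_obstacles`` bone-like chains of spheres in the corridor between
    the PTV and the entry side, an organ-at-risk cluster beside the PTV, a
    spherical body-surface model and the admissible hub workspace box.
    """
    rng = np.random.default_rng(core.rng_seed + 7919 if rng_seed is None else rng_seed)
    extent = float(np.max(np.linalg.norm(core.centers, axis=1))) + core.sphere_radius
    obstacles = []
    for _ in range(n_obstacles):
        # rib-like chain above the tumor, laterally offset so only some
        # entry trajectories clash with it
        az = rng.uniform(0, 2 * np.pi)
        lat = rng.uniform(8.0, 22.0)
        z0 = extent + rng.uniform(12.0, 22.0)
        along = np.array([-np.sin(az), np.cos(az), 0.0])
        base = np.array([lat * np.cos(az), lat * np.sin(az), z0])
        r_obs = rng.uniform(5.0, 7.0)
        for k in range(4):
            c = base + (k - 1.5) * 1.6 * r_obs * along
            obstacles.append(ObstacleSphere(center=c, radius=float(r_obs)))
    oar = []
    az = rng.uniform(0, 2 * np.pi)
    oar_c = np.array([np.cos(az), np.sin(az), 0.0]) * (extent + 18.0)
    for k in range(3):
        oar.append((oar_c + np.array([0.0, 0.0, (k - 1) * 9.0]), 8.0))
    body_r = max(BODY_RADIUS_MM, extent + 40.0)
    box = np.array([[-300.0, -300.0, -30.0], [300.0, 300.0, 350.0]])
    return SyntheticCase(
        case_id=core.case_id, rng_seed=core.rng_seed,
        sphere_radius=core.sphere_radius, centers=core.centers,
        seed_positions=core.seed_positions,
        seed_ids=list(core.seed_ids), ptv_margin=core.ptv_margin,
        obstacles=obstacles, oar_spheres=oar, workspace_box=box,
        body_surface={"type": "sphere", "center": [0.0, 0.0, 0.0], "radius": body_r},
    )


def _case_sub_seed(master_seed: int, index: int) -> int:
    # counter-based split keeping derived seeds below 2**31
    return int((master_seed * 100003 + 7919 * index + 1) % (2**31 - 1))


def generate_study(n_cases: int, rng_seed: int = 0, n_obstacles: int = 1,
                   sphere_radius: float = DEFAULT_SPHERE_RADIUS_MM) -> list[SyntheticCase]:
    """Generate the simulation study: the first half of the cases carry 25
    seeds, the second half 30, with independent per-case sub-seeds derived
    from the master seed."""
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    cases = []
    for i in range(n_cases):
        n_seeds = 25 if i < (n_cases + 1) // 2 else 30
        sub = _case_sub_seed(rng_seed, i)
        core = generate_tumor(n_seeds, sphere_radius, rng_seed=sub,
                              case_id=f"C{i + 1}")
        cases.append(generate_scene(core, n_obstacles=n_obstacles))
    return cases


def coplanar_baseline(case: SyntheticCase, grid_pitch: float = 5.0) -> np.ndarray:
    """Coplanar template plan: the same number of seeds placed on parallel
    surface-normal (vertical) needles at template pitch.

    Template positions form a square lattice in the entry plane; seeds are
    allotted to template chords through the tumor proportionally to chord
    length and spread uniformly along each chord, so every baseline seed
    lies inside the PTV.
    """
    if grid_pitch <= 0:
        raise ValueError("grid_pitch must be positive")
    n = case.n_seeds
    r = case.sphere_radius
    lo = case.centers.min(axis=0) - r
    hi = case.centers.max(axis=0) + r
    xs = np.arange(lo[0], hi[0] + grid_pitch, grid_pitch)
    ys = np.arange(lo[1], hi[1] + grid_pitch, grid_pitch)
    xs += (lo[0] + hi[0]) / 2.0 - (xs[0] + xs[-1]) / 2.0
    ys += (lo[1] + hi[1]) / 2.0 - (ys[0] + ys[-1]) / 2.0
    chords = []
    for x in xs:
        for y in ys:
            d_h = np.hypot(case.centers[:, 0] - x, case.centers[:, 1] - y)
            inside = d_h < r
            if not inside.any():
                continue
            half = np.sqrt(r**2 - d_h[inside] ** 2)
            z_lo = case.centers[inside, 2] - half
            z_hi = case.centers[inside, 2] + half
            # merge overlapping z-intervals; keep the longest run
            order = np.argsort(z_lo)
            best = (0.0, 0.0, 0.0)
            cur_lo, cur_hi = z_lo[order[0]], z_hi[order[0]]
            for k in order[1:]:
                if z_lo[k] <= cur_hi:
                    cur_hi = max(cur_hi, z_hi[k])
                else:
                    if cur_hi - cur_lo > best[0]:
                        best = (cur_hi - cur_lo, cur_lo, cur_hi)
                    cur_lo, cur_hi = z_lo[k], z_hi[k]
            if cur_hi - cur_lo > best[0]:
                best = (cur_hi - cur_lo, cur_lo, cur_hi)
            chords.append((x, y, best[1], best[2]))
    if not chords:
        raise ValueError("PTV too small for the template pitch")
    lengths = np.array([c[3] - c[2] for c in chords])
    # largest-remainder allotment of n seeds proportional to chord length
    quota = n * lengths / lengths.sum()
    alloc = np.floor(quota).astype(int)
    rem = n - alloc.sum()
    for k in np.argsort(-(quota - alloc))[:rem]:
        alloc[k] += 1
    seeds = []
    for (x, y, z0, z1), k in zip(chords, alloc):
        for j in range(k):
            seeds.append([x, y, z0 + (j + 0.5) * (z1 - z0) / k])
    return np.asarray(seeds, dtype=float)


def synth_ct_volume(seeds, spacing=(0.6, 0.6, 0.6), psf_sigma: float = 1.0,
                    noise_sd: float = 0.0, rng_seed: int = 0,
                    margin: float = 10.0, amplitude: float = 1000.0) -> DoseGrid:
    """CT-like intensity volume: Gaussian blobs at seed positions on a dark
    background plus white noise (fixture for seed localization)."""
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    spacing = np.asarray(spacing, dtype=float)
    if np.any(spacing <= 0) or psf_sigma <= 0:
        raise ValueError("spacing and psf_sigma must be positive")
    lo = seeds.min(axis=0) - margin
    hi = seeds.max(axis=0) + margin
    dims = np.ceil((hi - lo) / spacing).astype(int) + 1
    xs = lo[0] + spacing[0] * np.arange(dims[0])
    ys = lo[1] + spacing[1] * np.arange(dims[1])
    zs = lo[2] + spacing[2] * np.arange(dims[2])
    vol = np.zeros(tuple(dims))
    for s in seeds:
        gx = np.exp(-0.5 * ((xs - s[0]) / psf_sigma) ** 2)
        gy = np.exp(-0.5 * ((ys - s[1]) / psf_sigma) ** 2)
        gz = np.exp(-0.5 * ((zs - s[2]) / psf_sigma) ** 2)
        vol += amplitude * gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        vol += rng.normal(0.0, noise_sd, size=vol.shape)
    return DoseGrid(origin=lo, spacing=spacing, values=vol)
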
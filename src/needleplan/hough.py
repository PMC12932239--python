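"""3D Hough transform line detection for clustered seed dwell positions.

A line in 3D is parameterized by a unit direction ``b`` and an anchor point
``A`` lying in the plane through the origin orthogonal to ``b``.  The anchor
plane carries an orthonormal basis ``(e1, e2)`` derived from ``b`` (Roberts'
optimal line representation, after Dalitz et al.), giving planar coordinates
``(x', y')`` for the anchor.  Directions are discretized by subdividing an
icosahedron and projecting to the unit sphere; antipodal vertices are
identified because lines are undirected.  Every seed votes, for every
discretized direction, for the anchor-plane cell containing its projection;
cells with many votes correspond to lines supported by many nearly-collinear
seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import Line3, NeedleTrajectory, as_point, normalize, points_line_distance

__all__ = [
    "DirectionSet",
    "HoughAccumulator",
    "LineCandidate",
    "build_direction_set",
    "plane_basis",
    "forward_transform",
    "anchor_from_params",
    "vote",
    "extract_lines",
    "line_to_needle",
]

_EQUATOR_TOL = 1e-12


def _canonical_direction(v: np.ndarray) -> np.ndarray:
    """Pick one representative of the antipodal pair {v, -v}.

    Keeps the non-negative-z representative; on the equator (z == 0) the
    lexicographically larger of the two is kept.
    """
    if v[2] < -_EQUATOR_TOL:
        return -v
    if abs(v[2]) <= _EQUATOR_TOL:
        if tuple(v) < tuple(-v):
            return -v
    return v


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=int,
    )
    return verts, faces


@dataclass(frozen=True)
class DirectionSet:
    """Hemisphere-restricted direction discretization from icosahedral subdivision."""

    level: int
    directions: np.ndarray  # (m, 3) unit vectors, z >= 0
    mean_neighbour_deg: float
    max_neighbour_deg: float

    def __len__(self) -> int:
        return len(self.directions)


def build_direction_set(level: int) -> DirectionSet:
    """Subdivide the icosahedron ``level`` times and return one direction per
    antipodal vertex pair.

    Each subdivision splits every triangle into four via sphere-projected edge
    midpoints, so the vertex count is ``10 * 4**level + 2`` before antipodal
    halving.  Six levels give an angular resolution of about 1.3 degrees.
    """
    if not (0 <= int(level) <= 8):
        raise ValueError(f"subdivision level must be in [0, 8], got {level}")
    level = int(level)
    verts, faces = _icosahedron()
    verts = list(map(np.asarray, verts))
    for _ in range(level):
        midpoint: dict[tuple[int, int], int] = {}
        new_faces = []

        def mid(i: int, j: int) -> int:
            key = (i, j) if i < j else (j, i)
            idx = midpoint.get(key)
            if idx is None:
                m = verts[i] + verts[j]
                m /= np.linalg.norm(m)
                verts.append(m)
                idx = len(verts) - 1
                midpoint[key] = idx
            return idx

        for a, b, c in faces:
            ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        faces = np.asarray(new_faces, dtype=int)

    v = np.asarray(verts)
    assert len(v) == 10 * 4**level + 2
    # antipodal identification: keep the canonical representative of each pair
    canon = np.array([_canonical_direction(x) for x in v])
    # deduplicate (each pair appears twice)
    keys = np.round(canon / 1e-9).astype(np.int64)
    _, keep = np.unique(keys, axis=0, return_index=True)
    dirs = canon[np.sort(keep)]

    # nearest-neighbour angular spacing under the antipodal (axial) metric
    both = np.vstack([dirs, -dirs])
    tree = cKDTree(both)
    dist, _ = tree.query(dirs, k=2)
    chord = dist[:, 1]
    ang = np.degrees(2.0 * np.arcsin(np.clip(chord / 2.0, 0.0, 1.0)))
    return DirectionSet(
        level=level,
        directions=dirs,
        mean_neighbour_deg=float(np.mean(ang)),
        max_neighbour_deg=float(np.max(ang)),
    )


def plane_basis(b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal basis (e1, e2) of the anchor plane orthogonal to ``b``.

    Singular only at b = -z_hat, which the hemisphere-restricted direction
    set excludes.
    """
    bx, by, bz = b
    if bz <= -1.0 + 1e-9:
        raise ValueError("direction b = -z is singular for the anchor-plane basis")
    e1 = np.array([1.0 - bx * bx / (1.0 + bz), -bx * by / (1.0 + bz), -bx])
    e2 = np.array([-bx * by / (1.0 + bz), 1.0 - by * by / (1.0 + bz), -by])
    return e1, e2


def forward_transform(p, b) -> tuple[float, float]:
    """Anchor-plane coordinates (x', y') of the line through ``p`` with
    direction ``b``: the projection of ``p`` onto the plane orthogonal to
    ``b`` through the origin, expressed in the (e1, e2) basis."""
    p = as_point(p)
    b = normalize(b)
    e1, e2 = plane_basis(b)
    return float(np.dot(p, e1)), float(np.dot(p, e2))


def anchor_from_params(x_p: float, y_p: float, b) -> np.ndarray:
    """Cartesian anchor point A = x'*e1 + y'*e2 (closest line point to origin)."""
    b = normalize(b)
    e1, e2 = plane_basis(b)
    return x_p * e1 + y_p * e2


def _all_plane_bases(dirs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    bx, by, bz = dirs[:, 0], dirs[:, 1], dirs[:, 2]
    w = 1.0 / (1.0 + bz)
    e1 = np.stack([1.0 - bx * bx * w, -bx * by * w, -bx], axis=1)
    e2 = np.stack([-bx * by * w, 1.0 - by * by * w, -by], axis=1)
    return e1, e2


@dataclass
class HoughAccumulator:
    """Sparse vote accumulator over (direction, x'-bin, y'-bin) cells.

    Cells are keyed ``dir_idx * n_bins**2 + ix * n_bins + iy`` and stored as
    (key, count) pairs; counts are identical to a dense 3D array but only
    occupied cells are materialized.  Bin index = floor((v - range_min)/step).
    """

    direction_set: DirectionSet
    spatial_step: float
    range_min: float
    n_bins: int
    keys: np.ndarray = field(repr=False)
    counts: np.ndarray = field(repr=False)
    n_seeds: int = 0

    @property
    def total_votes(self) -> int:
        return int(self.counts.sum())

    def peak(self) -> tuple[int, int, int, int]:
        """Global-maximum cell as (dir_idx, ix, iy, votes).

        Ties break to the lowest direction index, then lowest (x', y') bin
        index — i.e. the smallest key, which np.unique ordering provides.
        """
        i = int(np.argmax(self.counts))  # first (lowest-key) maximum
        key = int(self.keys[i])
        nb2 = self.n_bins * self.n_bins
        d, rem = divmod(key, nb2)
        ix, iy = divmod(rem, self.n_bins)
        return d, ix, iy, int(self.counts[i])

    def cell_line(self, dir_idx: int, ix: int, iy: int) -> Line3:
        """Line represented by a cell, using bin-center anchor coordinates."""
        b = self.direction_set.directions[dir_idx]
        x_p = self.range_min + (ix + 0.5) * self.spatial_step
        y_p = self.range_min + (iy + 0.5) * self.spatial_step
        return Line3(anchor=anchor_from_params(x_p, y_p, b), direction=b)

    def counts_for_direction(self, dir_idx: int) -> np.ndarray:
        """Dense (n_bins, n_bins) vote slice for one direction."""
        nb2 = self.n_bins * self.n_bins
        lo, hi = dir_idx * nb2, (dir_idx + 1) * nb2
        sel = (self.keys >= lo) & (self.keys < hi)
        out = np.zeros((self.n_bins, self.n_bins), dtype=np.int64)
        rem = self.keys[sel] - lo
        out[rem // self.n_bins, rem % self.n_bins] = self.counts[sel]
        return out


def vote(seeds: np.ndarray, direction_set: DirectionSet, spatial_step: float = 0.2,
         range_radius: float | None = None) -> HoughAccumulator:
    """Vote every seed into every direction's anchor-plane histogram.

    ``range_radius`` fixes the (x', y') range half-width; by default it is
    the radius of the seed cloud's origin-centred bounding sphere (anchor
    coordinates cannot exceed the seed's distance from the origin).
    """
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    if seeds.size == 0:
        raise ValueError("empty seed list")
    if spatial_step <= 0:
        raise ValueError("spatial_step must be positive")
    dirs = direction_set.directions
    e1, e2 = _all_plane_bases(dirs)
    xp = seeds @ e1.T  # (n_seeds, n_dirs)
    yp = seeds @ e2.T
    if range_radius is None:
        range_radius = float(np.max(np.linalg.norm(seeds, axis=1)))
    range_min = -range_radius - spatial_step
    n_bins = int(np.ceil(2.0 * (range_radius + spatial_step) / spatial_step)) + 1
    ix = np.floor((xp - range_min) / spatial_step).astype(np.int64)
    iy = np.floor((yp - range_min) / spatial_step).astype(np.int64)
    dir_idx = np.broadcast_to(np.arange(len(dirs), dtype=np.int64), xp.shape)
    key = (dir_idx * n_bins + ix) * n_bins + iy
    keys, counts = np.unique(key.ravel(), return_counts=True)
    return HoughAccumulator(
        direction_set=direction_set,
        spatial_step=float(spatial_step),
        range_min=float(range_min),
        n_bins=n_bins,
        keys=keys,
        counts=counts,
        n_seeds=len(seeds),
    )


@dataclass
class LineCandidate:
    """One detected line with its supporting seeds."""

    line: Line3
    votes: int
    assigned_seed_ids: list
    rms_residual: float


def _orthogonal_fit(points: np.ndarray, fallback_dir: np.ndarray) -> Line3:
    """Total-least-squares line through >= 2 points (principal direction
    through the centroid); a single point keeps the fallback direction."""
    if len(points) == 1:
        return Line3(anchor=points[0], direction=fallback_dir)
    c = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - c, full_matrices=False)
    d = _canonical_direction(vt[0])
    return Line3(anchor=c, direction=d)


def _windowed_peak(pts: np.ndarray, direction_set: DirectionSet,
                   spatial_step: float, window_bins: int, range_min: float):
    """Best accumulator cell under box-window vote smoothing.

    For every remaining seed's cell in every direction slice, count the
    votes within ``window_bins`` (Chebyshev) of that cell and return the
    maximizer as (seed_index, dir_index, windowed_count).  Ties break to the
    lowest direction index, then the lowest (x', y') bin.  Smoothing makes
    the peak reflect the number of *approximately* collinear seeds even when
    residual scatter spreads their votes over several fine bins.
    """
    dirs = direction_set.directions
    e1, e2 = _all_plane_bases(dirs)
    xp = pts @ e1.T  # (n, m)
    yp = pts @ e2.T
    ix = np.floor((xp - range_min) / spatial_step).astype(np.int64)
    iy = np.floor((yp - range_min) / spatial_step).astype(np.int64)
    near = (
        (np.abs(ix[:, None, :] - ix[None, :, :]) <= window_bins)
        & (np.abs(iy[:, None, :] - iy[None, :, :]) <= window_bins)
    )
    counts = near.sum(axis=1)  # (n, m) windowed votes at each seed's cell
    order = np.lexsort((iy.ravel(), ix.ravel(),
                        np.broadcast_to(np.arange(counts.shape[1]), counts.shape).ravel(),
                        -counts.ravel()))
    m = counts.shape[1]
    peaks = []
    for flat in order[:32]:  # top peaks in deterministic tie-broken order
        s, d = divmod(int(flat), m)
        peaks.append((s, d, int(counts[s, d]), (float(xp[s, d]), float(yp[s, d]))))
    return peaks


def extract_lines(seeds: np.ndarray, direction_set: DirectionSet,
                  spatial_step: float = 0.2, capture_radius: float = 1.5,
                  min_votes: int = 2,
                  seed_ids: list | None = None) -> list[LineCandidate]:
    """Iterative peak extraction.

    Repeatedly (i) vote the remaining seeds, (ii) locate the best cell of
    the window-smoothed accumulator (window half-width = capture radius),
    (iii) capture remaining seeds within the capture radius of that cell's
    line, (iv) refit the line to the captured seeds by orthogonal least
    squares, (v) re-capture around the refit line, (vi) remove the captured
    seeds; stop when the best windowed count falls below ``min_votes``.
    Leftover seeds become singleton candidates along their locally
    best-voted direction.  Every seed ends up in exactly one candidate.
    """
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    if capture_radius <= 0:
        raise ValueError("capture_radius must be positive")
    if min_votes < 2:
        raise ValueError("min_votes must be >= 2")
    if seed_ids is None:
        seed_ids = list(range(len(seeds)))
    seed_ids = list(seed_ids)
    range_radius = float(np.max(np.linalg.norm(seeds, axis=1)))
    range_min = -range_radius - spatial_step
    window_bins = max(1, int(np.ceil(capture_radius / spatial_step)))

    def _capture_refit(pool, cell):
        """Capture within the radius of the cell line, refit by orthogonal
        least squares, re-capture around the refit; keep the larger set."""
        dist = points_line_distance(seeds[pool], cell.point_at(0.0), cell.point_at(1.0))
        captured = pool[dist <= capture_radius]
        if len(captured) == 0:
            return captured, cell
        fit = _orthogonal_fit(seeds[captured], cell.direction)
        dist2 = points_line_distance(seeds[pool], fit.point_at(0.0), fit.point_at(1.0))
        captured2 = pool[dist2 <= capture_radius]
        if len(captured2) >= len(captured):
            captured = captured2
            fit = _orthogonal_fit(seeds[captured], cell.direction)
        return captured, _orthogonal_fit(seeds[captured], fit.direction)

    remaining = np.arange(len(seeds))
    candidates: list[LineCandidate] = []
    while len(remaining) >= 1:
        peaks = _windowed_peak(
            seeds[remaining], direction_set, spatial_step, window_bins, range_min)
        if peaks[0][2] < min_votes:
            break
        best = None
        for _, d_idx, votes, (x_p, y_p) in peaks:
            if votes < min_votes:
                break
            b = direction_set.directions[d_idx]
            cell = Line3(anchor=anchor_from_params(x_p, y_p, b), direction=b)
            captured, fit = _capture_refit(remaining, cell)
            if best is None or len(captured) > len(best[0]):
                best = (captured, fit)
        captured, fit = best
        if len(captured) == 0:
            break
        res = points_line_distance(seeds[captured], fit.point_at(0.0), fit.point_at(1.0))
        candidates.append(
            LineCandidate(
                line=fit,
                votes=len(captured),
                assigned_seed_ids=[seed_ids[i] for i in captured],
                rms_residual=float(np.sqrt(np.mean(res**2))),
            )
        )
        remaining = np.setdiff1d(remaining, captured)

    if len(remaining) > 0:
        # singleton candidates along each leftover seed's best-voted direction
        dirs = direction_set.directions
        e1, e2 = _all_plane_bases(dirs)
        ix_all = np.floor((seeds[remaining] @ e1.T - range_min) / spatial_step).astype(np.int64)
        iy_all = np.floor((seeds[remaining] @ e2.T - range_min) / spatial_step).astype(np.int64)
        for k, i in enumerate(remaining):
            same = (
                (np.abs(ix_all - ix_all[k]) <= window_bins)
                & (np.abs(iy_all - iy_all[k]) <= window_bins)
            ).sum(axis=0)
            best = int(np.argmax(same))  # ties -> lowest direction index
            line = Line3(anchor=seeds[i], direction=dirs[best])
            candidates.append(
                LineCandidate(line=line, votes=1,
                              assigned_seed_ids=[seed_ids[i]], rms_residual=0.0)
            )
    return _consolidate(candidates, seeds, seed_ids)


def _consolidate(candidates: list[LineCandidate], seeds: np.ndarray,
                 seed_ids: list, iterations: int = 3) -> list[LineCandidate]:
    """Nearest-axis reassignment + refit (k-lines iterations).

    Greedy extraction can leave a seed on the line that captured it first
    even when another detected line passes closer; since the planning
    objective is the summed seed-to-axis deviation, each seed is moved to
    its nearest candidate line and the lines are refit until stable.  Empty
    candidates are dropped; assignment stays a partition of the seeds.
    """
    id_of = {s: k for k, s in enumerate(seed_ids)}
    for _ in range(iterations):
        dists = np.stack([
            points_line_distance(seeds, c.line.point_at(0.0), c.line.point_at(1.0))
            for c in candidates
        ])  # (n_candidates, n_seeds)
        nearest = np.argmin(dists, axis=0)
        groups = [[] for _ in candidates]
        for k, s in enumerate(seed_ids):
            groups[nearest[k]].append(s)
        changed = False
        new_candidates = []
        for c, grp in zip(candidates, groups):
            if not grp:
                changed = True
                continue
            if sorted(grp) != sorted(c.assigned_seed_ids):
                changed = True
            pts = seeds[[id_of[s] for s in grp]]
            fit = _orthogonal_fit(pts, c.line.direction)
            res = points_line_distance(pts, fit.point_at(0.0), fit.point_at(1.0))
            new_candidates.append(
                LineCandidate(line=fit, votes=len(grp), assigned_seed_ids=grp,
                              rms_residual=float(np.sqrt(np.mean(res**2))))
            )
        candidates = new_candidates
        if not changed:
            break
    return candidates


def line_to_needle(candidate: LineCandidate, seeds: np.ndarray, seed_ids: list,
                   needle_length: float, entry_direction_hint) -> NeedleTrajectory:
    """Convert a detected line into a hub/tip needle of fixed physical length.

    The insertion direction is the candidate direction signed so the hub lies
    on the entry side (``entry_direction_hint`` points from the target toward
    the entry side).  The tip is placed at the distal-most assigned seed's
    axial position; the hub sits ``needle_length`` behind the tip.
    """
    if needle_length <= 0:
        raise ValueError("needle_length must be positive")
    if not candidate.assigned_seed_ids:
        raise ValueError("candidate has no assigned seeds")
    hint = as_point(entry_direction_hint)
    b = candidate.line.direction
    # insertion direction points away from the entry side
    ins = -b if np.dot(b, hint) > 0 else b
    idx = [list(seed_ids).index(s) for s in candidate.assigned_seed_ids]
    pts = np.atleast_2d(np.asarray(seeds, dtype=float))[idx]
    t_ax = (pts - candidate.line.anchor) @ ins
    t = float(np.max(t_ax))  # distal-most seed along the insertion direction
    p_t = candidate.line.anchor + t * ins
    p_s = p_t - needle_length * ins
    if t - float(np.min(t_ax)) > needle_length:
        raise ValueError("needle shorter than the assigned seeds' axial extent")
    return NeedleTrajectory(
        p_s=p_s, p_t=p_t, length=float(needle_length),
        assigned_seed_ids=list(candidate.assigned_seed_ids),
    )
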
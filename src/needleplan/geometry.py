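"""Shared geometric primitives for needle-placement planning.

Conventions: right-handed world frame, millimetres throughout.  Points and
directions are ``numpy`` arrays of shape ``(3,)``; direction vectors are
unit-norm.  Lines are undirected and stored in anchor/direction form, where
the anchor is the point of the line closest to the origin (it lies in the
plane through the origin orthogonal to the direction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Line3",
    "NeedleTrajectory",
    "as_point",
    "normalize",
    "point_line_distance",
    "project_point_to_line",
]

_DEGENERATE_TOL = 1e-9


def as_point(p) -> np.ndarray:
    """Coerce to a float (3,) array, validating shape and finiteness."""
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite coordinate")
    return a


def normalize(v) -> np.ndarray:
    v = as_point(v)
    n = np.linalg.norm(v)
    if n < _DEGENERATE_TOL:
        raise ValueError("cannot normalize a (near-)zero vector")
    return v / n


@dataclass(frozen=True)
class Line3:
    """Undirected 3D line in anchor/direction form.

    ``anchor`` is the closest point of the line to the origin, so
    ``anchor . direction == 0``; ``direction`` is unit-norm.
    """

    anchor: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "anchor", as_point(self.anchor))
        d = normalize(self.direction)
        # re-anchor so the stored anchor is the closest point to the origin
        a = self.anchor - np.dot(self.anchor, d) * d
        object.__setattr__(self, "anchor", a)
        object.__setattr__(self, "direction", d)

    def point_at(self, t: float) -> np.ndarray:
        return self.anchor + t * self.direction

    @classmethod
    def through_points(cls, p: np.ndarray, q: np.ndarray) -> "Line3":
        p, q = as_point(p), as_point(q)
        return cls(anchor=p, direction=normalize(q - p))


@dataclass
class NeedleTrajectory:
    """Straight rigid needle: hub (shaft) point ``p_s``, tip point ``p_t``.

    The insertion direction runs from hub to tip; ``length`` is the fixed
    physical needle length, so ``‖p_s − p_t‖ == length`` for refined needles.
    """

    p_s: np.ndarray
    p_t: np.ndarray
    length: float
    assigned_seed_ids: list = field(default_factory=list)
    feasible: bool = True
    modified: bool = False

    def __post_init__(self):
        self.p_s = as_point(self.p_s)
        self.p_t = as_point(self.p_t)

    @property
    def direction(self) -> np.ndarray:
        """Unit insertion direction (hub → tip)."""
        return normalize(self.p_t - self.p_s)

    @property
    def axis(self) -> Line3:
        return Line3.through_points(self.p_s, self.p_t)

    def to_dict(self) -> dict:
        return {
            "p_s": self.p_s.tolist(),
            "p_t": self.p_t.tolist(),
            "length": float(self.length),
            "assigned_seed_ids": list(self.assigned_seed_ids),
            "feasible": bool(self.feasible),
            "modified": bool(self.modified),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NeedleTrajectory":
        return cls(
            p_s=np.asarray(d["p_s"], dtype=float),
            p_t=np.asarray(d["p_t"], dtype=float),
            length=float(d["length"]),
            assigned_seed_ids=list(d.get("assigned_seed_ids", [])),
            feasible=bool(d.get("feasible", True)),
            modified=bool(d.get("modified", False)),
        )


def point_line_distance(p, p_s, p_t) -> float:
    """Perpendicular distance of point ``p`` from the infinite line through
    ``p_s`` and ``p_t`` (the needle axis), in mm.

    Computed as ``‖(p − p_s) × (p − p_t)‖ / ‖p_s − p_t‖``.
    """
    p, p_s, p_t = as_point(p), as_point(p_s), as_point(p_t)
    axis = p_t - p_s
    denom = np.linalg.norm(axis)
    if denom < _DEGENERATE_TOL:
        raise ValueError("degenerate needle: hub and tip coincide")
    return float(np.linalg.norm(np.cross(p - p_s, p - p_t)) / denom)


def points_line_distance(points: np.ndarray, p_s, p_t) -> np.ndarray:
    """Vectorized ``point_line_distance`` for an (n, 3) point array."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    p_s, p_t = as_point(p_s), as_point(p_t)
    axis = p_t - p_s
    denom = np.linalg.norm(axis)
    if denom < _DEGENERATE_TOL:
        raise ValueError("degenerate needle: hub and tip coincide")
    cr = np.cross(pts - p_s, pts - p_t)
    return np.linalg.norm(cr, axis=1) / denom


def project_point_to_line(p, line: Line3) -> np.ndarray:
    """Orthogonal projection of ``p`` onto ``line`` (the closest line point)."""
    p = as_point(p)
    t = np.dot(p - line.anchor, line.direction)
    return line.point_at(t)
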
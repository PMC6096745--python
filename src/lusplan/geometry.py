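"""Core geometric types for vessel-based registration.

All coordinates are millimetres in a right-handed frame; the CT scan frame is
the global frame and every transform maps source (ultrasound / subset)
coordinates into it.  Transforms act on column vectors and are stored as a
rotation matrix plus translation vector; on disk they are serialised as 4x4
row-major homogeneous matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "RigidTransform",
    "PointSet",
    "VascularTree",
    "SurfaceMesh",
    "as_points",
    "rms_tre",
    "nearest_distances",
]

_ORTHO_TOL = 1e-9


def as_points(obj, *, allow_empty: bool = False, name: str = "points") -> np.ndarray:
    """Coerce *obj* to an (N, 3) float64 array of finite coordinates."""
    if isinstance(obj, PointSet):
        obj = obj.points
    pts = np.asarray(obj, dtype=float)
    if pts.ndim == 1 and pts.size == 0:
        pts = pts.reshape(0, 3)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"{name} must have shape (N, 3), got {pts.shape}")
    if pts.shape[0] == 0 and not allow_empty:
        raise ValueError(f"{name} must be non-empty")
    if pts.size and not np.all(np.isfinite(pts)):
        raise ValueError(f"{name} contains non-finite coordinates")
    return pts


@dataclass(frozen=True)
class RigidTransform:
    """An SE(3) element: proper rotation plus translation in mm."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        rot = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        tra = np.asarray(self.translation, dtype=float).reshape(3)
        err = np.abs(rot.T @ rot - np.eye(3)).max()
        if err > 1e-6:
            raise ValueError(f"rotation is not orthonormal (max deviation {err:.3g})")
        if np.linalg.det(rot) < 0:
            raise ValueError("rotation is a reflection (det = -1)")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tra)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    @staticmethod
    def from_matrix(matrix) -> "RigidTransform":
        """Build from a 4x4 (or 3x4) homogeneous matrix."""
        m = np.asarray(matrix, dtype=float)
        return RigidTransform(m[:3, :3], m[:3, 3])

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying *other* first, then self."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def apply(self, points) -> np.ndarray:
        """Apply to an (N, 3) point array; order is preserved."""
        pts = as_points(points)
        return pts @ self.rotation.T + self.translation

    def rotation_angle(self) -> float:
        """Rotation angle in radians (geodesic distance from the identity)."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.arccos(np.clip(c, -1.0, 1.0)))


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Composition: applying the result equals applying ``b`` then ``a``."""
    return a.compose(b)


def apply_transform(t: RigidTransform, points) -> np.ndarray:
    return t.apply(points)


@dataclass
class PointSet:
    """Ordered 3D points (mm) with optional per-point labels."""

    points: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self):
        self.points = as_points(self.points, allow_empty=True)
        if self.labels is not None and len(self.labels) != len(self.points):
            raise ValueError("labels must match points in length")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class VascularTree:
    """A vessel centreline model: branch polylines plus labelled bifurcations.

    ``branches`` are ordered (n_i, 3) polylines in mm; ``bifurcations`` is an
    (M, 3) array of branching points.  The concatenation of all branch points
    is the registration target; ``branch_ids`` tags each concatenated point
    with its branch index.
    """

    branches: list[np.ndarray]
    bifurcations: np.ndarray

    def __post_init__(self):
        self.branches = [as_points(b, name="branch") for b in self.branches]
        for i, b in enumerate(self.branches):
            if len(b) < 2:
                raise ValueError(f"branch {i} has fewer than 2 points")
        self.bifurcations = as_points(
            self.bifurcations, allow_empty=True, name="bifurcations"
        )

    @property
    def points(self) -> np.ndarray:
        """All centreline points concatenated over branches, (N, 3)."""
        return np.concatenate(self.branches, axis=0)

    @property
    def branch_ids(self) -> np.ndarray:
        """Branch index of each concatenated centreline point."""
        return np.concatenate(
            [np.full(len(b), i, dtype=int) for i, b in enumerate(self.branches)]
        )

    @property
    def n_points(self) -> int:
        return sum(len(b) for b in self.branches)

    def spacing(self) -> float:
        """Median distance between consecutive centreline points."""
        gaps = [np.linalg.norm(np.diff(b, axis=0), axis=1) for b in self.branches]
        return float(np.median(np.concatenate(gaps)))

    def transformed(self, t: RigidTransform) -> "VascularTree":
        return VascularTree(
            [t.apply(b) for b in self.branches],
            t.apply(self.bifurcations) if len(self.bifurcations) else self.bifurcations,
        )


@dataclass
class SurfaceMesh:
    """Triangle mesh of the organ surface with a flagged visible vertex subset.

    The visible subset stands for the anterior surface reachable by the probe
    during surgery; it is supplied, never computed.
    """

    vertices: np.ndarray
    faces: np.ndarray
    visible_mask: np.ndarray = field(default=None)

    def __post_init__(self):
        self.vertices = as_points(self.vertices, name="vertices")
        self.faces = np.asarray(self.faces, dtype=int)
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must have shape (F, 3)")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face indices out of range")
        if self.visible_mask is None:
            self.visible_mask = np.ones(len(self.vertices), dtype=bool)
        else:
            self.visible_mask = np.asarray(self.visible_mask, dtype=bool).reshape(-1)
            if len(self.visible_mask) != len(self.vertices):
                raise ValueError("visible_mask must match vertices in length")
        if not self.visible_mask.any():
            raise ValueError("visible_mask selects no vertices")

    @property
    def visible_vertices(self) -> np.ndarray:
        return self.vertices[self.visible_mask]


def farthest_point_indices(points: np.ndarray, k: int, start_index: int = 0) -> np.ndarray:
    """Greedy max-min (farthest-point) subsample of an (N, 3) array.

    Iteratively adds the point farthest from the already-selected set,
    starting from ``start_index``; deterministic.  Returns ``k`` indices.
    """
    pts = as_points(points)
    n = len(pts)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if not 0 <= start_index < n:
        raise ValueError("start_index out of range")
    chosen = np.empty(k, dtype=int)
    chosen[0] = start_index
    dmin = np.linalg.norm(pts - pts[start_index], axis=1)
    for i in range(1, k):
        nxt = int(np.argmax(dmin))
        chosen[i] = nxt
        dmin = np.minimum(dmin, np.linalg.norm(pts - pts[nxt], axis=1))
    return chosen


def rms_tre(original, displaced) -> float:
    """Root-mean-square target registration error between paired point lists.

    Points are paired by index (landmark lists are pre-matched); the result is
    the RMS of the per-pair Euclidean distances in mm.
    """
    a = as_points(original, name="original")
    b = as_points(displaced, name="displaced")
    if a.shape != b.shape:
        raise ValueError(f"point counts differ: {a.shape[0]} vs {b.shape[0]}")
    d2 = np.sum((a - b) ** 2, axis=1)
    return float(np.sqrt(d2.mean()))


def nearest_distances(query, reference) -> np.ndarray:
    """Distance from each query point to its closest reference point.

    Uses a k-d tree; results are identical to exhaustive search.
    """
    q = as_points(query, name="query")
    r = as_points(reference, name="reference")
    tree = cKDTree(r)
    d, _ = tree.query(q, k=1)
    return np.asarray(d, dtype=float)
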
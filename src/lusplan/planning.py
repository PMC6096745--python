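"""Uniqueness-radius planning over the liver surface.

For each candidate probe contact position sampled on the visible surface, an
expanding sequence of capture spheres selects centreline points of the CT
vascular model; the captured subset is declared *unique* when a globally
optimal registration of the subset back onto the full tree, run with a
finite acceptance threshold, lands on (a transform close to) the identity.
The uniqueness radius R_U of a position is the smallest capture radius whose
subset is unique; mapping R_U over all sampled positions, and interpolating
to the remaining visible vertices, tells the surgeon how broad an
acquisition must be at each liver region for a reliable global alignment.

The rationale: self-registration of a tree subset has a global optimum of
zero error at the identity.  Running the branch-and-bound with an acceptance
threshold lets it stop at *any* alignment whose mean closest-point distance
is under the threshold — if such an alignment exists away from the identity,
the subset's shape is ambiguous within the tree and more data is needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import SurfaceMesh, VascularTree, as_points, farthest_point_indices
from .registration import RegistrationResult, goicp

__all__ = [
    "PlanningConfig",
    "UniquenessMap",
    "farthest_point_sampling",
    "capture_sphere",
    "is_unique",
    "uniqueness_radius",
    "build_uniqueness_map",
    "interpolate_map",
]

logger = logging.getLogger(__name__)

#: sentinel for "not unique at the maximum radius" in numeric arrays
NOT_UNIQUE = -1.0


@dataclass
class PlanningConfig:
    """Parameters of the uniqueness-map computation.

    Defaults follow the planning protocol: 400 probe contact positions
    sampled evenly (farthest-point) over the visible surface, capture radii
    from 5 to 100 mm in 5 mm steps, a GO-ICP acceptance threshold of 2.4 mm
    mean distance error, and a 5 mm tolerance (the clinical accuracy level)
    on the self-displacement that still counts as "the correct alignment".
    """

    n_surface_samples: int = 400
    radii: tuple[float, ...] = tuple(float(r) for r in range(5, 105, 5))
    accept_mean_error: float = 2.4
    uniqueness_tol: float = 5.0
    min_capture_points: int = 10
    seed: int = 0
    goicp_max_nodes: int = 800

    def __post_init__(self):
        radii = tuple(float(r) for r in self.radii)
        if not radii or any(r <= 0 for r in radii):
            raise ValueError("radii must be positive")
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise ValueError("radii must be strictly ascending")
        self.radii = radii


@dataclass
class UniquenessMap:
    """Sampled surface positions with their uniqueness radii.

    ``r_u`` holds one value per sample: a member of the radius schedule, or
    ``NOT_UNIQUE`` (-1) where no radius up to the maximum yielded a unique
    capture.  ``interpolated`` (optional) carries per-visible-vertex values.
    """

    sample_positions: np.ndarray
    r_u: np.ndarray
    interpolated: np.ndarray | None = None
    #: per-sample scan record: list of (radius, n_captured, unique) triples
    details: list | None = None

    def __post_init__(self):
        self.sample_positions = as_points(self.sample_positions, name="samples")
        self.r_u = np.asarray(self.r_u, dtype=float).reshape(-1)
        if len(self.r_u) != len(self.sample_positions):
            raise ValueError("r_u must pair with sample_positions")

    def value_near(self, point) -> tuple[float, float]:
        """(R_U at the sample nearest ``point``, distance to that sample)."""
        p = np.asarray(point, dtype=float).reshape(3)
        d = np.linalg.norm(self.sample_positions - p, axis=1)
        i = int(np.argmin(d))
        return float(self.r_u[i]), float(d[i])


def farthest_point_sampling(points, k: int, start_index: int = 0) -> np.ndarray:
    """Evenly spread ``k`` indices by greedy max-min (farthest-point) sampling."""
    return farthest_point_indices(as_points(points), k, start_index)


def capture_sphere(points, centre, radius: float) -> np.ndarray:
    """Indices of points within the closed ball of ``radius`` around ``centre``."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    pts = as_points(points, allow_empty=True)
    if len(pts) == 0:
        return np.empty(0, dtype=int)
    c = np.asarray(centre, dtype=float).reshape(3)
    d = np.linalg.norm(pts - c, axis=1)
    return np.flatnonzero(d <= radius)


def is_unique(
    subset,
    tree_points,
    accept_mean_error: float = 2.4,
    uniqueness_tol: float = 5.0,
    min_capture_points: int = 10,
    goicp_max_nodes: int = 800,
) -> tuple[bool, RegistrationResult | None]:
    """Test whether a captured centreline subset registers uniquely.

    Runs unconstrained GO-ICP of the subset against the full tree with the
    given acceptance threshold; the subset is unique iff the alignment the
    search accepts displaces the subset points by at most ``uniqueness_tol``
    on average from their original positions.  Subsets smaller than
    ``min_capture_points`` are never unique (insufficient data).
    """
    sub = as_points(subset, allow_empty=True, name="subset")
    if len(sub) < min_capture_points:
        return False, None
    res = goicp(
        sub,
        tree_points,
        accept_mean_error=accept_mean_error,
        max_nodes=goicp_max_nodes,
    )
    displacement = float(
        np.linalg.norm(res.transform.apply(sub) - sub, axis=1).mean()
    )
    accepted = res.residual_mean <= accept_mean_error
    return bool(accepted and displacement <= uniqueness_tol), res


def uniqueness_radius(
    centre,
    tree: VascularTree,
    config: PlanningConfig | None = None,
    return_details: bool = False,
):
    """Smallest capture radius at which the captured points are unique.

    Scans the radius schedule in ascending order and returns the first
    radius whose capture passes :func:`is_unique`; returns ``NOT_UNIQUE``
    (-1) when none does.  With ``return_details`` the per-radius scan record
    (radius, number of captured points, unique flag) is returned as well.
    """
    cfg = config if config is not None else PlanningConfig()
    pts = tree.points
    c = np.asarray(centre, dtype=float).reshape(3)
    details = []
    result = NOT_UNIQUE
    for r in cfg.radii:
        idx = capture_sphere(pts, c, r)
        unique, _ = is_unique(
            pts[idx],
            pts,
            accept_mean_error=cfg.accept_mean_error,
            uniqueness_tol=cfg.uniqueness_tol,
            min_capture_points=cfg.min_capture_points,
            goicp_max_nodes=cfg.goicp_max_nodes,
        )
        details.append((float(r), int(len(idx)), bool(unique)))
        if unique:
            result = float(r)
            break
    if return_details:
        return result, details
    return result


def interpolate_map(samples, values, targets, k: int = 3, power: float = 1.0) -> np.ndarray:
    """Inverse-distance-weighted interpolation of sampled values.

    Each target gets the IDW average of its ``k`` nearest finite-valued
    samples; a target coincident with a sample returns that sample's value
    exactly.  Sentinel-valued (negative) and NaN samples are excluded.
    """
    smp = as_points(samples, name="samples")
    vals = np.asarray(values, dtype=float).reshape(-1)
    if len(vals) != len(smp):
        raise ValueError("values must pair with samples")
    finite = np.isfinite(vals) & (vals >= 0)
    if not finite.any():
        raise ValueError("no finite-valued samples to interpolate from")
    smp, vals = smp[finite], vals[finite]
    tgt = as_points(targets, name="targets")
    kk = min(k, len(smp))
    tree = cKDTree(smp)
    d, idx = tree.query(tgt, k=kk)
    d = np.atleast_2d(d.reshape(len(tgt), kk))
    idx = np.atleast_2d(idx.reshape(len(tgt), kk))
    out = np.empty(len(tgt))
    exact = d[:, 0] < 1e-12
    out[exact] = vals[idx[exact, 0]]
    rest = ~exact
    if rest.any():
        w = 1.0 / d[rest] ** power
        out[rest] = (w * vals[idx[rest]]).sum(axis=1) / w.sum(axis=1)
    return out


def build_uniqueness_map(
    surface: SurfaceMesh, tree: VascularTree, config: PlanningConfig | None = None
) -> UniquenessMap:
    """Compute the R_U map over the visible surface.

    Samples ``n_surface_samples`` probe contact positions on the visible
    vertices by farthest-point sampling, computes the uniqueness radius at
    each, and interpolates the finite values to every visible vertex.
    Deterministic for a fixed configuration.
    """
    cfg = config if config is not None else PlanningConfig()
    visible = surface.visible_vertices
    k = min(cfg.n_surface_samples, len(visible))
    sample_idx = farthest_point_sampling(visible, k, start_index=0)
    positions = visible[sample_idx]
    r_u = np.empty(k)
    all_details = []
    for i, pos in enumerate(positions):
        r_u[i], det = uniqueness_radius(pos, tree, cfg, return_details=True)
        all_details.append(det)
        logger.debug("sample %d/%d at %s: R_U = %s", i + 1, k, pos, r_u[i])
    if np.any(r_u >= 0):
        interpolated = interpolate_map(positions, r_u, visible)
    else:
        interpolated = None
    return UniquenessMap(positions, r_u, interpolated, all_details)
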
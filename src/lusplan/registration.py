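"""Rigid registration algorithms: landmark fit, ICP, and globally optimal ICP.

Three levels of registration are provided:

* :func:`fit_rigid_landmarks` — closed-form least-squares rigid fit between
  pre-matched point lists (centroid demeaning + SVD of the cross-covariance,
  reflection corrected), the classic landmark / fiducial registration.
* :func:`icp` — iterative closest point: alternating nearest-neighbour
  correspondence and landmark fit; a local optimiser.
* :func:`goicp` — globally optimal ICP: branch and bound over SE(3) with
  geometric error bounds, optionally restricted to a rotation cone about a
  prior and a translation box.  Guarantees the global L2 optimum up to a gap
  tolerance, or terminates early once the incumbent's mean closest-point
  distance drops below an acceptance threshold.

The branch-and-bound parameterises rotations as the angle-axis ball (radius
pi, or the given half-angle about the prior rotation) subdivided
octree-style, with a nested translation branch-and-bound per rotation node.
Both clouds are internally shifted to their centroids and scaled into
[-1, 1]^3 by a shared factor; all thresholds are converted consistently and
results are reported back in mm.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .geometry import RigidTransform, as_points, farthest_point_indices

__all__ = [
    "RegistrationResult",
    "SearchConstraints",
    "fit_rigid_landmarks",
    "icp",
    "goicp",
]


@dataclass
class RegistrationResult:
    """Outcome of a rigid registration.

    ``residual_rms`` / ``residual_mean`` are the RMS and mean closest-point
    (or paired-point) distances in mm under ``transform``.  For GO-ICP,
    ``lower_bound`` is a certified lower bound on the achievable RMS residual
    (mm) and ``optimal`` records whether the branch-and-bound closed its gap;
    ``converged`` is False only when the node budget ran out first.
    """

    transform: RigidTransform
    residual_rms: float
    residual_mean: float
    iterations: int = 0
    converged: bool = True
    optimal: bool = False
    lower_bound: float | None = None
    nodes_expanded: int = 0
    residual_history: list[float] | None = None


@dataclass
class SearchConstraints:
    """Prior knowledge restricting the GO-ICP search space.

    ``translation_box`` bounds where the source centroid may land in target
    (CT) coordinates — the practical reading of "constrain the dataset to the
    liver lobe where it was captured".  ``rotation_prior`` with
    ``rotation_half_angle_deg`` restricts rotations to a cone: admissible
    rotations are ``prior @ R`` with ``R`` within the half-angle of identity.
    """

    translation_box: np.ndarray | None = None
    rotation_prior: np.ndarray = field(default_factory=lambda: np.eye(3))
    rotation_half_angle_deg: float = 180.0

    def __post_init__(self):
        if self.translation_box is not None:
            box = np.asarray(self.translation_box, dtype=float).reshape(2, 3)
            if np.any(box[1] <= box[0]):
                raise ValueError("translation_box is degenerate (max <= min)")
            self.translation_box = box
        self.rotation_prior = np.asarray(self.rotation_prior, dtype=float).reshape(3, 3)
        if not (0.0 < self.rotation_half_angle_deg <= 180.0):
            raise ValueError("rotation_half_angle_deg must be in (0, 180]")

    @staticmethod
    def from_dict(d: dict) -> "SearchConstraints":
        return SearchConstraints(
            translation_box=d.get("translation_box"),
            rotation_prior=np.asarray(d.get("rotation_prior", np.eye(3))),
            rotation_half_angle_deg=float(d.get("rotation_half_angle_deg", 180.0)),
        )

    def to_dict(self) -> dict:
        return {
            "translation_box": None
            if self.translation_box is None
            else self.translation_box.tolist(),
            "rotation_prior": self.rotation_prior.tolist(),
            "rotation_half_angle_deg": self.rotation_half_angle_deg,
        }


def _fit_rigid(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Lean SVD rigid fit (no validation) for ICP's inner loop."""
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    h = (src - sc).T @ (dst - dc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, dc - rot @ sc


def fit_rigid_landmarks(source, target) -> RegistrationResult:
    """Least-squares rigid transform between paired landmark lists.

    Solves ``argmin_T sum_i ||T(s_i) - t_i||^2`` over rigid ``T`` by centroid
    demeaning and SVD of the cross-covariance matrix, with the reflection
    corrected to a proper rotation.  ``residual_rms`` is the fiducial
    registration error.
    """
    src = as_points(source, name="source")
    dst = as_points(target, name="target")
    if src.shape != dst.shape:
        raise ValueError("source and target must be paired lists of equal length")
    n = len(src)
    if n < 3:
        raise ValueError(f"need at least 3 landmark pairs, got {n}")
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    src_c, dst_c = src - sc, dst - dc
    # collinear landmarks leave the rotation about the line undetermined
    s_sing = np.linalg.svd(src_c, compute_uv=False)
    if s_sing[1] <= 1e-9 * max(s_sing[0], 1.0):
        raise ValueError("landmarks are collinear: rotation is underdetermined")
    h = src_c.T @ dst_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    tra = dc - rot @ sc
    t = RigidTransform(rot, tra)
    dists = np.linalg.norm(t.apply(src) - dst, axis=1)
    return RegistrationResult(
        transform=t,
        residual_rms=float(np.sqrt((dists**2).mean())),
        residual_mean=float(dists.mean()),
        iterations=1,
        converged=True,
    )


def icp(
    source,
    target,
    init: RigidTransform | None = None,
    max_iter: int = 200,
    tol: float = 1e-4,
    _target_tree: cKDTree | None = None,
) -> RegistrationResult:
    """Iterative closest point between unpaired clouds (local optimiser).

    Alternates nearest-neighbour correspondence against all target points and
    a landmark fit of the full source onto its correspondents, until the RMS
    residual changes by less than ``tol`` (mm) or ``max_iter`` is reached.
    The per-iteration residual sequence is non-increasing.  Correspondence
    ties are resolved to the lowest target index by the k-d tree query.
    """
    src = as_points(source, name="source")
    dst = as_points(target, name="target")
    tree = _target_tree if _target_tree is not None else cKDTree(dst)
    if init is None:
        rot, tra = np.eye(3), np.zeros(3)
    else:
        rot, tra = init.rotation, init.translation
    prev_rms = np.inf
    rms = np.inf
    mean = np.inf
    it = 0
    history: list[float] = []
    for it in range(1, max_iter + 1):
        moved = src @ rot.T + tra
        d, idx = tree.query(moved, k=1)
        rms = float(np.sqrt((d**2).mean()))
        mean = float(d.mean())
        history.append(rms)
        if prev_rms - rms < tol:
            break
        prev_rms = rms
        corr = dst[idx]
        # degenerate correspondence sets (all matched to <3 distinct points)
        if len(np.unique(idx)) < 3:
            raise ValueError(
                "ICP correspondences collapsed onto fewer than 3 target points"
            )
        rot, tra = _fit_rigid(src, corr)
    return RegistrationResult(
        transform=RigidTransform(rot, tra),
        residual_rms=rms,
        residual_mean=mean,
        iterations=it,
        converged=(it < max_iter or prev_rms - rms < tol),
        residual_history=history,
    )


# ---------------------------------------------------------------------------
# Globally optimal ICP (branch and bound over SE(3))
# ---------------------------------------------------------------------------


def _cube_intersects_ball(centre: np.ndarray, half: float, radius: float) -> bool:
    nearest = np.clip(np.zeros(3), centre - half, centre + half)
    return float(np.linalg.norm(nearest)) <= radius


_OCTANTS = np.array(list(itertools.product([-0.5, 0.5], repeat=3)))


class _TranslationBnB:
    """Nested translation branch-and-bound for one rotation node.

    Minimises ``sum_i max(d(q_i + t) - gamma_i - gamma_t, 0)^2`` over an
    axis-aligned box, where ``d`` is the closest-target-point distance and
    ``gamma_i`` the per-point rotation uncertainty of the enclosing rotation
    cube.  Returns a lower bound valid over the whole box and the best
    translation found (its bound evaluated with rotation uncertainty only).

    The frontier is expanded in batches so nearest-neighbour queries are
    amortised over many boxes at once; capping the number of rounds only
    loosens the returned lower bound, never invalidates it.
    """

    def __init__(self, tree: cKDTree, box_lo: np.ndarray, box_hi: np.ndarray):
        self.tree = tree
        self.box_centre = 0.5 * (box_lo + box_hi)
        self.box_half = 0.5 * (box_hi - box_lo)

    def run(
        self,
        q: np.ndarray,
        gamma_r: np.ndarray,
        prune_sse: float,
        max_rounds: int = 7,
        batch: int = 16,
    ) -> tuple[float, np.ndarray, float]:
        """Return (lower_bound_sse, best_t, best_ub_sse)."""
        cen = self.box_centre[None, :]
        hal = self.box_half[None, :]
        lbs, ubs = self._bounds(q, gamma_r, cen, hal)
        best_ub = float(ubs[0])
        best_t = self.box_centre.copy()
        discard_min = np.inf  # min lb among regions pruned against bounds
        for _ in range(max_rounds):
            thresh = min(best_ub - 1e-15, prune_sse)
            active = lbs < thresh
            if not active.any():
                if lbs.size:
                    discard_min = min(discard_min, float(lbs.min()))
                lbs = np.empty(0)
                break
            if (~active).any():
                discard_min = min(discard_min, float(lbs[~active].min()))
            a_idx = np.flatnonzero(active)
            order = a_idx[np.argsort(lbs[a_idx])]
            sel = order[:batch]
            rest = order[batch:]
            # split selected boxes into octants
            child_c = (cen[sel, None, :] + _OCTANTS[None, :, :] * hal[sel, None, :]).reshape(-1, 3)
            child_h = np.repeat(hal[sel] * 0.5, 8, axis=0)
            clbs, cubs = self._bounds(q, gamma_r, child_c, child_h)
            k = int(np.argmin(cubs))
            if cubs[k] < best_ub:
                best_ub = float(cubs[k])
                best_t = child_c[k].copy()
            lbs = np.concatenate([lbs[rest], clbs])
            cen = np.concatenate([cen[rest], child_c])
            hal = np.concatenate([hal[rest], child_h])
        frontier_min = float(lbs.min()) if lbs.size else np.inf
        lower = min(best_ub, frontier_min, discard_min)
        return float(lower), best_t, best_ub

    def _bounds(self, q, gamma_r, centres, halves):
        """Vectorised lb/ub of the clamped-L2 objective for boxes."""
        m = len(centres)
        pts = (q[None, :, :] + centres[:, None, :]).reshape(-1, 3)
        d, _ = self.tree.query(pts)
        d = d.reshape(m, -1)
        gamma_t = np.sqrt((halves**2).sum(axis=1))
        lb_d = np.maximum(d - gamma_r[None, :] - gamma_t[:, None], 0.0)
        ub_d = np.maximum(d - gamma_r[None, :], 0.0)
        return (lb_d**2).sum(axis=1), (ub_d**2).sum(axis=1)


def goicp(
    source,
    target,
    accept_mean_error: float,
    constraints: SearchConstraints | None = None,
    *,
    rms_gap_tol: float = 1e-3,
    max_nodes: int = 200_000,
    translation_margin: float = 10.0,
    icp_max_iter: int = 60,
    search_points: int = 40,
    min_nodes: int = 1,
    explore_prior_first: bool = False,
) -> RegistrationResult:
    """Globally optimal rigid registration by branch and bound over SE(3).

    Searches rotations (angle-axis ball, octree-subdivided cubes) and, nested
    per rotation node, translations (axis-aligned boxes).  Each node's lower
    bound subtracts per-point rotation/translation uncertainty radii from the
    nearest-neighbour distances (clamped at zero); upper bounds come from
    local ICP started at the node centre.  Terminates when the global gap
    closes to ``rms_gap_tol`` (mm) or when the incumbent's mean closest-point
    distance is at most ``accept_mean_error`` (mm) — the threshold exit may
    only fire once at least ``min_nodes`` rotation nodes have been expanded,
    so the accepted incumbent is a best-of-explored-regions solution.  If
    the node budget runs out first the result is flagged not converged.

    Sources larger than ``search_points`` are farthest-point subsampled for
    the search; incumbents and the acceptance test always use the full
    source, and the optimality certificate is withheld in that case.  With
    ``explore_prior_first`` lower-bound ties in the queue break toward the
    prior rotation — appropriate when the prior is informative (a tracked
    acquisition) but not for ambiguity detection, which relies on the
    bound-driven order.

    The returned transform maps source coordinates into target coordinates
    and always satisfies the constraints (when given).
    """
    src = as_points(source, name="source")
    dst = as_points(target, name="target")
    cons = constraints if constraints is not None else SearchConstraints()

    # --- normalisation: demean both clouds, shared scale into [-1, 1]^3 ---
    cs, ct = src.mean(axis=0), dst.mean(axis=0)
    src_c, dst_c = src - cs, dst - ct
    if cons.translation_box is not None:
        box_lo_mm, box_hi_mm = cons.translation_box
    else:
        box_lo_mm = dst.min(axis=0) - translation_margin
        box_hi_mm = dst.max(axis=0) + translation_margin
    scale = max(
        np.abs(src_c).max(),
        np.abs(dst_c).max(),
        np.abs(box_lo_mm - ct).max(),
        np.abs(box_hi_mm - ct).max(),
        1e-9,
    )
    x = src_c / scale
    y = dst_c / scale
    # translation box bounds where the source centroid lands, in target frame
    t_lo = (box_lo_mm - ct) / scale
    t_hi = (box_hi_mm - ct) / scale
    if np.any(t_hi <= t_lo):
        raise ValueError("translation constraint box is infeasible")
    accept = accept_mean_error / scale
    gap_tol = rms_gap_tol / scale

    tree = cKDTree(y)
    prior = cons.rotation_prior
    theta_max = np.deg2rad(cons.rotation_half_angle_deg)

    # Large sources are subsampled (farthest-point) for the search itself;
    # incumbents and the acceptance threshold are always evaluated on the
    # full source, but optimality is then not certified.
    subsampled = len(x) > search_points
    xs = x[farthest_point_indices(x, search_points)] if subsampled else x
    ns = len(xs)
    xnorm = np.linalg.norm(xs, axis=1)
    tbnb = _TranslationBnB(tree, t_lo, t_hi)

    def eval_sse(rot: np.ndarray, t: np.ndarray) -> tuple[float, float, float]:
        """(full sse, full mean, search-subset sse) of closest distances."""
        d, _ = tree.query(x @ rot.T + t)
        sse = float((d**2).sum())
        if subsampled:
            ds, _ = tree.query(xs @ rot.T + t)
            sse_s = float((ds**2).sum())
        else:
            sse_s = sse
        return sse, float(d.mean()), sse_s

    def feasible(rot: np.ndarray, t: np.ndarray) -> bool:
        rel = Rotation.from_matrix(prior.T @ rot)
        ang = np.linalg.norm(rel.as_rotvec())
        return (
            ang <= theta_max + 1e-9
            and np.all(t >= t_lo - 1e-12)
            and np.all(t <= t_hi + 1e-12)
        )

    def try_candidate(rot, t):
        """Evaluate a candidate; ICP-refine it when promising; update incumbent."""
        nonlocal inc_sse, inc_mean, inc_rot, inc_t, inc_sse_s
        sse, mean, sse_s = eval_sse(rot, t)
        if sse < inc_sse:
            inc_sse, inc_mean, inc_rot, inc_t = sse, mean, rot, t
            inc_sse_s = min(inc_sse_s, sse_s)
        # while still hunting for an acceptable basin, refine every start
        # (multi-start ICP is what finds the global basin); once the incumbent
        # is acceptable only competitive starts are worth refining
        if inc_mean > accept or sse < 3.0 * inc_sse:
            try:
                res = icp(
                    xs, y, RigidTransform(rot, t), max_iter=icp_max_iter,
                    tol=1e-9, _target_tree=tree,
                )
            except ValueError:  # correspondences collapsed (degenerate fit)
                return
            rt, tt = res.transform.rotation, res.transform.translation
            if feasible(rt, tt):
                sse2, mean2, sse_s2 = eval_sse(rt, tt)
                if sse2 < inc_sse:
                    inc_sse, inc_mean, inc_rot, inc_t = sse2, mean2, rt, tt
                inc_sse_s = min(inc_sse_s, sse_s2)

    # incumbent: start from the prior rotation with centroid-aligned translation
    inc_rot = prior.copy()
    inc_t = np.clip(np.zeros(3), t_lo, t_hi)
    inc_sse_s = np.inf
    inc_sse, inc_mean, inc_sse_s = eval_sse(inc_rot, inc_t)
    try_candidate(inc_rot, inc_t)

    counter = itertools.count()
    heap: list = []
    root_c = np.zeros(3)
    root_h = min(np.pi, theta_max)

    def node_key(lb: float, centre: np.ndarray) -> tuple:
        # with an informative prior, break lower-bound ties toward it so the
        # physically plausible region enters the incumbent pool first;
        # otherwise insertion order (bound-driven search) decides
        if explore_prior_first:
            return (lb, float(np.linalg.norm(centre)), next(counter))
        return (lb, next(counter), 0.0)

    heap.append((*node_key(0.0, root_c), root_c, root_h))
    nodes = 0
    global_lb = 0.0
    optimal = False
    hit_cap = False

    while heap:
        lb, _, _, wc, wh = heapq.heappop(heap)
        global_lb = lb  # heap min: lower bound over the whole remaining space
        # at least min_nodes rotation cubes are expanded before the
        # threshold exit may fire, so the incumbent offered to the
        # acceptance test is the best over that many explored regions,
        # never just the seeding guess
        if nodes >= max(min_nodes, 1) and inc_mean <= accept:
            break
        if np.sqrt(inc_sse_s / ns) - np.sqrt(max(global_lb, 0.0) / ns) <= gap_tol:
            optimal = True
            break
        if lb >= inc_sse_s - 1e-15:
            optimal = True
            break
        if nodes >= max_nodes:
            hit_cap = True
            break
        nodes += 1
        # split rotation cube into octants
        offs = _OCTANTS * wh
        for off in offs:
            cc = wc + off
            ch = wh * 0.5
            if not _cube_intersects_ball(cc, ch, theta_max):
                continue
            rot_c = prior @ Rotation.from_rotvec(cc).as_matrix()
            half_diag = np.sqrt(3.0) * ch
            gamma_r = 2.0 * np.sin(min(half_diag / 2.0, np.pi / 2.0)) * xnorm
            q = xs @ rot_c.T
            child_lb, t_best, _ = tbnb.run(q, gamma_r, inc_sse_s)
            try_candidate(rot_c, t_best)
            if child_lb < inc_sse_s - 1e-15:
                heapq.heappush(heap, (*node_key(child_lb, cc), cc, ch))
        if inc_mean <= accept and nodes >= max(min_nodes, 1):
            break
    else:
        # queue exhausted: every region was pruned against the incumbent
        optimal = True
        global_lb = inc_sse_s

    if subsampled:
        # bounds refer to the search subsample; the full-source optimum is
        # not certified, so only the trivial lower bound is reported
        optimal = False
        global_lb = 0.0

    # map the incumbent back to mm:  x_t = R (x_s - cs)/s * s + ct + s*t
    rot_mm = inc_rot
    t_mm = ct + scale * inc_t - rot_mm @ cs
    transform = RigidTransform(rot_mm, t_mm)
    d, _ = tree.query(x @ inc_rot.T + inc_t)
    d_mm = d * scale
    lb_rms_mm = float(np.sqrt(max(global_lb, 0.0) / ns) * scale)
    rms_mm = float(np.sqrt((d_mm**2).mean()))
    return RegistrationResult(
        transform=transform,
        residual_rms=rms_mm,
        residual_mean=float(d_mm.mean()),
        iterations=nodes,
        converged=not hit_cap,
        optimal=optimal,
        lower_bound=min(lb_rms_mm, rms_mm),
        nodes_expanded=nodes,
    )
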
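"""Registration of tracked laparoscopic ultrasound sweeps to the CT tree.

A tracked sweep is an ordered sequence of 2D binary vessel masks with a
per-frame rigid pose and pixel calibration, plus digitised liver-surface
contact points and paired validation landmarks (vessel bifurcations picked
in both the sweep and the CT model).

The pipeline mirrors the planning stage: vessel-section centroids extracted
from the masks form an intra-operative centreline cloud; the probe contact
position P (mean of the digitised surface points) is the centre of an
expanding sequence of capture spheres; at each radius the captured cloud is
globally registered to the full CT tree under prior search-space constraints
and the landmark TRE is recorded.  The success radius R_S is the smallest
radius from which the TRE curve has reached its stable minimum; if the curve
never stabilises the registration is unsuccessful.

Image-plane convention: mask axes (u, v) map to (x, y) in the probe frame
with the frame normal along +z, the origin at the centre of pixel (0, 0) and
0-based pixel indexing; the frame pose carries the probe calibration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import make_smoothing_spline

from .geometry import RigidTransform, VascularTree, as_points, rms_tre
from .planning import UniquenessMap, capture_sphere
from .registration import SearchConstraints, fit_rigid_landmarks, goicp

__all__ = [
    "SweepFrame",
    "TrackedSweep",
    "TreCurve",
    "extract_sweep_centrelines",
    "smooth_sweep",
    "probe_contact_position",
    "lobe_translation_box",
    "expanding_radius_registration",
    "success_radius",
    "reference_standard",
]

logger = logging.getLogger(__name__)

#: connected components smaller than this (pixels) are segmentation specks
MIN_COMPONENT_PIXELS = 5

_FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass
class SweepFrame:
    """One tracked ultrasound frame: binary mask, pose and calibration.

    ``mask`` is indexed ``[v, u]`` (row v maps to y, column u to x);
    ``pixel_spacing`` is (mm/pixel along u, mm/pixel along v); ``pose`` maps
    probe-frame mm coordinates into the common (CT-comparable) frame.
    """

    mask: np.ndarray
    pose: RigidTransform
    pixel_spacing: tuple[float, float]

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be a 2D grid")
        su, sv = self.pixel_spacing
        if su <= 0 or sv <= 0:
            raise ValueError("pixel spacings must be positive")
        self.pixel_spacing = (float(su), float(sv))


@dataclass
class TrackedSweep:
    """An ordered tracked LUS sweep with digitised surface and landmarks."""

    frames: list[SweepFrame]
    digitised_surface: np.ndarray
    landmarks_lus: np.ndarray
    landmarks_ct: np.ndarray

    def __post_init__(self):
        if len(self.frames) < 1:
            raise ValueError("sweep needs at least one frame")
        self.digitised_surface = as_points(
            self.digitised_surface, name="digitised_surface"
        )
        self.landmarks_lus = as_points(
            self.landmarks_lus, allow_empty=True, name="landmarks_lus"
        )
        self.landmarks_ct = as_points(
            self.landmarks_ct, allow_empty=True, name="landmarks_ct"
        )
        if self.landmarks_lus.shape != self.landmarks_ct.shape:
            raise ValueError("landmark lists must be paired (equal length)")


@dataclass
class TreCurve:
    """Landmark RMS TRE as a function of capture radius.

    Entries are NaN where the capture held fewer points than required for a
    registration; ``transforms`` holds the per-radius registration (None
    where undefined).
    """

    radii: np.ndarray
    rms_tre: np.ndarray
    transforms: list[RigidTransform | None]

    def __post_init__(self):
        self.radii = np.asarray(self.radii, dtype=float).reshape(-1)
        self.rms_tre = np.asarray(self.rms_tre, dtype=float).reshape(-1)
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be strictly ascending")
        if len(self.rms_tre) != len(self.radii) or len(self.transforms) != len(
            self.radii
        ):
            raise ValueError("curve entries must pair with radii")


def extract_sweep_centrelines(sweep: TrackedSweep) -> tuple[np.ndarray, np.ndarray]:
    """Estimate 3D centreline points as vessel-section centroids.

    Per frame: 4-connected components of the binary mask; components smaller
    than ``MIN_COMPONENT_PIXELS`` are discarded; each remaining component's
    area centroid (pixel coordinates) is converted to mm via the pixel
    spacing and lifted to 3D through the frame pose.  Returns the
    concatenated points and the index of the frame each came from.
    """
    pts, frame_ids = [], []
    for f_idx, frame in enumerate(sweep.frames):
        labels, n = ndimage.label(frame.mask, structure=_FOUR_CONNECTED)
        if n == 0:
            continue
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
        keep = [i + 1 for i in range(n) if sizes[i] >= MIN_COMPONENT_PIXELS]
        if not keep:
            continue
        centroids = ndimage.center_of_mass(frame.mask, labels, keep)
        su, sv = frame.pixel_spacing
        for cv, cu in centroids:  # center_of_mass returns (row, col) = (v, u)
            local = np.array([cu * su, cv * sv, 0.0])
            pts.append(frame.pose.apply(local[None, :])[0])
            frame_ids.append(f_idx)
    if not pts:
        raise ValueError("sweep contains no vessel sections")
    return np.asarray(pts), np.asarray(frame_ids, dtype=int)


def smooth_sweep(
    points,
    frame_ids,
    reference_positions,
    lam: float | None = None,
) -> np.ndarray:
    """Suppress tracking jitter using the digitised surface path.

    Fits a smoothing cubic spline (one per coordinate, over frame order) to
    the per-frame reference positions — the tracked surface digitisation —
    and subtracts each frame's residual (raw minus spline) from every
    centreline point of that frame.  With fewer than 4 frames no smoothing
    is applied.  ``lam`` is the spline regularisation weight (GCV-chosen
    when None).
    """
    pts = as_points(points)
    frame_ids = np.asarray(frame_ids, dtype=int)
    ref = as_points(reference_positions, name="reference_positions")
    if len(frame_ids) != len(pts):
        raise ValueError("frame_ids must pair with points")
    if len(ref) < 4:
        warnings.warn("fewer than 4 frames: sweep smoothing skipped")
        return pts.copy()
    x = np.arange(len(ref), dtype=float)
    smooth = np.column_stack(
        [make_smoothing_spline(x, ref[:, j], lam=lam)(x) for j in range(3)]
    )
    residual = ref - smooth
    return pts - residual[frame_ids]


def probe_contact_position(digitised) -> np.ndarray:
    """Probe contact position P: the mean of the digitised surface points."""
    return as_points(digitised, name="digitised").mean(axis=0)


def lobe_translation_box(
    tree: VascularTree, near_point, reach: float = 60.0, margin: float = 10.0
) -> np.ndarray:
    """Translation box for the liver lobe an acquisition was captured in.

    The lobe is operationalised as the branches with any point within
    ``reach`` of the acquisition position; the box is their bounding box
    plus ``margin`` mm.  It bounds where the registered sweep's centroid may
    land, excluding physically impossible cross-liver alignments.
    """
    p = np.asarray(near_point, dtype=float).reshape(3)
    selected = [
        b for b in tree.branches if np.linalg.norm(b - p, axis=1).min() <= reach
    ]
    if not selected:
        raise ValueError(f"no branches within {reach} mm of the given position")
    pts = np.concatenate(selected)
    return np.array([pts.min(axis=0) - margin, pts.max(axis=0) + margin])


def expanding_radius_registration(
    sweep_points,
    p,
    tree: VascularTree,
    radii,
    constraints: SearchConstraints | None = None,
    landmarks_lus=None,
    landmarks_ct=None,
    accept_mean_error: float = 2.4,
    min_capture_points: int = 10,
    goicp_max_nodes: int = 300,
    goicp_min_nodes: int = 24,
) -> TreCurve:
    """Register expanding captures of the sweep cloud and record the TRE.

    For each radius: capture the sweep centreline points within the ball
    around ``p``, run constrained GO-ICP against all tree centreline points
    (prior-first exploration, at least ``goicp_min_nodes`` rotation regions
    examined), apply the transform to the LUS landmarks and record the RMS
    TRE against the paired CT landmarks.  Captures below
    ``min_capture_points`` leave a NaN entry.
    """
    pts = as_points(sweep_points, name="sweep_points")
    lm_lus = as_points(landmarks_lus, name="landmarks_lus")
    lm_ct = as_points(landmarks_ct, name="landmarks_ct")
    if lm_lus.shape != lm_ct.shape:
        raise ValueError("landmark lists must be paired")
    radii = np.asarray(radii, dtype=float).reshape(-1)
    centre = np.asarray(p, dtype=float).reshape(3)
    tree_pts = tree.points
    tres = np.full(len(radii), np.nan)
    transforms: list[RigidTransform | None] = [None] * len(radii)
    for i, r in enumerate(radii):
        idx = capture_sphere(pts, centre, r)
        if len(idx) < min_capture_points:
            continue
        res = goicp(
            pts[idx],
            tree_pts,
            accept_mean_error=accept_mean_error,
            constraints=constraints,
            max_nodes=goicp_max_nodes,
            min_nodes=goicp_min_nodes,
            explore_prior_first=True,
        )
        transforms[i] = res.transform
        tres[i] = rms_tre(res.transform.apply(lm_lus), lm_ct)
        logger.debug(
            "radius %.0f mm: %d points, %d nodes, mean residual %.2f mm, "
            "TRE %.2f mm",
            r, len(idx), res.nodes_expanded, res.residual_mean, tres[i],
        )
    return TreCurve(radii, tres, transforms)


def success_radius(
    curve: TreCurve,
    rel_tol: float = 0.10,
    abs_tol: float = 1.0,
    sanity_cap: float = 50.0,
    min_tail: int = 2,
) -> float | None:
    """Radius from which the TRE curve has reached its stable minimum.

    Returns the smallest radius r* such that every defined TRE at radii
    >= r* stays within ``min * (1 + rel_tol) + abs_tol`` of the overall
    defined minimum, requiring at least ``min_tail`` defined entries in the
    stable tail; None (failure) when no such radius exists or the stable
    minimum exceeds ``sanity_cap`` mm.
    """
    defined = np.isfinite(curve.rms_tre)
    if defined.sum() < 2:
        return None
    tre = curve.rms_tre
    level = float(np.nanmin(tre)) * (1.0 + rel_tol) + abs_tol
    if float(np.nanmin(tre)) > sanity_cap:
        return None
    # scan from the end: the stable tail is the maximal suffix within level
    ok_suffix = np.zeros(len(tre), dtype=bool)
    good = True
    for i in range(len(tre) - 1, -1, -1):
        if defined[i] and tre[i] > level:
            good = False
        ok_suffix[i] = good
    candidates = np.flatnonzero(ok_suffix & defined)
    if len(candidates) == 0 or defined[candidates[0]:].sum() < min_tail:
        return None
    return float(curve.radii[candidates[0]])


def reference_standard(
    sweep: TrackedSweep, uniqueness_map: UniquenessMap, p
) -> tuple[RigidTransform, float, np.ndarray, float, float]:
    """Best-achievable rigid alignment from the validation landmarks.

    Fits the landmark pairs directly (least squares), giving the reference
    transform and its RMS TRE ``e_r`` — the minimum TRE any rigid transform
    can achieve.  The reference probe position ``p_r`` is the transform
    applied to P; the planning prediction ``r_u`` is the uniqueness radius at
    the map sample nearest ``p_r`` and ``d_r`` the distance to that sample.

    Returns ``(transform, e_r, p_r, r_u, d_r)``.
    """
    if len(sweep.landmarks_lus) < 3:
        raise ValueError("need at least 3 landmark pairs")
    res = fit_rigid_landmarks(sweep.landmarks_lus, sweep.landmarks_ct)
    p = np.asarray(p, dtype=float).reshape(3)
    p_r = res.transform.apply(p[None, :])[0]
    r_u, d_r = uniqueness_map.value_near(p_r)
    return res.transform, res.residual_rms, p_r, r_u, d_r
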
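"""Synthetic vascular trees, liver-like surfaces, and tracked LUS sweeps.

Generates data with the statistical structure the framework assumes, so
every stage can be exercised end to end without patient data:

* a recursive, asymmetric, binary-bifurcating vascular tree grown inside a
  liver-scale bounding ellipsoid (semi-axes ~120 x 80 x 60 mm), with every
  internal node recorded as a bifurcation and branches resampled at a fixed
  centreline spacing;
* a triangulated ellipsoid surface whose anterior (max-z) vertex fraction is
  flagged visible, standing in for the surface reachable by the probe;
* planar sweep acquisition: frames posed along a surface path, each a binary
  mask rasterised from the intersection of vessel tubes with the image
  plane, with optional per-frame centroid noise, pose jitter and tree
  deformation (per-branch Gaussian displacements or a global squash standing
  in for insufflation).

Trees are binary-bifurcating; real hepatic anatomy also shows trifurcations,
but binary branching is sufficient for the geometry the framework exercises.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, cKDTree

from .assessment import perturb_branches
from .geometry import RigidTransform, SurfaceMesh, VascularTree, as_points
from .sweep import SweepFrame, TrackedSweep

__all__ = [
    "TreeGenParams",
    "SweepGenParams",
    "generate_tree",
    "generate_surface",
    "simulate_sweep",
    "apply_global_deformation",
    "default_sweep_path",
]


@dataclass
class TreeGenParams:
    """Recursive bifurcating-tree generator parameters (mm / degrees)."""

    depth: int = 6
    root_length: float = 50.0
    length_decay: float = 0.72
    branch_angle_range: tuple[float, float] = (25.0, 50.0)
    segment_spacing: float = 2.5
    jitter: float = 0.0
    bounding_ellipsoid: tuple[float, float, float] = (120.0, 80.0, 60.0)
    seed: int = 0

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2 to produce bifurcations")
        if self.segment_spacing <= 0 or self.root_length <= 0:
            raise ValueError("lengths and spacing must be positive")
        if not 0 < self.length_decay < 1:
            raise ValueError("length_decay must be in (0, 1)")


def _inside_ellipsoid(p: np.ndarray, semi: np.ndarray) -> bool:
    return float(((p / semi) ** 2).sum()) <= 1.0


def _clip_to_ellipsoid(p: np.ndarray, semi: np.ndarray) -> np.ndarray:
    q = ((p / semi) ** 2).sum()
    if q <= 1.0:
        return p
    return p / np.sqrt(q)


def _resample_polyline(a: np.ndarray, b: np.ndarray, spacing: float) -> np.ndarray:
    """Points from a to b (inclusive) at roughly the requested spacing."""
    length = np.linalg.norm(b - a)
    n = max(int(np.ceil(length / spacing)) + 1, 2)
    t = np.linspace(0.0, 1.0, n)
    return a + t[:, None] * (b - a)


def generate_tree(params: TreeGenParams | None = None) -> VascularTree:
    """Grow an asymmetric binary-bifurcating tree inside the ellipsoid.

    Every internal node is recorded as a bifurcation; each parent-to-child
    segment becomes one branch polyline resampled at ``segment_spacing``.
    Randomised branching angles and lengths make the tree asymmetric by
    construction, so generic subsets have no self-similar twins.  Segments
    that would leave the bounding ellipsoid are clipped to it (with a
    warning).  A tree of depth d has 2^(d-1) - 1 bifurcations.
    """
    p = params if params is not None else TreeGenParams()
    rng = np.random.default_rng(p.seed)
    semi = np.asarray(p.bounding_ellipsoid, dtype=float)
    branches: list[np.ndarray] = []
    bifurcations: list[np.ndarray] = []
    clipped = False

    root_start = np.array([-0.75 * semi[0], 0.0, 0.0])
    root_dir = np.array([1.0, 0.15, 0.1])
    root_dir = root_dir / np.linalg.norm(root_dir)

    def orthonormal(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        helper = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        u = np.cross(d, helper)
        u /= np.linalg.norm(u)
        return u, np.cross(d, u)

    def grow(start: np.ndarray, direction: np.ndarray, length: float, level: int):
        nonlocal clipped
        end = start + direction * length
        if not _inside_ellipsoid(end, semi):
            end = _clip_to_ellipsoid(end, semi)
            clipped = True
        seg = _resample_polyline(start, end, p.segment_spacing)
        if p.jitter > 0 and len(seg) > 2:
            seg = seg.copy()
            seg[1:-1] += rng.normal(0.0, p.jitter, size=(len(seg) - 2, 3))
        branches.append(seg)
        if level >= p.depth:
            return
        bifurcations.append(end.copy())
        u, v = orthonormal(direction)
        child_len = length * p.length_decay
        lo, hi = np.deg2rad(p.branch_angle_range)
        # two children on roughly opposite sides of the parent direction
        phi0 = rng.uniform(0.0, 2 * np.pi)
        for k in range(2):
            ang = rng.uniform(lo, hi)
            phi = phi0 + np.pi * k + rng.uniform(-0.4, 0.4)
            d = (
                np.cos(ang) * direction
                + np.sin(ang) * (np.cos(phi) * u + np.sin(phi) * v)
            )
            d /= np.linalg.norm(d)
            grow(end, d, child_len * rng.uniform(0.85, 1.15), level + 1)

    grow(root_start, root_dir, p.root_length, 1)
    if clipped:
        warnings.warn("tree reached the bounding ellipsoid and was clipped")
    return VascularTree(branches, np.asarray(bifurcations))


def generate_surface(
    semi_axes=(120.0, 80.0, 60.0),
    n_vertices: int = 800,
    visible_fraction: float = 0.4,
    seed: int = 0,
) -> SurfaceMesh:
    """Triangulated ellipsoid with the anterior vertex fraction flagged visible.

    Vertices are a spherical Fibonacci lattice (even coverage) scaled by the
    semi-axes; faces come from the convex hull, so the mesh is watertight.
    The visible mask marks the top ``visible_fraction`` of vertices by z.
    """
    semi = np.asarray(semi_axes, dtype=float)
    if np.any(semi <= 0):
        raise ValueError("semi-axes must be positive")
    n = int(n_vertices)
    i = np.arange(n)
    golden = (1 + np.sqrt(5)) / 2
    z = 1 - 2 * (i + 0.5) / n
    r = np.sqrt(np.maximum(1 - z**2, 0.0))
    phi = 2 * np.pi * i / golden
    unit = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    hull = ConvexHull(unit)
    faces = hull.simplices.copy()
    # orient faces outward (hull simplices are not consistently wound)
    tri = unit[faces]
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    centres = tri.mean(axis=1)
    flip = (normals * centres).sum(axis=1) < 0
    faces[flip] = faces[flip][:, ::-1]
    vertices = unit * semi
    n_visible = max(int(round(visible_fraction * n)), 1)
    order = np.argsort(-vertices[:, 2])
    mask = np.zeros(n, dtype=bool)
    mask[order[:n_visible]] = True
    return SurfaceMesh(vertices, faces, mask)


def apply_global_deformation(
    tree: VascularTree, mode: str, magnitude: float, seed: int = 0
) -> VascularTree:
    """A simple stand-in for intra-operative deformation.

    ``branch_gaussian`` displaces each branch rigidly by a Gaussian vector
    of per-axis deviation ``magnitude`` (within-branch shape preserved);
    ``affine_squash`` scales the z axis by (1 - magnitude) about the tree
    centroid — a genuine non-rigid change emulating insufflation-style
    compression.  No biomechanics is modelled.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    if mode == "branch_gaussian":
        return perturb_branches(tree, magnitude, seed)
    if mode == "affine_squash":
        centroid = tree.points.mean(axis=0)
        scale = np.array([1.0, 1.0, 1.0 - magnitude])

        def squash(pts):
            return (pts - centroid) * scale + centroid

        return VascularTree(
            [squash(b) for b in tree.branches],
            squash(tree.bifurcations) if len(tree.bifurcations) else tree.bifurcations,
        )
    raise ValueError(f"unknown deformation mode {mode!r}")


@dataclass
class SweepGenParams:
    """Planar sweep acquisition parameters."""

    path: np.ndarray = None
    frame_count: int = 40
    fov: tuple[float, float] = (60.0, 70.0)
    pixel_spacing: tuple[float, float] = (0.5, 0.5)
    vessel_radius: float = 3.0
    centroid_noise: float = 0.0
    pose_jitter: tuple[float, float] = (0.0, 0.0)  # (mm, degrees)
    deformation: dict | None = None
    seed: int = 0

    def __post_init__(self):
        if self.path is None:
            raise ValueError("a sweep path on the surface is required")
        self.path = as_points(self.path, name="path")
        if self.frame_count < 4:
            raise ValueError("frame_count must be >= 4")
        if min(self.fov) <= 0 or min(self.pixel_spacing) <= 0:
            raise ValueError("fov and pixel_spacing must be positive")


def default_sweep_path(
    surface: SurfaceMesh, start, end, n: int = 40, lift: float = 0.0
) -> np.ndarray:
    """A straight path between two points projected onto nearby surface vertices.

    Convenience for building sweep paths in simulations: interpolates
    ``start`` to ``end`` and snaps each sample to the closest visible
    vertex, then linearly blends to keep ordering smooth.
    """
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    t = np.linspace(0.0, 1.0, n)[:, None]
    raw = start + t * (end - start)
    vis = surface.visible_vertices
    tree = cKDTree(vis)
    _, idx = tree.query(raw)
    snapped = vis[idx]
    return 0.5 * (raw + snapped) + np.array([0.0, 0.0, lift])


def _frame_pose(pos, tangent, interior_point) -> RigidTransform:
    """Pose of a frame at a path position: x lateral, y depth, z sweep normal."""
    d = tangent / np.linalg.norm(tangent)
    depth = interior_point - pos
    depth = depth - (depth @ d) * d
    nd = np.linalg.norm(depth)
    if nd < 1e-9:
        raise ValueError("degenerate sweep geometry: depth direction undefined")
    depth /= nd
    lateral = np.cross(depth, d)
    rot = np.column_stack([lateral, depth, d])
    return RigidTransform(rot, pos)


def simulate_sweep(
    tree: VascularTree,
    surface: SurfaceMesh,
    params: SweepGenParams,
) -> tuple[TrackedSweep, dict]:
    """Simulate a tracked LUS sweep through the vascular tree.

    For each frame pose along the path the tube of ``vessel_radius`` around
    the (optionally deformed) centrelines is intersected with the image
    plane and rasterised: a pixel is set iff its centre lies within the tube.
    ``centroid_noise`` shifts each frame's imaged content by a random
    in-plane vector (segmentation/localisation error) while the stored pose
    stays clean; ``pose_jitter`` corrupts the stored poses instead (tracking
    error).  The digitised surface points are the frame contact positions.

    Landmark pairs are the bifurcations visible near the sweep: the LUS side
    from the (deformed) acquisition geometry, the CT side from the original
    tree.  Returns the sweep and a ground-truth dict with the true
    sweep-to-CT transform (identity) and the acquisition tree.
    """
    rng = np.random.default_rng(params.seed)
    acq_tree = tree
    if params.deformation:
        mode = params.deformation.get("mode", "branch_gaussian")
        magnitude = float(params.deformation.get("magnitude", 0.0))
        acq_tree = apply_global_deformation(
            tree, mode, magnitude, seed=int(rng.integers(2**31))
        )

    # dense resampling of the acquisition tree for tube distance queries
    dense = []
    for b in acq_tree.branches:
        seg_len = np.linalg.norm(np.diff(b, axis=0), axis=1).sum()
        n = max(int(seg_len / 0.4), len(b))
        t = np.linspace(0.0, 1.0, n)
        cum = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(b, axis=0), axis=1))])
        cum /= max(cum[-1], 1e-12)
        dense.append(
            np.column_stack([np.interp(t, cum, b[:, j]) for j in range(3)])
        )
    dense = np.concatenate(dense)
    dense_tree = cKDTree(dense)

    # frame positions along the path
    path = params.path
    cum = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(path, axis=0), axis=1))]
    )
    s = np.linspace(0.0, cum[-1], params.frame_count)
    pos = np.column_stack([np.interp(s, cum, path[:, j]) for j in range(3)])
    tangents = np.gradient(pos, axis=0)
    interior = surface.vertices.mean(axis=0)

    fov_u, fov_v = params.fov
    su, sv = params.pixel_spacing
    nu, nv = int(round(fov_u / su)), int(round(fov_v / sv))
    uu, vv = np.meshgrid(np.arange(nu) * su, np.arange(nv) * sv)
    pix_local = np.column_stack(
        [uu.ravel() - fov_u / 2.0, vv.ravel(), np.zeros(uu.size)]
    )

    frames: list[SweepFrame] = []
    any_vessel = False
    jit_t, jit_r = params.pose_jitter
    for k in range(params.frame_count):
        true_pose = _frame_pose(pos[k], tangents[k], interior)
        slice_pose = true_pose
        if params.centroid_noise > 0:
            # shift the imaged content in-plane; the stored pose stays clean,
            # so extracted centroids carry this offset as localisation error
            off = rng.normal(0.0, params.centroid_noise, size=2)
            shift = true_pose.rotation[:, 0] * off[0] + true_pose.rotation[:, 1] * off[1]
            slice_pose = RigidTransform(true_pose.rotation, true_pose.translation + shift)
        pix_world = slice_pose.apply(pix_local)
        d, _ = dense_tree.query(pix_world)
        mask = (d <= params.vessel_radius).reshape(nv, nu)
        if mask.any():
            any_vessel = True
        stored_pose = true_pose
        if jit_t > 0 or jit_r > 0:
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            ang = np.deg2rad(rng.normal(0.0, max(jit_r, 1e-12)))
            from scipy.spatial.transform import Rotation as _R

            jr = _R.from_rotvec(axis * ang).as_matrix()
            jt = rng.normal(0.0, max(jit_t, 1e-12), size=3)
            stored_pose = RigidTransform(jr @ true_pose.rotation, true_pose.translation + jt)
        # the mask was built with the lateral origin at -fov/2; shift the pose
        # so pixel (0, 0) maps to that corner per the image-plane convention
        corner = stored_pose.translation - stored_pose.rotation[:, 0] * (fov_u / 2.0)
        frames.append(
            SweepFrame(mask, RigidTransform(stored_pose.rotation, corner), (su, sv))
        )
    if not any_vessel:
        raise ValueError("empty sweep: the path misses all vessels")

    digitised = pos + rng.normal(0.0, 0.3, size=pos.shape)

    # landmarks: bifurcations near the swept volume, paired LUS <-> CT
    near = np.linalg.norm(
        acq_tree.bifurcations[:, None, :] - pos[None, :, :], axis=2
    ).min(axis=1)
    margin = float(np.hypot(fov_u, fov_v))
    lm_idx = np.flatnonzero(near <= margin)
    landmarks_lus = acq_tree.bifurcations[lm_idx] + rng.normal(
        0.0, 0.5, size=(len(lm_idx), 3)
    )
    landmarks_ct = tree.bifurcations[lm_idx]

    sweep = TrackedSweep(frames, digitised, landmarks_lus, landmarks_ct)
    truth = {
        "transform": RigidTransform.identity(),
        "acquisition_tree": acq_tree,
        "frame_positions": pos,
        "landmark_indices": lm_idx,
    }
    return sweep, truth
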
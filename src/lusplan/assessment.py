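"""Vascular feature assessment: bifurcation landmarks vs centreline ICP.

Simulates the perfect acquisition of N bifurcations (and, for the centreline
method, the branches surrounding them), applies Gaussian displacements that
stand in for deformation and segmentation error, registers the displaced
features back onto the unperturbed model, and measures the induced target
registration error (TRE) over every bifurcation of the model.

Two displacement models are used, matching how each feature type degrades in
practice: bifurcation landmarks are displaced independently per point
(localisation error), whereas centreline branches are displaced rigidly as a
whole (one Gaussian vector per branch, emulating inter-branch deformation).
Displacements are isotropic Gaussians with per-axis standard deviation sigma.

Besides the RMS TRE, each trial yields a *working radius*: the distance
around the acquisition centre within which every bifurcation is registered
to better than a clinical threshold (5 mm by default).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import RigidTransform, VascularTree, as_points
from .registration import fit_rigid_landmarks, icp

__all__ = [
    "AssessmentConfig",
    "sample_bifurcation_subsets",
    "perturb_points",
    "perturb_branches",
    "neighbouring_branches",
    "registration_trial",
    "working_radius",
    "run_feature_assessment",
]


@dataclass
class AssessmentConfig:
    """Factorial design of the feature-assessment experiment.

    Defaults follow the full simulation protocol: subsets of N = 3..10
    bifurcations, 50 random combinations per N, and 200 Gaussian displacement
    repetitions per deviation sigma = 1..5 mm, with a 5 mm clinical TRE
    threshold for the working radius.
    """

    n_values: tuple[int, ...] = tuple(range(3, 11))
    n_combinations: int = 50
    sigmas: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    reps_per_sigma: int = 200
    tre_threshold: float = 5.0
    seed: int = 0
    icp_max_iter: int = 200
    icp_tol: float = 1e-4

    def __post_init__(self):
        if any(s <= 0 for s in self.sigmas):
            raise ValueError("sigmas must be positive")
        if self.n_combinations <= 0 or self.reps_per_sigma <= 0:
            raise ValueError("counts must be positive")


def sample_bifurcation_subsets(
    tree: VascularTree, n: int, k: int, seed
) -> list[np.ndarray]:
    """Draw ``k`` distinct index subsets of ``n`` bifurcations each.

    Each subset is sampled uniformly without replacement; subsets are
    distinct from one another and the draw is reproducible under ``seed``.
    """
    m = len(tree.bifurcations)
    if n > m:
        raise ValueError(f"cannot pick {n} of {m} bifurcations")
    rng = np.random.default_rng(seed)
    subsets: list[np.ndarray] = []
    seen: set[tuple[int, ...]] = set()
    # distinct subsets by rejection; feasible whenever C(m, n) >= k
    max_tries = 1000 * k
    for _ in range(max_tries):
        if len(subsets) == k:
            break
        cand = np.sort(rng.choice(m, size=n, replace=False))
        key = tuple(int(i) for i in cand)
        if key not in seen:
            seen.add(key)
            subsets.append(cand)
    if len(subsets) < k:
        raise ValueError(f"could not draw {k} distinct subsets of size {n}")
    return subsets


def perturb_points(points, sigma: float, seed) -> np.ndarray:
    """Displace each point by an independent isotropic Gaussian vector.

    ``sigma`` is the per-axis standard deviation in mm.
    """
    pts = as_points(points)
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return pts.copy()
    rng = np.random.default_rng(seed)
    return pts + rng.normal(0.0, sigma, size=pts.shape)


def perturb_branches(tree: VascularTree, sigma: float, seed) -> VascularTree:
    """Displace every branch rigidly by one Gaussian vector per branch.

    All centreline points of a branch share the same displacement, so
    within-branch shape is preserved exactly.  Each bifurcation moves with
    the mean displacement of the branches whose endpoints meet it, keeping
    junction labels attached to the displaced geometry.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    shifts = [
        rng.normal(0.0, sigma, size=3) if sigma > 0 else np.zeros(3)
        for _ in tree.branches
    ]
    new_branches = [b + s for b, s in zip(tree.branches, shifts)]
    bifs = tree.bifurcations.copy()
    if len(bifs):
        reach = 2.0 * tree.spacing()
        ends = np.stack([b[[0, -1]] for b in tree.branches])  # (B, 2, 3)
        for i, bif in enumerate(tree.bifurcations):
            d = np.linalg.norm(ends - bif, axis=2).min(axis=1)
            adjacent = np.flatnonzero(d <= reach)
            if len(adjacent):
                bifs[i] = bif + np.mean([shifts[j] for j in adjacent], axis=0)
    return VascularTree(new_branches, bifs)


def neighbouring_branches(
    tree: VascularTree, bifurcation_idx, spacing_factor: float = 2.0
) -> list[int]:
    """Branches with an endpoint near any selected bifurcation.

    "Near" means within ``spacing_factor`` times the centreline point spacing
    — the branches that meet at, or run right past, the selected junctions.
    """
    bifs = tree.bifurcations[np.asarray(bifurcation_idx, dtype=int)]
    reach = spacing_factor * tree.spacing()
    out = []
    for i, b in enumerate(tree.branches):
        ends = b[[0, -1]]
        d = np.linalg.norm(ends[:, None, :] - bifs[None, :, :], axis=2)
        if d.min() <= reach:
            out.append(i)
    return out


def registration_trial(
    tree: VascularTree,
    subset_idx,
    method: str,
    sigma: float,
    seed,
    icp_max_iter: int = 200,
    icp_tol: float = 1e-4,
) -> tuple[RigidTransform, np.ndarray, np.ndarray]:
    """One simulated acquisition-and-registration trial.

    Perturbs the selected features, registers them back onto the unperturbed
    full model (landmark fit with known pairing for ``method='bifurcation'``;
    ICP from identity for ``method='centreline'``), applies the recovered
    transform to *all* bifurcations of the model, and returns
    ``(transform, per-bifurcation TRE, picked feature points)``.
    With sigma = 0 the recovered transform is the identity and all TREs are
    zero for both methods.
    """
    subset_idx = np.asarray(subset_idx, dtype=int)
    if len(subset_idx) < 3:
        raise ValueError("subset must select at least 3 bifurcations")
    bifs = tree.bifurcations

    if method == "bifurcation":
        picked = bifs[subset_idx]
        displaced = perturb_points(picked, sigma, seed)
        t = fit_rigid_landmarks(displaced, picked).transform
    elif method == "centreline":
        branch_ids = neighbouring_branches(tree, subset_idx)
        sub = VascularTree(
            [tree.branches[i] for i in branch_ids], bifs[subset_idx]
        )
        picked = sub.points
        displaced_tree = perturb_branches(sub, sigma, seed)
        res = icp(
            displaced_tree.points,
            tree.points,
            init=RigidTransform.identity(),
            max_iter=icp_max_iter,
            tol=icp_tol,
        )
        t = res.transform
    else:
        raise ValueError(f"unknown method {method!r}")

    moved = t.apply(bifs)
    tre = np.linalg.norm(moved - bifs, axis=1)
    return t, tre, picked


def working_radius(picked, bifurcations, tre, threshold: float) -> float:
    """Largest radius around the picked centre with all TREs under threshold.

    The centre is the centroid of the picked feature points.  Bifurcations
    are sorted by distance from the centre and scanned outward; the radius
    returned is the distance of the farthest bifurcation in the compliant
    prefix (0 if the nearest bifurcation already violates the threshold).
    """
    picked = as_points(picked, name="picked")
    bifs = as_points(bifurcations, name="bifurcations")
    tre = np.asarray(tre, dtype=float)
    if len(tre) != len(bifs):
        raise ValueError("tre must pair with bifurcations")
    centre = picked.mean(axis=0)
    dist = np.linalg.norm(bifs - centre, axis=1)
    order = np.argsort(dist, kind="stable")
    radius = 0.0
    for i in order:
        if tre[i] >= threshold:
            break
        radius = float(dist[i])
    return radius


def _trial_seed(master: int, method_i: int, n: int, sig_i: int, combo: int, rep: int):
    """Counter-based seed fan-out: independent, reproducible child streams."""
    return [int(master), method_i, n, sig_i, combo, rep]


def run_feature_assessment(
    tree: VascularTree, config: AssessmentConfig | None = None
) -> pd.DataFrame:
    """Full factorial experiment over method x N x sigma.

    For every method, subset size N and deviation sigma, draws
    ``n_combinations`` random bifurcation subsets and ``reps_per_sigma``
    displacement repetitions per subset, and averages the RMS TRE (over all
    model bifurcations) and the working radius.  Returns a tidy frame with
    columns ``method, N, sigma, mean_rms_tre_mm, mean_working_radius_mm,
    n_reps``.
    """
    cfg = config if config is not None else AssessmentConfig()
    rows = []
    for method_i, method in enumerate(("bifurcation", "centreline")):
        for n in cfg.n_values:
            subset_rng = np.random.default_rng([int(cfg.seed), 977, method_i, n])
            subsets = sample_bifurcation_subsets(
                tree, n, cfg.n_combinations, subset_rng
            )
            for sig_i, sigma in enumerate(cfg.sigmas):
                tres, radii = [], []
                for combo, rep in itertools.product(
                    range(cfg.n_combinations), range(cfg.reps_per_sigma)
                ):
                    seed = _trial_seed(cfg.seed, method_i, n, sig_i, combo, rep)
                    _, tre, picked = registration_trial(
                        tree,
                        subsets[combo],
                        method,
                        sigma,
                        seed,
                        icp_max_iter=cfg.icp_max_iter,
                        icp_tol=cfg.icp_tol,
                    )
                    tres.append(np.sqrt((tre**2).mean()))
                    radii.append(
                        working_radius(
                            picked, tree.bifurcations, tre, cfg.tre_threshold
                        )
                    )
                rows.append(
                    {
                        "method": method,
                        "N": n,
                        "sigma": sigma,
                        "mean_rms_tre_mm": float(np.mean(tres)),
                        "mean_working_radius_mm": float(np.mean(radii)),
                        "n_reps": len(tres),
                    }
                )
    return pd.DataFrame(rows)
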
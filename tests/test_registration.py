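"""Landmark fit, ICP, and globally optimal ICP."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from lusplan.geometry import RigidTransform
from lusplan.registration import (
    SearchConstraints,
    fit_rigid_landmarks,
    goicp,
    icp,
)

from .conftest import random_rigid_transform


class TestFitRigidLandmarks:
    def test_identity_on_equal_sets(self, rng):
        p = rng.uniform(-20, 20, (8, 3))
        res = fit_rigid_landmarks(p, p)
        assert np.allclose(res.transform.as_matrix(), np.eye(4), atol=1e-12)
        assert res.residual_rms == pytest.approx(0.0, abs=1e-12)

    def test_recovers_known_transform(self, rng):
        src = rng.uniform(-30, 30, (12, 3))
        t = random_rigid_transform(rng)
        res = fit_rigid_landmarks(src, t.apply(src))
        assert np.allclose(res.transform.rotation, t.rotation, atol=1e-9)
        assert np.allclose(res.transform.translation, t.translation, atol=1e-9)

    def test_beats_random_transforms(self, rng):
        src = rng.uniform(-30, 30, (10, 3))
        dst = src + rng.normal(0, 2.0, src.shape)
        best = fit_rigid_landmarks(src, dst).residual_rms
        for _ in range(1000):
            t = random_rigid_transform(rng, max_translation=5.0)
            rand_rms = np.sqrt(((t.apply(src) - dst) ** 2).sum(axis=1).mean())
            assert best <= rand_rms + 1e-12

    def test_equivariance_under_common_rotation(self, rng):
        src = rng.uniform(-30, 30, (9, 3))
        dst = src + rng.normal(0, 1.0, src.shape)
        q = random_rigid_transform(rng)
        base = fit_rigid_landmarks(src, dst).transform
        conj = fit_rigid_landmarks(q.apply(src), q.apply(dst)).transform
        expected = q.compose(base).compose(q.inverse())
        assert np.allclose(conj.as_matrix(), expected.as_matrix(), atol=1e-9)

    def test_too_few_points_error(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_rigid_landmarks(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_points_error(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="collinear"):
            fit_rigid_landmarks(line, line + 1.0)

    def test_proper_rotation_even_with_noise(self, rng):
        src = rng.uniform(-10, 10, (6, 3))
        dst = rng.uniform(-10, 10, (6, 3))  # unrelated: worst case
        res = fit_rigid_landmarks(src, dst)
        assert np.linalg.det(res.transform.rotation) == pytest.approx(1.0)


class TestIcp:
    def test_subset_identity_start_stays_identity(self, tree):
        pts = tree.points
        res = icp(pts[::5], pts, init=RigidTransform.identity())
        assert res.residual_rms == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(res.transform.as_matrix(), np.eye(4), atol=1e-9)

    def test_recovers_small_transform(self, tree):
        pts = tree.points
        sub = pts[::3]
        rot = Rotation.from_euler("xyz", [3, -2, 4], degrees=True).as_matrix()
        t_true = RigidTransform(rot, np.array([1.5, -1.0, 0.8]))
        # move the subset away; ICP must find the way back
        res = icp(t_true.apply(sub), pts, max_iter=200, tol=1e-6)
        recovered = res.transform.compose(t_true)
        angle = np.rad2deg(recovered.rotation_angle())
        assert angle < 0.5
        assert np.linalg.norm(recovered.translation) < 0.1

    def test_residuals_monotone_non_increasing(self, rng, tree):
        pts = tree.points
        for _ in range(20):
            sub = pts[rng.choice(len(pts), 60, replace=False)]
            sub = sub + rng.normal(0, 2.0, sub.shape)
            res = icp(sub, pts, max_iter=50, tol=0.0)
            hist = np.asarray(res.residual_history)
            assert np.all(np.diff(hist) <= 1e-9)

    def test_returns_proper_rotation(self, rng, tree):
        sub = tree.points[::7] + rng.normal(0, 3.0, tree.points[::7].shape)
        res = icp(sub, tree.points)
        assert np.linalg.det(res.transform.rotation) == pytest.approx(1.0)


class TestSearchConstraints:
    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            SearchConstraints(translation_box=[[0, 0, 0], [1, -1, 1]])

    def test_half_angle_range_checked(self):
        with pytest.raises(ValueError):
            SearchConstraints(rotation_half_angle_deg=0.0)

    def test_dict_round_trip(self):
        c = SearchConstraints(
            translation_box=[[0, 0, 0], [10, 10, 10]], rotation_half_angle_deg=60
        )
        back = SearchConstraints.from_dict(c.to_dict())
        assert np.allclose(back.translation_box, c.translation_box)
        assert back.rotation_half_angle_deg == 60


class TestGoIcp:
    def test_subset_meets_tight_threshold(self, rng):
        tgt = rng.uniform(-50, 50, (60, 3))
        src = tgt[rng.choice(60, 15, replace=False)]
        res = goicp(src, tgt, accept_mean_error=0.1)
        assert res.residual_mean <= 0.1
        assert res.converged

    def test_finds_global_alignment_of_transformed_subset(self, rng):
        tgt = rng.uniform(-50, 50, (70, 3))
        idx = rng.choice(70, 18, replace=False)
        t = random_rigid_transform(rng, max_translation=40.0)
        src = t.inverse().apply(tgt[idx])
        res = goicp(src, tgt, accept_mean_error=0.05)
        assert res.residual_mean <= 0.05
        # recovered alignment maps the source onto its true twins
        err = np.linalg.norm(res.transform.apply(src) - tgt[idx], axis=1)
        assert err.max() < 0.1

    def test_incumbent_not_worse_than_identity_icp(self, rng, tree):
        pts = tree.points
        sub = pts[rng.choice(len(pts), 40, replace=False)]
        sub = sub + rng.normal(0, 1.0, sub.shape)
        icp_res = icp(sub, pts, init=RigidTransform.identity())
        go_res = goicp(sub, pts, accept_mean_error=0.0, max_nodes=100)
        assert go_res.residual_rms <= icp_res.residual_rms + 1e-9

    def test_lower_bound_below_residual(self, rng):
        tgt = rng.uniform(-30, 30, (50, 3))
        src = tgt[:12] + rng.normal(0, 0.5, (12, 3))
        res = goicp(src, tgt, accept_mean_error=0.0, max_nodes=150)
        assert res.lower_bound <= res.residual_rms + 1e-12

    def test_proper_rotation_and_constraint_satisfaction(self, rng):
        tgt = rng.uniform(-40, 40, (60, 3))
        src = tgt[:15]
        cons = SearchConstraints(
            translation_box=[tgt.min(0) - 5, tgt.max(0) + 5],
            rotation_half_angle_deg=60.0,
        )
        res = goicp(src, tgt, accept_mean_error=0.5, constraints=cons)
        rot = res.transform.rotation
        assert np.linalg.det(rot) == pytest.approx(1.0)
        angle = np.rad2deg(
            np.linalg.norm(Rotation.from_matrix(rot).as_rotvec())
        )
        assert angle <= 60.0 + 1e-6

    def test_constrained_not_worse_than_unconstrained_on_self_data(self, rng):
        tgt = rng.uniform(-40, 40, (60, 3))
        src = tgt[rng.choice(60, 15, replace=False)]
        cons = SearchConstraints(
            translation_box=[tgt.min(0) - 5, tgt.max(0) + 5],
            rotation_half_angle_deg=60.0,  # truth (identity) is inside
        )
        free = goicp(src, tgt, accept_mean_error=0.01)
        tied = goicp(src, tgt, accept_mean_error=0.01, constraints=cons)
        assert tied.residual_rms <= free.residual_rms + 1e-6
        assert tied.nodes_expanded <= free.nodes_expanded

    def test_infeasible_box_rejected(self, rng):
        tgt = rng.uniform(-10, 10, (20, 3))
        with pytest.raises(ValueError, match="degenerate"):
            SearchConstraints(translation_box=[[0, 0, 0], [0, 0, 0]])

    def test_empty_source_rejected(self, rng):
        with pytest.raises(ValueError):
            goicp(np.empty((0, 3)), rng.uniform(-1, 1, (10, 3)), 1.0)
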
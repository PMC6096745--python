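"""Sweep processing: centroid extraction, smoothing, TRE curve, R_S."""

import numpy as np
import pytest

from lusplan.geometry import RigidTransform, VascularTree, nearest_distances
from lusplan.planning import UniquenessMap
from lusplan.sweep import (
    SweepFrame,
    TrackedSweep,
    TreCurve,
    extract_sweep_centrelines,
    probe_contact_position,
    reference_standard,
    smooth_sweep,
    success_radius,
)
from lusplan.synthetic import SweepGenParams, generate_surface, simulate_sweep

from .conftest import random_rigid_transform


def _sweep_from_masks(masks, spacing=(1.0, 1.0)):
    frames = [SweepFrame(m, RigidTransform.identity(), spacing) for m in masks]
    lm = np.zeros((3, 3))
    lm[1, 0] = lm[2, 1] = 1.0
    return TrackedSweep(frames, np.zeros((len(masks), 3)), lm, lm)


class TestExtraction:
    def test_single_square_component_centroid(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[19:22, 9:12] = True  # 3x3 block centred at (v=20, u=10)
        pts, fids = extract_sweep_centrelines(_sweep_from_masks([mask]))
        assert np.allclose(pts, [[10.0, 20.0, 0.0]])
        assert np.array_equal(fids, [0])

    def test_two_components_two_points(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:8, 5:8] = True
        mask[30:33, 30:33] = True
        pts, _ = extract_sweep_centrelines(_sweep_from_masks([mask]))
        assert len(pts) == 2

    def test_specks_discarded(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[3, 3] = True  # 1-pixel speck
        mask[20:25, 20:25] = True
        pts, _ = extract_sweep_centrelines(_sweep_from_masks([mask]))
        assert len(pts) == 1

    def test_pixel_spacing_applied(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[19:22, 9:12] = True
        pts, _ = extract_sweep_centrelines(
            _sweep_from_masks([mask], spacing=(2.0, 0.5))
        )
        assert np.allclose(pts, [[20.0, 10.0, 0.0]])

    def test_all_empty_sweep_errors(self):
        masks = [np.zeros((10, 10), dtype=bool)]
        with pytest.raises(ValueError, match="no vessel"):
            extract_sweep_centrelines(_sweep_from_masks(masks))

    def test_tube_phantom_centroids_on_axis(self):
        # straight tube along x at liver scale, swept perpendicular
        axis = np.column_stack(
            [np.linspace(-40, 40, 60), np.zeros(60), np.full(60, -20.0)]
        )
        tube = VascularTree([axis], np.empty((0, 3)))
        surf = generate_surface((60.0, 50.0, 40.0), n_vertices=400, seed=0)
        path = np.column_stack(
            [np.linspace(-30, 30, 25), np.zeros(25), np.full(25, 40.0)]
        )
        sweep, truth = simulate_sweep(
            tube, surf, SweepGenParams(path=path, frame_count=25, seed=3)
        )
        pts, _ = extract_sweep_centrelines(sweep)
        # distance to the continuous axis (resample finely)
        fine = np.column_stack(
            [np.linspace(-40, 40, 4000), np.zeros(4000), np.full(4000, -20.0)]
        )
        d = nearest_distances(pts, fine)
        assert np.sqrt((d**2).mean()) <= 0.5


class TestSmoothing:
    def test_jitter_free_sweep_nearly_unchanged(self, rng):
        ref = np.column_stack(
            [np.linspace(0, 50, 20), np.linspace(0, 5, 20), np.zeros(20)]
        )
        pts = ref + rng.uniform(-1, 1, ref.shape) * 0  # exactly on path
        out = smooth_sweep(pts, np.arange(20), ref)
        assert np.allclose(out, pts, atol=1e-6)

    def test_jitter_reduced_towards_truth(self, rng):
        n = 40
        truth_ref = np.column_stack(
            [np.linspace(0, 80, n), 10 * np.sin(np.linspace(0, 2, n)), np.zeros(n)]
        )
        jitter = rng.normal(0, 1.0, truth_ref.shape)
        noisy_ref = truth_ref + jitter
        truth_pts = truth_ref + np.array([0.0, 5.0, -10.0])
        noisy_pts = truth_pts + jitter  # points jittered with their frames
        out = smooth_sweep(noisy_pts, np.arange(n), noisy_ref)
        err_before = np.linalg.norm(noisy_pts - truth_pts, axis=1)
        err_after = np.linalg.norm(out - truth_pts, axis=1)
        assert np.sqrt((err_after**2).mean()) < np.sqrt((err_before**2).mean())

    def test_count_and_frame_association_preserved(self, rng):
        ref = rng.uniform(-10, 10, (8, 3))
        pts = rng.uniform(-10, 10, (20, 3))
        fids = rng.integers(0, 8, 20)
        out = smooth_sweep(pts, fids, ref)
        assert out.shape == pts.shape

    def test_too_few_frames_warns_and_passes_through(self, rng):
        pts = rng.uniform(-1, 1, (6, 3))
        ref = rng.uniform(-1, 1, (3, 3))
        with pytest.warns(UserWarning, match="fewer than 4"):
            out = smooth_sweep(pts, np.zeros(6, dtype=int), ref)
        assert np.array_equal(out, pts)


class TestProbeContact:
    def test_single_point(self):
        assert np.allclose(probe_contact_position([[1.0, 2.0, 3.0]]), [1, 2, 3])

    def test_two_point_mean(self):
        p = probe_contact_position([[0.0, 0, 0], [2.0, 0, 0]])
        assert np.allclose(p, [1.0, 0, 0])

    def test_mean_minimises_squared_distance(self, rng):
        pts = rng.uniform(-10, 10, (15, 3))
        p = probe_contact_position(pts)
        best = ((pts - p) ** 2).sum()
        for _ in range(1000):
            cand = p + rng.normal(0, 3.0, 3)
            assert best <= ((pts - cand) ** 2).sum() + 1e-9


class TestSuccessRadius:
    def _curve(self, radii, tre):
        return TreCurve(np.asarray(radii, float), np.asarray(tre, float),
                        [None] * len(radii))

    def test_flattening_tail(self):
        c = self._curve([10, 20, 30, 40, 50], [40.0, 20.0, 3.0, 2.9, 3.0])
        assert success_radius(c) == 30.0

    def test_constant_curve_first_radius(self):
        c = self._curve([10, 20, 30], [2.0, 2.0, 2.0])
        assert success_radius(c) == 10.0

    def test_late_spike_is_failure(self):
        c = self._curve([10, 20, 30, 40], [5.0, 2.0, 2.1, 40.0])
        assert success_radius(c) is None

    def test_high_stable_minimum_fails_sanity_cap(self):
        c = self._curve([10, 20, 30], [80.0, 75.0, 76.0])
        assert success_radius(c) is None

    def test_undefined_entries_skipped(self):
        c = self._curve([10, 20, 30, 40], [np.nan, np.nan, 3.0, 3.1])
        assert success_radius(c) == 30.0

    def test_all_undefined_is_failure(self):
        c = self._curve([10, 20], [np.nan, np.nan])
        assert success_radius(c) is None


class TestReferenceStandard:
    def _map(self):
        pos = np.array([[0.0, 0, 50.0], [40.0, 0, 50.0]])
        return UniquenessMap(pos, np.array([30.0, 60.0]))

    def _sweep(self, lm_lus, lm_ct):
        frame = SweepFrame(
            np.ones((8, 8), dtype=bool), RigidTransform.identity(), (1.0, 1.0)
        )
        return TrackedSweep([frame], np.zeros((4, 3)), lm_lus, lm_ct)

    def test_aligned_landmarks_identity(self, rng):
        lm = rng.uniform(-20, 20, (5, 3))
        sweep = self._sweep(lm, lm)
        t, e_r, p_r, r_u, d_r = reference_standard(sweep, self._map(), [1.0, 2, 3])
        assert np.allclose(t.as_matrix(), np.eye(4), atol=1e-9)
        assert e_r == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(p_r, [1, 2, 3])

    def test_known_transform_recovered_and_nearest_sample_used(self, rng):
        lm = rng.uniform(-20, 20, (6, 3))
        truth = random_rigid_transform(rng, max_translation=20.0)
        sweep = self._sweep(lm, truth.apply(lm))
        p = np.array([5.0, 0.0, 0.0])
        t, e_r, p_r, r_u, d_r = reference_standard(sweep, self._map(), p)
        assert np.allclose(t.as_matrix(), truth.as_matrix(), atol=1e-9)
        assert np.allclose(p_r, truth.apply(p[None])[0])
        # nearest-sample lookup equals exhaustive search
        samples = self._map().sample_positions
        dists = np.linalg.norm(samples - p_r, axis=1)
        assert d_r == pytest.approx(dists.min())
        assert r_u == self._map().r_u[np.argmin(dists)]

    def test_too_few_landmarks_rejected(self, rng):
        lm = rng.uniform(-5, 5, (2, 3))
        frame = SweepFrame(
            np.ones((4, 4), dtype=bool), RigidTransform.identity(), (1.0, 1.0)
        )
        sweep = TrackedSweep([frame], np.zeros((4, 3)), lm, lm)
        with pytest.raises(ValueError, match="3 landmark"):
            reference_standard(sweep, self._map(), np.zeros(3))
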
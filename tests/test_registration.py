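"""Vessel landmarks, rigid estimation and mask warping."""

import warnings

import numpy as np
import pytest

from fafseg.metrics import evaluate_pair
from fafseg.registration import (
    RigidTransform,
    RigidVesselRegistration,
    detect_vessel_landmarks,
    estimate_rigid,
    image_center,
    register_pair,
    warp_mask,
)
from fafseg.synthetic import SceneSpec, generate_scene, simulate_followup_acquisition


def draw_line(img, p0, p1, value=0.1, width=1):
    n = int(max(abs(p1[0] - p0[0]), abs(p1[1] - p0[1])) * 2) + 1
    for s in np.linspace(0, 1, n):
        r = p0[0] * (1 - s) + p1[0] * s
        c = p0[1] * (1 - s) + p1[1] * s
        r0, r1 = int(round(r)) - width, int(round(r)) + width
        c0, c1 = int(round(c)) - width, int(round(c)) + width
        img[max(r0, 0):r1 + 1, max(c0, 0):c1 + 1] = value


class TestLandmarkDetection:
    def test_single_straight_vessel_has_no_junctions(self):
        img = np.full((96, 96), 0.6)
        draw_line(img, (10, 48), (90, 48))
        lm = detect_vessel_landmarks(img)
        assert len(lm) == 0

    def test_y_junction_found_at_known_location(self):
        img = np.full((96, 128), 0.6)
        draw_line(img, (40, 60), (90, 60))          # stem
        draw_line(img, (40, 60), (8, 30))           # left arm
        draw_line(img, (40, 60), (8, 95))           # right arm
        lm = detect_vessel_landmarks(img)
        d = np.linalg.norm(lm.points - np.array([40, 60]), axis=1)
        assert (d < 3).sum() == 1
        assert len(lm) == 1

    def test_x_crossing_classified_as_crossover(self):
        img = np.full((96, 96), 0.6)
        draw_line(img, (10, 10), (85, 85))
        draw_line(img, (10, 85), (85, 10))
        lm = detect_vessel_landmarks(img)
        assert len(lm) == 1
        assert lm.kinds[0] == "crossover"
        assert np.linalg.norm(lm.points[0] - np.array([47.5, 47.5])) < 3

    def test_vessel_free_image_warns_and_returns_empty(self):
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            lm = detect_vessel_landmarks(np.full((80, 80), 0.6))
        assert len(lm) == 0
        assert any("vessel" in str(x.message) for x in w)

    def test_landmarks_inside_bounds_on_scene(self, small_scene):
        lm = detect_vessel_landmarks(small_scene.image_t0)
        assert len(lm) >= 3
        assert (lm.points >= 0).all()
        assert (lm.points[:, 0] < 128).all() and (lm.points[:, 1] < 128).all()
        # no duplicates
        d = np.linalg.norm(lm.points[:, None] - lm.points[None], axis=-1)
        assert (d[np.triu_indices(len(lm), 1)] > 1.0).all()


def random_points(rng, n=10, lo=10, hi=110):
    return rng.uniform(lo, hi, size=(n, 2))


class TestEstimateRigid:
    def test_identity_on_equal_sets(self, rng):
        pts = random_points(rng)
        tf = estimate_rigid(pts, pts, center=(60, 60))
        assert abs(tf.theta_deg) < 1e-6
        assert np.allclose(tf.t, 0, atol=1e-6)

    def test_exact_recovery_of_known_transform(self, rng):
        pts = random_points(rng)
        true = RigidTransform(5.0, (10.0, -4.0), center=(60, 60))
        tf = estimate_rigid(pts, true.apply(pts), center=(60, 60))
        assert abs(tf.theta_deg - 5.0) < 0.1
        assert np.allclose(tf.t, (10.0, -4.0), atol=0.1)
        assert tf.residual_rms < 1e-6

    def test_recovery_under_jitter_monte_carlo(self):
        # 0.5 px landmark jitter: 95th-percentile errors within 0.5 deg / 1 px
        errs = []
        for seed in range(100):
            g = np.random.default_rng(seed)
            pts = random_points(g, n=12)
            true = RigidTransform(float(g.uniform(-8, 8)),
                                  tuple(g.uniform(-15, 15, 2)), center=(60, 60))
            noisy = true.apply(pts) + g.normal(0, 0.5, (12, 2))
            tf = estimate_rigid(pts, noisy, center=(60, 60), seed=seed)
            errs.append((abs(tf.theta_deg - true.theta_deg),
                         np.hypot(tf.t[0] - true.t[0], tf.t[1] - true.t[1])))
        errs = np.array(errs)
        assert np.percentile(errs[:, 0], 95) < 0.5
        assert np.percentile(errs[:, 1], 95) < 1.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            estimate_rigid(np.array([[1.0, 2.0]]), np.array([[1.0, 2.0]]))

    def test_coincident_points_rejected(self):
        pts = np.array([[30.0, 30.0]] * 5)
        with pytest.raises(ValueError):
            estimate_rigid(pts, pts, center=(30, 30))


class TestRigidTransform:
    def test_rigidity_preserves_pairwise_distances(self, rng):
        pts = random_points(rng, n=20)
        tf = RigidTransform(17.3, (5.2, -8.9), center=(64, 64))
        out = tf.apply(pts)
        d0 = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        d1 = np.linalg.norm(out[:, None] - out[None], axis=-1)
        np.testing.assert_allclose(d1, d0, rtol=1e-9, atol=1e-9)

    def test_inverse_composes_to_identity(self, rng):
        tf = RigidTransform(9.0, (4.0, -2.5), center=(50, 50))
        pts = random_points(rng)
        back = tf.inverse().apply(tf.apply(pts))
        np.testing.assert_allclose(back, pts, atol=1e-9)

    def test_json_roundtrip(self, tmp_path):
        tf = RigidTransform(3.25, (1.5, -2.75), center=(95.5, 95.5))
        path = tmp_path / "tf.json"
        tf.save(path)
        assert RigidTransform.load(path) == tf


class TestWarpMask:
    def test_identity_is_exact(self, small_scene):
        mask = small_scene.mask_t0
        tf = RigidTransform.identity(mask.shape)
        assert np.array_equal(warp_mask(mask, tf), mask)

    def test_translation_roundtrip_on_interior(self, small_scene):
        mask = small_scene.mask_t0
        ctr = image_center(mask.shape)
        fwd = RigidTransform(0.0, (5.0, 0.0), ctr)
        back = RigidTransform(0.0, (-5.0, 0.0), ctr)
        out = warp_mask(warp_mask(mask, fwd), back)
        interior = np.zeros_like(mask, dtype=bool)
        interior[6:-6, 6:-6] = True
        assert np.array_equal(out[interior], mask[interior])

    def test_90_degree_rotation_lands_at_analytic_position(self):
        mask = np.zeros((64, 64), dtype=np.uint8)
        mask[10:20, 30:40] = 1
        tf = RigidTransform(90.0, (0.0, 0.0), center=image_center((64, 64)))
        out = warp_mask(mask, tf)
        expected = np.zeros_like(mask)
        # (dr, dc) -> (-dc, dr) about centre (31.5, 31.5), computed by hand:
        # rows 10..19 -> cols 10..19, cols 30..39 -> rows 33..24
        expected[24:34, 10:20] = 1
        assert np.array_equal(out, expected)

    def test_non_binary_mask_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            warp_mask(np.full((8, 8), 3), RigidTransform.identity((8, 8)))


class TestEndToEndRecovery:
    def test_scene_recovery_small_sample(self):
        hits = 0
        n = 8
        for k in range(n):
            g = np.random.default_rng(500 + k)
            b = generate_scene(SceneSpec(canvas_size=(192, 192), seed=600 + k))
            true = RigidTransform(float(g.uniform(-10, 10)),
                                  tuple(g.uniform(-20, 20, 2)),
                                  image_center((192, 192)))
            img_mv, mask_mv = simulate_followup_acquisition(
                b, true, noise_sigma=0.02, seed=k)
            tf, warped = register_pair(b.image_t0, img_mv, mask_mv, seed=k)
            inv = true.inverse()
            ok = (abs(tf.theta_deg - inv.theta_deg) < 0.5
                  and np.hypot(tf.t[0] - inv.t[0], tf.t[1] - inv.t[1]) < 1.0
                  and evaluate_pair(warped, b.mask_t12).dice >= 0.95)
            hits += ok
        assert hits >= n - 1

    def test_estimator_wrapper_matches_function(self, small_scene):
        b = generate_scene(SceneSpec(canvas_size=(192, 192), seed=900))
        true = RigidTransform(4.0, (6.0, -3.0), image_center((192, 192)))
        img_mv, mask_mv = simulate_followup_acquisition(b, true, 0.0, seed=0)
        reg = RigidVesselRegistration(seed=0).fit(b.image_t0, img_mv)
        warped = reg.transform(mask_mv)
        assert evaluate_pair(warped, b.mask_t12).dice >= 0.95
        inv = true.inverse()
        assert abs(reg.transform_.theta_deg - inv.theta_deg) < 0.5
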
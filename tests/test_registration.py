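import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from contourreg.geometry import InputError, compute_normals
from contourreg.matching import Correspondence, CorrespondenceSet
from contourreg.registration import (
    DegenerateSampleError,
    RansacParams,
    RigidTransform,
    dense_rmse,
    estimate_rigid,
    evaluate_registration,
    marker_alignment_tre,
    normal_test,
    ransac_rigid,
    refine_icp,
)


def random_transform(rng) -> RigidTransform:
    return RigidTransform(Rotation.random(random_state=rng).as_matrix(),
                          rng.uniform(-50, 50, 3))


def rotation_angle_deg(R1, R2) -> float:
    cosang = (np.trace(R1.T @ R2) - 1) / 2
    return float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))


class TestEstimateRigid:
    def test_identity(self):
        pts = np.random.default_rng(0).uniform(-10, 10, (8, 3))
        tf = estimate_rigid(pts, pts)
        np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(tf.translation, 0.0, atol=1e-12)

    def test_exact_recovery(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            src = rng.uniform(-100, 100, (6, 3))
            truth = random_transform(rng)
            tf = estimate_rigid(src, truth.apply(src))
            resid = np.linalg.norm(tf.apply(src) - truth.apply(src), axis=1)
            assert resid.max() < 1e-9

    def test_collinear_rejected(self):
        pts = np.outer([0.0, 1.0, 2.0], [1.0, 1.0, 0.0])
        with pytest.raises(DegenerateSampleError):
            estimate_rigid(pts, pts + 1.0)

    def test_no_reflection(self):
        rng = np.random.default_rng(2)
        src = rng.uniform(-10, 10, (5, 3))
        dst = src * [-1, 1, 1]  # mirrored target
        tf = estimate_rigid(src, dst)
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_beats_exhaustive_rotation_grid(self):
        # planar 4-point toy: closed form must beat a 1-degree brute force
        src = np.array([[0, 0, 0], [10, 0, 0], [10, 10, 0], [0, 10, 0.0]])
        rng = np.random.default_rng(3)
        ang = rng.uniform(0, 2 * np.pi)
        Rz = Rotation.from_euler("z", ang).as_matrix()
        dst = src @ Rz.T + [5.0, -3.0, 0.0]
        dst += rng.normal(scale=0.1, size=dst.shape)  # slight noise
        tf = estimate_rigid(src, dst)
        best_grid = np.inf
        for deg in range(360):
            Rg = Rotation.from_euler("z", deg, degrees=True).as_matrix()
            t = dst.mean(0) - Rg @ src.mean(0)
            best_grid = min(best_grid,
                            ((src @ Rg.T + t - dst) ** 2).sum())
        assert ((tf.apply(src) - dst) ** 2).sum() <= best_grid + 1e-9


class TestNormalTest:
    def test_identical_normals_pass(self):
        n = np.array([[0, 0, 1.0], [1.0, 0, 0]])
        assert normal_test(n, n, RigidTransform.identity(), a_normals=1.0)

    def test_perpendicular_fail_at_60(self):
        nm = np.array([[0, 0, 1.0]])
        nt = np.array([[1.0, 0, 0]])
        assert not normal_test(nm, nt, RigidTransform.identity(), 60.0)

    @pytest.mark.parametrize("angle,expected", [(59.9, True), (60.1, False)])
    def test_threshold_boundary(self, angle, expected):
        a = np.deg2rad(angle)
        nm = np.array([[0.0, 0.0, 1.0]])
        nt = np.array([[np.sin(a), 0.0, np.cos(a)]])
        assert normal_test(nm, nt, RigidTransform.identity(), 60.0) is expected

    def test_rotation_applied_to_moving_normals(self):
        R90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        tf = RigidTransform(R90, np.zeros(3))
        nm = np.array([[1.0, 0.0, 0.0]])
        nt = np.array([[0.0, 1.0, 0.0]])  # = R90 @ nm
        assert normal_test(nm, nt, tf, 5.0)

    def test_zero_normals_skipped_with_warning(self):
        nm = np.array([[0.0, 0.0, 0.0], [0, 0, 1.0]])
        nt = np.array([[1.0, 0.0, 0.0], [0, 0, 1.0]])
        with pytest.warns(UserWarning):
            assert normal_test(nm, nt, RigidTransform.identity(), 10.0)


def make_cset(n):
    return CorrespondenceSet([Correspondence(i, i, 1.0) for i in range(n)],
                             stage="inliers")


class TestRansac:
    def test_clean_case_accepted(self):
        rng = np.random.default_rng(0)
        src = rng.uniform(-50, 50, (12, 3))
        truth = random_transform(rng)
        dst = truth.apply(src)
        res = ransac_rigid(make_cset(12), src, dst,
                           params=RansacParams(seed=1))
        assert res.accepted and not res.fallback
        assert res.rmse < 1e-9
        err = np.linalg.norm(res.transform.apply(src) - dst, axis=1)
        assert err.max() < 1e-9

    def test_gross_outliers_rejected(self):
        rng = np.random.default_rng(1)
        src = rng.uniform(-50, 50, (13, 3))
        for seed in range(20):
            truth = random_transform(rng)
            dst = truth.apply(src)
            dst[10:] += 50.0  # three gross outliers
            res = ransac_rigid(make_cset(13), src, dst,
                               params=RansacParams(seed=seed))
            assert rotation_angle_deg(res.transform.rotation,
                                      truth.rotation) < 1.0
            assert np.linalg.norm(res.transform.translation
                                  - truth.translation) < 1.0

    def test_fallback_when_nothing_fits(self):
        rng = np.random.default_rng(2)
        src = rng.uniform(-50, 50, (10, 3))
        dst = rng.uniform(-50, 50, (10, 3))  # unrelated: no rigid fit
        res = ransac_rigid(make_cset(10), src, dst,
                           params=RansacParams(seed=0, d_ransac=0.5))
        assert res.fallback and not res.accepted

    def test_too_few_correspondences(self):
        src = np.zeros((2, 3))
        with pytest.raises(InputError, match="Relax"):
            ransac_rigid(make_cset(2), src, src)

    def test_success_monotone_in_inlier_fraction(self):
        rng = np.random.default_rng(3)
        n = 20
        src = rng.uniform(-50, 50, (n, 3))
        truth = random_transform(rng)
        rates = []
        for frac in (0.4, 0.6, 0.8):
            wins = 0
            for seed in range(50):
                dst = truth.apply(src)
                n_out = int(round((1 - frac) * n))
                out = rng.choice(n, n_out, replace=False)
                dst[out] += rng.uniform(20, 80, (n_out, 3))
                res = ransac_rigid(
                    make_cset(n), src, dst,
                    params=RansacParams(seed=seed, max_iterations=40))
                if rotation_angle_deg(res.transform.rotation,
                                      truth.rotation) < 2.0:
                    wins += 1
            rates.append(wins / 50)
        assert rates[0] <= rates[1] <= rates[2]

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        src = rng.uniform(-50, 50, (10, 3))
        dst = random_transform(rng).apply(src)
        dst[7:] += 40.0
        a = ransac_rigid(make_cset(10), src, dst,
                         params=RansacParams(seed=9))
        b = ransac_rigid(make_cset(10), src, dst,
                         params=RansacParams(seed=9))
        np.testing.assert_array_equal(a.transform.as_matrix(),
                                      b.transform.as_matrix())


class TestICP:
    def test_fixed_point_when_aligned(self, sphere_mm):
        init = RigidTransform.identity()
        tf = refine_icp(sphere_mm, sphere_mm, init, tol=1e-6)
        assert np.abs(tf.as_matrix() - np.eye(4)).max() < 1e-6

    def test_recovers_small_perturbation(self, sphere_mm):
        rng = np.random.default_rng(0)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        Rp = Rotation.from_rotvec(axis * np.deg2rad(5)).as_matrix()
        pert = RigidTransform(Rp, np.array([5.0, -2.0, 3.0]))
        # moving = perturbed copy; target = original; start from identity
        moved = pert.apply(sphere_mm.vertices)
        tf = refine_icp(moved, sphere_mm, RigidTransform.identity(),
                        max_iter=100, tol=1e-6)
        final = np.linalg.norm(tf.apply(moved) - sphere_mm.vertices, axis=1)
        assert final.mean() < 0.5

    def test_never_worse_than_init(self, sphere_mm):
        rng = np.random.default_rng(1)
        pert = RigidTransform(
            Rotation.from_euler("y", 8, degrees=True).as_matrix(),
            np.array([4.0, 4.0, -6.0]))
        moved = pert.apply(sphere_mm.vertices)
        init = RigidTransform.identity()
        before = dense_rmse(moved, sphere_mm.vertices, init)
        tf = refine_icp(moved, sphere_mm, init)
        after = dense_rmse(moved, sphere_mm.vertices, tf)
        assert after <= before + 1e-9


class TestEvaluation:
    def test_perfect_transform_zero_error(self):
        pts = np.random.default_rng(0).uniform(-10, 10, (20, 3))
        m = evaluate_registration(RigidTransform.identity(), pts, pts)
        assert m["mean_mm"] == 0.0

    def test_pure_translation_offset(self):
        pts = np.random.default_rng(0).uniform(-10, 10, (20, 3))
        tf = RigidTransform(np.eye(3), [5.0, 0, 0])
        m = evaluate_registration(tf, pts, pts)
        assert m["mean_mm"] == pytest.approx(5.0)
        assert m["std_mm"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_distances(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(-10, 10, (15, 3))
        truth = rng.uniform(-10, 10, (15, 3))
        tf = random_transform(rng)
        m = evaluate_registration(tf, pts, truth)
        brute = [np.sqrt(((tf.rotation @ p + tf.translation - q) ** 2).sum())
                 for p, q in zip(pts, truth)]
        np.testing.assert_allclose(m["per_point_mm"], brute, rtol=1e-12)

    def test_empty_ground_truth(self):
        with pytest.raises(InputError):
            evaluate_registration(RigidTransform.identity(),
                                  np.empty((0, 3)), np.empty((0, 3)))

    def test_marker_tre_synthetic_deformation(self):
        # synthetic stand-in for a marker-implanted deforming phantom:
        # rigid motion plus a known non-rigid residual of ~2 mm per marker
        rng = np.random.default_rng(6)
        markers = rng.uniform(-60, 60, (12, 3))
        truth = random_transform(rng)
        resid = rng.normal(scale=2.0, size=(12, 3))
        resid -= resid.mean(axis=0)
        after = truth.apply(markers) + resid
        m = marker_alignment_tre(markers, after)
        # best-case rigid TRE is of the order of the injected non-rigidity
        assert 0.5 < m["mean_mm"] < 2.0 * np.sqrt(3) * 2.0

    def test_transform_json_roundtrip(self, tmp_path):
        tf = random_transform(np.random.default_rng(7))
        path = tmp_path / "t.json"
        tf.to_json(path, rmse_mm=1.0)
        back = RigidTransform.from_json(path)
        np.testing.assert_allclose(back.as_matrix(), tf.as_matrix(),
                                   atol=1e-12)
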
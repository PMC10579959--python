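"""Rigid transforms, correspondence search, the point-to-plane solver and
the full ICP loop."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from atrialign.exceptions import (
    DegenerateNormalsError,
    NonOverlappingCloudsError,
)
from atrialign.phantom import (
    AcquisitionParams,
    random_rigid_transform,
    simulate_acquisition,
)
from atrialign.registration import (
    IcpConfig,
    RigidTransform,
    apply_transform,
    find_correspondences,
    icp_point_to_plane,
    initialize_transform,
    point_to_plane_cost,
    solve_point_to_plane,
)
from atrialign.surface_io import LabeledSurface, estimate_normals


class TestRigidTransform:
    def test_rejects_non_rotation(self):
        with pytest.raises(ValueError):
            RigidTransform(np.eye(3) * 2, np.zeros(3))
        with pytest.raises(ValueError, match="determinant"):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_compose_and_inverse_closed(self, rng):
        a = random_rigid_transform(170, 50, 1)
        b = random_rigid_transform(170, 50, 2)
        c = a @ b
        ident = c @ c.inverse()
        assert np.allclose(ident.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(ident.translation, 0, atol=1e-9)

    def test_matrix_roundtrip_via_file(self, tmp_path):
        t = random_rigid_transform(30, 10, 5)
        t.save(tmp_path / "t.txt")
        back = RigidTransform.load(tmp_path / "t.txt")
        assert np.allclose(back.as_matrix(), t.as_matrix(), atol=1e-12)

    def test_apply_preserves_pairwise_distances(self, rng):
        pts = rng.uniform(-30, 30, size=(40, 3))
        s = LabeledSurface(pts)
        t = random_rigid_transform(120, 40, 9)
        out = apply_transform(s, t)
        d_in = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        d_out = np.linalg.norm(
            out.vertices[:, None] - out.vertices[None], axis=-1
        )
        assert np.allclose(d_in, d_out, atol=1e-9)
        assert np.array_equal(out.labels, s.labels)

    def test_involution_and_inverse_roundtrip(self, rng):
        pts = rng.uniform(-10, 10, size=(20, 3))
        half_turn = RigidTransform(
            Rotation.from_euler("z", 180, degrees=True).as_matrix(), np.zeros(3)
        )
        twice = half_turn @ half_turn
        assert np.allclose(twice.apply(pts), pts, atol=1e-9)
        t = random_rigid_transform(60, 20, 11)
        assert np.allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-9)


class TestCorrespondences:
    def test_identity_pairs_at_zero(self, rng):
        pts = rng.uniform(0, 10, size=(30, 3))
        midx, fidx, d = find_correspondences(pts, pts)
        assert np.array_equal(midx, fidx)
        assert np.allclose(d, 0)

    def test_shifted_lattice_all_distances_one(self):
        xs, ys = np.meshgrid(np.arange(6), np.arange(6))
        pts = np.column_stack(
            [2.0 * xs.ravel(), 2.0 * ys.ravel(), np.zeros(36)]
        )
        shifted = pts + [1.0, 0, 0]
        # oracle: exhaustive pairwise scan
        full = np.linalg.norm(shifted[:, None] - pts[None], axis=-1)
        expected = full.min(axis=1)
        _, _, d = find_correspondences(shifted, pts)
        assert np.allclose(d, expected)
        assert np.allclose(d, 1.0)

    def test_median_factor_rejects_outlier(self, rng):
        inliers = rng.uniform(0, 5, size=(10, 3))
        moving = np.vstack([inliers + 0.01, [[100.0, 100, 100]]])
        midx, _, d = find_correspondences(
            moving, inliers, rejection_distance_factor=3.0,
            min_correspondences=6,
        )
        med = np.median(
            np.linalg.norm(moving[:, None] - inliers[None], axis=-1).min(1)
        )
        assert len(midx) == 10
        assert (d <= 3.0 * med).all()

    def test_non_overlapping_clouds_error(self):
        a = np.zeros((8, 3)) + np.arange(8)[:, None]
        with pytest.raises(NonOverlappingCloudsError):
            find_correspondences(a, a + 1000, min_correspondences=50)


def _cost_fn(params, p, q, n):
    t = RigidTransform(Rotation.from_rotvec(params[:3]).as_matrix(), params[3:])
    return point_to_plane_cost(p, q, n, t)


class TestPointToPlaneSolver:
    def test_zero_residual_gives_identity(self, rng):
        p = rng.uniform(-10, 10, size=(20, 3))
        n = rng.normal(size=(20, 3))
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        t = solve_point_to_plane(p, p, n)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-8)
        assert np.allclose(t.translation, 0, atol=1e-8)

    def test_pure_normal_translation_recovered_exactly(self, rng):
        # plane z=0 shifted 2 mm along its own normal: closed form says the
        # optimal transform moves points by exactly the mean normal residual
        p = np.column_stack(
            [rng.uniform(-10, 10, 30), rng.uniform(-10, 10, 30), np.zeros(30)]
        )
        q = p + [0, 0, 2.0]
        n = np.tile([0.0, 0, 1], (30, 1))
        t = solve_point_to_plane(p, q, n)
        moved = t.apply(p)
        assert np.allclose(moved[:, 2], 2.0, atol=1e-12)
        assert point_to_plane_cost(p, q, n, t) < 1e-20

    def test_matches_bruteforce_minimizer_on_sphere(self, rng):
        dirs = rng.normal(size=(50, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        p = 30.0 * dirs
        truth = RigidTransform(
            Rotation.from_rotvec(np.radians(3.0) * np.array([0, 0, 1.0])).as_matrix(),
            np.array([0.5, -0.3, 0.2]),
        )
        q = truth.apply(p)
        normals = q / np.linalg.norm(q, axis=1, keepdims=True)  # fixed side
        t = solve_point_to_plane(p, q, normals)
        ours = point_to_plane_cost(p, q, normals, t)
        res = minimize(
            _cost_fn, np.zeros(6), args=(p, q, normals), method="Powell",
            options={"xtol": 1e-12, "ftol": 1e-14, "maxiter": 20000},
        )
        assert ours <= res.fun + 1e-6

    def test_never_worse_than_identity(self, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            p = r.uniform(-20, 20, size=(40, 3))
            q = p + r.normal(0, 1.0, size=(40, 3))
            n = r.normal(size=(40, 3))
            n /= np.linalg.norm(n, axis=1, keepdims=True)
            t = solve_point_to_plane(p, q, n)
            assert point_to_plane_cost(p, q, n, t) <= point_to_plane_cost(
                p, q, n
            ) + 1e-12

    def test_parallel_normals_with_misfit_degenerate(self, rng):
        # all normals parallel, residuals not explainable by any rigid
        # motion: sliding/rotation in the plane is genuinely undetermined
        p = rng.uniform(-10, 10, size=(20, 3))
        p[:, 2] = 0
        n = np.tile([0.0, 0, 1], (20, 1))
        q = p.copy()
        q[:, 2] = rng.normal(0, 1.0, 20)  # incoherent normal offsets
        with pytest.raises(DegenerateNormalsError):
            solve_point_to_plane(p, q, n)

    def test_too_few_correspondences(self, rng):
        p = rng.uniform(0, 1, size=(4, 3))
        n = np.tile([0.0, 0, 1], (4, 1))
        with pytest.raises(Exception, match="at least 6"):
            solve_point_to_plane(p, p, n)


class TestIcp:
    def test_self_alignment_is_identity(self, small_phantom):
        t, diag = icp_point_to_plane(
            small_phantom, small_phantom,
            initial=RigidTransform.identity(),
        )
        assert diag.converged
        assert diag.iterations_run == 1
        assert diag.rmse_mm[0] < 1e-9
        assert np.allclose(t.as_matrix(), np.eye(4), atol=1e-12)

    def test_known_transform_recovered(self, small_phantom):
        truth = random_rigid_transform(10.0, 5.0, 21)
        fixed = apply_transform(small_phantom, truth)
        t, diag = icp_point_to_plane(small_phantom, fixed)
        err = np.linalg.norm(
            t.apply(small_phantom.vertices) - fixed.vertices, axis=1
        )
        assert err.max() < 0.05
        assert diag.converged

    def test_max_iterations_cap(self, small_phantom):
        truth = random_rigid_transform(15.0, 8.0, 3)
        fixed = apply_transform(small_phantom, truth)
        _, diag = icp_point_to_plane(
            small_phantom, fixed, config=IcpConfig(max_iterations=3)
        )
        assert diag.iterations_run <= 3
        assert len(diag.rmse_mm) == diag.iterations_run

    def test_rmse_sequence_monotone(self, small_phantom):
        truth = random_rigid_transform(18.0, 9.0, 5)
        fixed = apply_transform(small_phantom, truth)
        _, diag = icp_point_to_plane(small_phantom, fixed)
        rmse = np.array(diag.rmse_mm)
        assert (np.diff(rmse) <= 1e-9).all()

    @pytest.mark.parametrize("seed", range(20))
    def test_capture_range_20deg_10mm(self, small_phantom, seed):
        truth = random_rigid_transform(20.0, 10.0, seed)
        fixed = apply_transform(small_phantom, truth)
        t, _ = icp_point_to_plane(small_phantom, fixed)
        err = np.linalg.norm(
            t.apply(small_phantom.vertices) - fixed.vertices, axis=1
        )
        assert err.max() < 0.1

    def test_forward_backward_are_mutual_inverses(self, small_phantom):
        truth = random_rigid_transform(12.0, 6.0, 8)
        fixed = apply_transform(small_phantom, truth)
        fwd, _ = icp_point_to_plane(small_phantom, fixed)
        bwd, _ = icp_point_to_plane(fixed, small_phantom)
        roundtrip = bwd @ fwd
        err = np.linalg.norm(
            roundtrip.apply(small_phantom.vertices) - small_phantom.vertices,
            axis=1,
        )
        assert err.max() < 0.1

    def test_pca_init_beats_centroid_beyond_capture_range(self, small_phantom):
        truth = random_rigid_transform(40.0, 15.0, 2)
        fixed = apply_transform(small_phantom, truth)
        init = initialize_transform(
            small_phantom.vertices, fixed.vertices, "centroid_pca"
        )
        t, _ = icp_point_to_plane(small_phantom, fixed, initial=init)
        err = np.linalg.norm(
            t.apply(small_phantom.vertices) - fixed.vertices, axis=1
        )
        assert err.max() < 0.1

    def test_partial_coverage_still_converges(self, small_phantom):
        truth = random_rigid_transform(10.0, 5.0, 4)
        eam = simulate_acquisition(
            small_phantom,
            AcquisitionParams(
                true_transform=truth, coverage_fraction=0.75, seed=4
            ),
        )
        t, _ = icp_point_to_plane(small_phantom, eam)
        ref = truth.apply(small_phantom.vertices)
        err = np.linalg.norm(t.apply(small_phantom.vertices) - ref, axis=1)
        assert err.max() < 0.5
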
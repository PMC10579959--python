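"""Synthetic left-atrium phantom and acquisition simulator."""

import numpy as np
import pytest
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from atrialign.exceptions import PhantomError
from atrialign.phantom import (
    AcquisitionParams,
    PhantomParams,
    _ellipsoid_area,
    expected_median_residual,
    generate_phantom,
    random_rigid_transform,
    simulate_acquisition,
)
from atrialign.surface_io import AnatomicalLabel


class TestGeneratePhantom:
    def test_deterministic_per_seed(self):
        a = generate_phantom(PhantomParams(seed=7))
        b = generate_phantom(PhantomParams(seed=7))
        assert np.array_equal(a.vertices, b.vertices)
        assert np.array_equal(a.labels, b.labels)
        c = generate_phantom(PhantomParams(seed=8))
        assert not np.array_equal(a.vertices, c.vertices)

    def test_census_contains_all_labels_body_plurality(self, phantom):
        counts = phantom.label_counts()
        assert set(counts) == set(AnatomicalLabel)
        assert counts[AnatomicalLabel.BODY] == max(counts.values())

    def test_body_vertex_count_tracks_ellipsoid_area(self, phantom):
        # oracle: Thomsen's closed-form ellipsoid area
        params = PhantomParams(seed=0)
        area = _ellipsoid_area(*params.body_semi_axes)
        n_body = sum(
            int(np.sum(phantom.labels == int(lab)))
            for lab in (AnatomicalLabel.BODY, AnatomicalLabel.MV_ANNULUS)
        )
        c = area / (n_body * params.target_spacing**2)
        assert 0.5 <= c <= 2.0

    def test_body_points_near_ellipsoid_with_irregularity(self, phantom):
        # the body is a radially modulated ellipsoid: deviations from the
        # base ellipsoid are bounded by the irregularity amplitude and are
        # actually present (a perfect ellipsoid would leave body-only
        # registration rotationally under-constrained)
        params = PhantomParams(seed=0)
        axes = np.asarray(params.body_semi_axes)
        body = phantom.vertices[phantom.labels == int(AnatomicalLabel.BODY)]
        radial = np.sqrt(np.sum((body / axes) ** 2, axis=1))
        assert np.abs(radial - 1.0).max() < 3 * params.body_irregularity
        assert radial.std() > 0.2 * params.body_irregularity

    def test_zero_irregularity_gives_exact_ellipsoid(self):
        params = PhantomParams(seed=0, body_irregularity=0.0)
        ph = generate_phantom(params)
        axes = np.asarray(params.body_semi_axes)
        body = ph.vertices[ph.labels == int(AnatomicalLabel.BODY)]
        implicit = np.sum((body / axes) ** 2, axis=1)
        assert np.allclose(implicit, 1.0, atol=1e-9)

    def test_impossible_geometry_rejected(self):
        with pytest.raises(PhantomError, match="pv_radius"):
            PhantomParams(pv_radius=15.0)
        with pytest.raises(PhantomError, match="annulus"):
            PhantomParams(annulus_radius=30.0)
        with pytest.raises(PhantomError):
            PhantomParams(pv_length=-1.0)


class TestSimulateAcquisition:
    def test_noiseless_identity_strips_labels_only(self, phantom):
        eam = simulate_acquisition(phantom, AcquisitionParams())
        assert np.allclose(eam.vertices, phantom.vertices)
        assert (eam.labels == int(AnatomicalLabel.BODY)).all()
        assert eam.source_modality == "EAM"

    def test_patch_dropout_is_contiguous(self, phantom):
        eam = simulate_acquisition(
            phantom, AcquisitionParams(coverage_fraction=0.7, seed=3)
        )
        n_dropped = phantom.n_vertices - eam.n_vertices
        assert n_dropped == round(0.3 * phantom.n_vertices)
        # the dropped vertices form a spatially coherent patch: each one
        # has another dropped vertex essentially at sampling distance,
        # unlike i.i.d. dropout which scatters them ~1.8x the spacing apart
        kept_tree = cKDTree(eam.vertices)
        d_all, _ = cKDTree(phantom.vertices).query(phantom.vertices, k=2)
        spacing = np.median(d_all[:, 1])
        d, _ = kept_tree.query(phantom.vertices)
        dropped = phantom.vertices[d > 1e-9]
        d_dd, _ = cKDTree(dropped).query(dropped, k=2)
        assert np.median(d_dd[:, 1]) < 1.3 * spacing

    def test_excessive_dropout_errors(self, phantom):
        with pytest.raises(PhantomError, match="coverage"):
            simulate_acquisition(
                phantom, AcquisitionParams(coverage_fraction=0.01)
            )

    def test_noise_median_matches_monte_carlo(self, phantom):
        # perfect alignment assumed: distance from each clean vertex to the
        # nearest noisy vertex, against the noise model's own Monte-Carlo
        medians = []
        for seed in range(5):
            eam = simulate_acquisition(
                phantom, AcquisitionParams(noise_sd=0.5, seed=seed)
            )
            d, _ = cKDTree(eam.vertices).query(phantom.vertices)
            medians.append(np.median(d))
        mc = expected_median_residual(0.5, surface=phantom, seed=99)
        assert abs(np.mean(medians) - mc) / mc < 0.15

    def test_noise_monotonically_raises_median_residual(self, phantom):
        med = []
        for sd in (0.0, 0.5, 1.0):
            vals = []
            for seed in range(3):
                eam = simulate_acquisition(
                    phantom, AcquisitionParams(noise_sd=sd, seed=seed)
                )
                d, _ = cKDTree(eam.vertices).query(phantom.vertices)
                vals.append(np.median(d))
            med.append(np.mean(vals))
        assert med[0] <= med[1] <= med[2]


class TestRandomRigidTransform:
    def test_zero_magnitudes_give_identity(self):
        t = random_rigid_transform(0.0, 0.0, 5)
        assert np.allclose(t.as_matrix(), np.eye(4))

    def test_invariants_over_seed_sweep(self):
        for seed in range(200):
            t = random_rigid_transform(25.0, 12.0, seed)
            R = t.rotation
            assert np.allclose(R.T @ R, np.eye(3), atol=1e-9)
            assert abs(np.linalg.det(R) - 1) < 1e-9
            assert t.rotation_angle_deg() <= 25.0 + 1e-9
            assert np.linalg.norm(t.translation) <= 12.0 + 1e-9

    def test_angle_matches_axis_angle_decomposition(self):
        # oracle: replicate the generator's draws, then decompose the
        # returned rotation back to axis-angle
        rng = np.random.default_rng(17)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = np.radians(rng.uniform(0.0, 30.0))
        t = random_rigid_transform(30.0, 0.0, 17)
        extracted = Rotation.from_matrix(t.rotation).magnitude()
        assert extracted == pytest.approx(angle, abs=1e-9)


class TestExpectedMedianResidual:
    def test_zero_noise_zero_residual(self):
        assert expected_median_residual(0.0, spacing=2.0) == 0.0

    def test_isolated_point_limit_is_chi3_median(self):
        # with neighbours pushed far away, the nearest noisy point is the
        # vertex's own counterpart: distance follows a chi distribution
        # with 3 dof, median sigma * 1.5382
        mc = expected_median_residual(
            0.5, spacing=1000.0, n_draws=200_000, seed=0
        )
        assert mc == pytest.approx(0.5 * 1.5382, rel=0.02)

    def test_neighbour_competition_lowers_median(self):
        dense = expected_median_residual(1.0, spacing=1.5, seed=1)
        sparse = expected_median_residual(1.0, spacing=10.0, seed=1)
        assert dense < sparse
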
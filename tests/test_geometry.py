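"""Sphere fitting, interommatidial angles, diameters and the optics formulas."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import eyemetrics as em
from eyemetrics.geometry import DegenerateSphereFitError, nearest_neighbors

from _oracles import sphere_fit_nonlinear


def sphere_points(n, center, radius, seed=0):
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return np.asarray(center) + radius * v


class TestFitSphere:
    def test_exact_recovery_on_noiseless_sphere(self):
        pts = sphere_points(60, (10.0, -5.0, 3.0), 1000.0, seed=1)
        fit = em.fit_sphere(pts)
        np.testing.assert_allclose(fit.center_um, [10, -5, 3], rtol=1e-6, atol=1e-3)
        assert fit.radius_um == pytest.approx(1000.0, rel=1e-6)

    def test_five_point_unit_sphere(self):
        pts = np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1]], float
        )
        fit = em.fit_sphere(pts)
        np.testing.assert_allclose(fit.center_um, 0.0, atol=1e-9)
        assert fit.radius_um == pytest.approx(1.0, abs=1e-9)

    def test_noisy_radius_recovery_monte_carlo(self):
        """Median recovered R within 1% over 200 noisy replicates.

        A nonlinear multistart fit serves as an independent oracle on a
        subsample of replicates.
        """
        rng = np.random.default_rng(12345)
        radii = []
        for rep in range(200):
            v = rng.normal(size=(60, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            pts = (1000.0 + rng.normal(scale=0.5, size=60))[:, None] * v
            fit = em.fit_sphere(pts)
            radii.append(fit.radius_um)
            if rep < 5:
                _, r_oracle = sphere_fit_nonlinear(pts, seed=rep)
                assert fit.radius_um == pytest.approx(r_oracle, rel=1e-4)
        assert np.median(radii) == pytest.approx(1000.0, rel=0.01)

    def test_coplanar_points_raise(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.normal(size=(30, 2)), np.zeros(30)])
        with pytest.raises(DegenerateSphereFitError):
            em.fit_sphere(pts)

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            em.fit_sphere(np.zeros((3, 3)))


class TestLocalFits:
    def test_phantom_local_fits_recover_sphere(self, small_phantom):
        _, truth = small_phantom
        centers = truth.true_centers_um
        fits, warn = em.local_sphere_fits(centers, cluster_size=60)
        assert not warn
        radii = np.array([f.radius_um for f in fits])
        np.testing.assert_allclose(radii, 1000.0, rtol=0.01)
        offsets = np.linalg.norm(
            [f.center_um - truth.true_sphere_center_um for f in fits], axis=1
        )
        assert offsets.max() < 0.02 * 1000.0

    def test_cluster_size_equal_to_n_gives_identical_fits(self):
        pts = sphere_points(30, (0, 0, 0), 500.0, seed=3)
        fits, _ = em.local_sphere_fits(pts, cluster_size=30)
        radii = {round(f.radius_um, 9) for f in fits}
        assert len(radii) == 1

    def test_global_fallback_when_too_few_centers(self):
        pts = sphere_points(20, (0, 0, 0), 500.0, seed=4)
        fits, warn = em.local_sphere_fits(pts, cluster_size=60)
        assert warn and len(fits) == 20

    def test_coplanar_cluster_propagates_degeneracy(self):
        pts = np.column_stack([np.random.default_rng(5).normal(size=(40, 2)), np.zeros(40)])
        with pytest.raises(DegenerateSphereFitError):
            em.local_sphere_fits(pts, cluster_size=40)
        fits, _ = em.local_sphere_fits(pts, cluster_size=40, on_degenerate="flag")
        assert all(f is None for f in fits)


def hex_lattice(rows, cols, spacing=1.0):
    pts = []
    for j in range(rows):
        for i in range(cols):
            pts.append((spacing * (i + 0.5 * (j % 2)), spacing * np.sqrt(3) / 2 * j, 0.0))
    return np.array(pts)


class TestNeighborMetrics:
    def test_planar_hex_lattice_interior_diameter_is_spacing(self):
        pts = hex_lattice(9, 9, spacing=2.5)
        D = em.ommatidial_diameters(pts)
        interior = np.linalg.norm(pts - pts.mean(axis=0), axis=1) < 4.0
        np.testing.assert_allclose(D[interior], 2.5, rtol=1e-9)

    def test_collinear_points_middle_diameter(self):
        s = 3.0
        pts = np.column_stack([np.arange(7) * s, np.zeros(7), np.zeros(7)])
        D = em.ommatidial_diameters(pts)
        assert D[3] == pytest.approx(2 * s)

    def test_jittered_phantom_median_diameter(self):
        spec = em.SyntheticEyeSpec(
            cap_half_angle_deg=10.0, voxel_size_um=1.0, center_jitter_um=1.0, seed=9
        )
        centers, truth = em.generate_hex_cap_centers(spec)
        D = em.ommatidial_diameters(centers)
        interior = truth.interior_mask()
        assert np.median(D[interior]) == pytest.approx(25.0, rel=0.02)

    def test_k_neighbors_exceeding_centers_raises(self):
        with pytest.raises(ValueError):
            nearest_neighbors(np.zeros((5, 3)), 5)

    def test_identical_radial_vectors_give_zero_angle(self):
        fit = em.SphereFit(np.zeros(3), 1.0, 0.0, 60)
        centers = np.array([[0, 0, 1.0], [0, 0, 2.0]])
        dphi = em.interommatidial_angles(centers, [fit, fit], k_neighbors=1)
        np.testing.assert_allclose(dphi, 0.0, atol=1e-12)

    def test_antipodal_neighbor_is_180_and_excluded(self):
        fit = em.SphereFit(np.zeros(3), 1.0, 0.0, 60)
        centers = np.array([[0, 0, 1.0], [0, 0, -1.0]])
        dphi = em.interommatidial_angles(centers, [fit, fit], k_neighbors=1)
        np.testing.assert_allclose(dphi, 180.0)
        import pandas as pd

        df = pd.DataFrame(
            {"delta_phi_deg": dphi, "R_local_um": [1.0, 1.0]}
        )
        out = em.apply_metric_filters(df)
        assert out["excluded"].all()
        assert (out["reason"] == "angle>90").all()

    def test_phantom_interommatidial_angle_recovery(self, small_phantom):
        _, truth = small_phantom
        centers = truth.true_centers_um
        fits, _ = em.local_sphere_fits(centers)
        dphi = em.interommatidial_angles(centers, fits)
        interior = truth.interior_mask()
        assert np.median(dphi[interior]) == pytest.approx(
            truth.true_interommatidial_angle_deg, rel=0.05
        )


class TestOpticsFormulas:
    @pytest.mark.parametrize(
        "D,expected", [(20.54, 1.70), (31.09, 1.12)]
    )
    def test_resolving_power_extremes(self, D, expected):
        """θ = 1.22·λ/D maps the diameter extremes onto the θ extremes (2 dp)."""
        assert round(em.resolving_power(D), 2) == expected

    def test_resolving_power_inverse_proportionality(self):
        assert em.resolving_power(50.0) == pytest.approx(em.resolving_power(25.0) / 2)

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(ValueError):
            em.resolving_power(0.0)

    def test_barlow_identity_and_paper_medians(self):
        assert em.barlow_ratio(1.5, 1.5) == 1.0
        assert em.barlow_ratio(1.66, 1.46) == pytest.approx(1.137, abs=5e-4)
        with pytest.raises(ValueError):
            em.barlow_ratio(1.0, 0.0)

    def test_barlow_unit_independence(self):
        assert em.barlow_ratio(1.66, 1.46) == pytest.approx(
            em.barlow_ratio(np.radians(1.66), np.radians(1.46))
        )

    def test_designed_phantom_has_unit_barlow(self):
        """With D² = 1.22·λ·R the sampling and diffraction angles coincide."""
        R = 1000.0
        D = np.sqrt(1.22 * 0.5 * R)
        spec = em.SyntheticEyeSpec(
            sphere_radius_um=R, lattice_spacing_um=D, cap_half_angle_deg=10.0
        )
        centers, truth = em.generate_hex_cap_centers(spec)
        m = em.compute_ommatidium_metrics(centers)
        interior = truth.interior_mask()
        ratio = m.loc[interior, "barlow_ratio"].median()
        assert ratio == pytest.approx(1.0, rel=0.05)

    def test_snyder_parameter_values_and_identity(self):
        assert em.snyder_eye_parameter(25.0, np.degrees(0.025)) == pytest.approx(0.625)
        # Barlow ratio exactly 1 -> p = 0.61 at lambda = 0.5 um
        D = 20.0
        theta = em.resolving_power(D)
        assert em.snyder_eye_parameter(D, theta) == pytest.approx(0.61, abs=1e-12)

    def test_snyder_identity_on_metrics_records(self, small_results):
        res, _ = small_results
        m = res["metrics"]
        p = m["eye_parameter_um_rad"].to_numpy()
        assert np.nanmax(np.abs(p - 0.61 * m["barlow_ratio"].to_numpy())) < 1e-9

    def test_diameter_bias_bound(self):
        assert em.diameter_bias_bound(1.66, 44.4) == pytest.approx(1.286, abs=5e-3)
        assert em.diameter_bias_bound(1.66, 44.4) < 2.0
        assert em.diameter_bias_bound(0.0, 44.4) == 0.0
        assert em.diameter_bias_bound(1.0, 88.8) == pytest.approx(
            2 * em.diameter_bias_bound(1.0, 44.4)
        )


class TestMetricsTableInvariants:
    def test_barlow_theta_identity_exact(self, small_results):
        res, _ = small_results
        m = res["metrics"]
        lhs = m["barlow_ratio"] * m["theta_deg"]
        np.testing.assert_allclose(lhs, m["delta_phi_deg"], rtol=1e-12)

    def test_theta_sort_reverses_diameter_sort(self, small_results):
        res, _ = small_results
        m = res["metrics"]
        assert list(m.sort_values("D_um").index) == list(
            m.sort_values("theta_deg", ascending=False).index
        )

    def test_rigid_motion_invariance(self):
        spec = em.SyntheticEyeSpec(cap_half_angle_deg=8.0, voxel_size_um=1.0)
        centers, _ = em.generate_hex_cap_centers(spec)
        m0 = em.compute_ommatidium_metrics(centers)
        rot = em.morphology.rotation_to_z(np.array([1.0, 1.0, 1.0]))
        moved = centers @ rot.T + np.array([100.0, -50.0, 7.0])
        m1 = em.compute_ommatidium_metrics(moved)
        for col in ("D_um", "delta_phi_deg", "theta_deg", "barlow_ratio"):
            np.testing.assert_allclose(m0[col], m1[col], rtol=1e-9, atol=1e-9)

    def test_scale_covariance(self):
        spec = em.SyntheticEyeSpec(cap_half_angle_deg=8.0, voxel_size_um=1.0)
        centers, _ = em.generate_hex_cap_centers(spec)
        s = 2.5
        m0 = em.compute_ommatidium_metrics(centers)
        m1 = em.compute_ommatidium_metrics(centers * s)
        np.testing.assert_allclose(m1["D_um"], s * m0["D_um"], rtol=1e-9)
        np.testing.assert_allclose(
            m1["delta_phi_deg"], m0["delta_phi_deg"], rtol=1e-7
        )
        np.testing.assert_allclose(
            m1["theta_deg"], em.resolving_power(s * m0["D_um"].to_numpy()), rtol=1e-12
        )

    def test_clean_phantom_interior_never_excluded(self, small_results):
        res, truth = small_results
        m = res["metrics"]
        interior = truth.interior_mask()
        assert not m.loc[interior, "excluded"].any()

    def test_displaced_center_is_flagged_or_excluded(self):
        spec = em.SyntheticEyeSpec(cap_half_angle_deg=8.0, voxel_size_um=1.0)
        centers, truth = em.generate_hex_cap_centers(spec)
        bad = int(np.argmax(truth.interior_mask()))
        centers[bad] += 200.0 * truth.true_axes[bad]
        m = em.compute_ommatidium_metrics(centers)
        assert m.loc[bad, "excluded"] or m.loc[bad, "is_edge"]
        # untouched interior cones far from the displacement stay included
        far = truth.interior_mask() & (
            np.linalg.norm(
                truth.true_centers_um - truth.true_centers_um[bad], axis=1
            )
            > 100.0
        )
        assert not m.loc[far, "excluded"].any()

    @settings(deadline=None, max_examples=25)
    @given(
        dphi=st.floats(0.01, 89.0),
        D=st.floats(1.0, 100.0),
    )
    def test_identity_chain_property(self, dphi, D):
        theta = em.resolving_power(D)
        ratio = em.barlow_ratio(dphi, theta)
        assert ratio * theta == pytest.approx(dphi, rel=1e-12)
        p = em.snyder_eye_parameter(D, dphi)
        assert p == pytest.approx(0.61 * ratio, rel=1e-12)
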
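"""Biconic fitting, sagittal curvature maps, extrema and axial-length change."""

import numpy as np
import pytest

from corneosim.curvature import (
    FitError,
    delta_axial_length,
    difference_map,
    extract_extrema,
    fit_biconic,
    sagittal_map,
)
from corneosim.geometry import BiconicParams
from corneosim.surfaces import (
    DEFAULT_CONE,
    DEFAULT_DESIGNS,
    add_kc_cone,
    apply_icrs_effect,
    make_biconic_surface,
)

from conftest import HEALTHY_ANT, KC_ANT


class TestFitBiconic:
    def test_noiseless_sphere_exact(self, sphere_surface):
        p = fit_biconic(sphere_surface, 5.0)
        assert p.Rx == pytest.approx(7.5, abs=1e-6)
        assert p.Ry == pytest.approx(7.5, abs=1e-6)
        assert abs(p.Qx) < 1e-6 and abs(p.Qy) < 1e-6
        assert p.rms_residual < 1e-9

    def test_kc_reference_parameters_recovered(self):
        s = make_biconic_surface(KC_ANT, 9.0, 0.1)
        p = fit_biconic(s, 5.0)
        for got, truth in ((p.Rx, 6.15), (p.Ry, 7.24), (p.Qx, -1.55), (p.Qy, 1.33)):
            assert got == pytest.approx(truth, rel=1e-4)

    def test_noisy_sphere_monte_carlo(self):
        # 1 um elevation noise on a 0.1 mm grid: the free q-value makes the
        # radius estimator scatter with sigma ~ 0.007 mm, so the bound is
        # set at ~4.5 sigma for the worst of 100 replicates and 1.5 sigma
        # for the RMS
        s = make_biconic_surface(BiconicParams(7.5, 7.5, 0, 0), 6.0, 0.1)
        rng = np.random.default_rng(42)
        errs = []
        for _ in range(100):
            noisy = s.copy()
            noisy.z = s.z + rng.normal(0, 1e-3, s.n_points)
            p = fit_biconic(noisy, 5.0)
            errs.append(p.Rx - 7.5)
        errs = np.array(errs)
        assert np.abs(errs).max() < 0.03
        assert np.sqrt(np.mean(errs**2)) < 0.01

    def test_degenerate_point_set_raises(self):
        from corneosim.surfaces import SurfaceSampling

        line = SurfaceSampling(np.linspace(-1, 1, 30), np.zeros(30),
                               np.linspace(-1, 1, 30) ** 2 / 15,
                               zone_diameter=5.0)
        with pytest.raises(FitError):
            fit_biconic(line, 5.0)

    def test_too_few_points_raises(self):
        from corneosim.surfaces import SurfaceSampling

        s = SurfaceSampling(np.array([0.0, 1, 0]), np.array([0.0, 0, 1]),
                            np.array([0.0, 0.1, 0.1]), zone_diameter=5.0)
        with pytest.raises(FitError, match=">= 6 points"):
            fit_biconic(s, 5.0)


class TestSagittalMap:
    def test_sphere_map_uniform_at_eq2_value(self, sphere_surface):
        m = sagittal_map(sphere_surface, 6.0)
        assert m.values == pytest.approx(0.375 / 0.0075, abs=0.05)

    def test_posterior_sphere_sign(self):
        s = make_biconic_surface(BiconicParams(7.5, 7.5, 0, 0), 8.0, 0.1,
                                 surface_side="posterior")
        m = sagittal_map(s, 6.0)
        assert m.values == pytest.approx(-0.042 / 0.0075, abs=0.05)

    def test_biconic_apex_meridional_limit(self, healthy_surface):
        # analytic meridional limit at the apex: 375/Rx on the x meridian
        m = sagittal_map(healthy_surface, 8.0)
        i_x = 0  # theta = 0
        i_y = np.argmin(np.abs(m.thetas - np.pi / 2))
        assert m.values[i_x, 0] == pytest.approx(375 / 7.37, abs=0.05)
        assert m.values[i_y, 0] == pytest.approx(375 / 7.62, abs=0.05)

    def test_re_origin_is_elevation_argmax(self, healthy_surface):
        kc = add_kc_cone(healthy_surface, DEFAULT_CONE)
        m = sagittal_map(kc, 6.0, re_origin=True)
        assert m.origin == kc.most_elevated_point()
        assert m.origin != (0.0, 0.0)

    def test_tangential_mode_sphere(self, sphere_surface):
        m = sagittal_map(sphere_surface, 6.0, mode="tangential")
        assert m.values == pytest.approx(50.0, abs=0.1)


class TestDifferenceMap:
    def test_identical_maps_zero(self, sphere_surface):
        m = sagittal_map(sphere_surface, 6.0)
        d = difference_map(m, m)
        assert np.all(d.values == 0)

    def test_antisymmetry(self, healthy_surface, sphere_surface):
        a = sagittal_map(healthy_surface, 6.0)
        b = sagittal_map(sphere_surface, 6.0)
        d1 = difference_map(a, b)
        d2 = difference_map(b, a)
        assert np.allclose(d1.values, -d2.values)

    def test_grid_mismatch_raises(self, healthy_surface):
        a = sagittal_map(healthy_surface, 6.0)
        b = sagittal_map(healthy_surface, 6.0, n_meridians=32)
        with pytest.raises(ValueError, match="grids"):
            difference_map(a, b)

    def test_sym_icrs_sign_pattern(self, healthy_surface):
        # flattening on the ring-track half, steepening on the opposite half
        post = apply_icrs_effect(healthy_surface, DEFAULT_DESIGNS["sym"], 250.0)
        pre_m = sagittal_map(healthy_surface, 8.0)
        post_m = sagittal_map(post, 8.0)
        d = difference_map(post_m, pre_m)
        tt, rr = np.meshgrid(d.thetas, d.rs, indexing="ij")
        # interior of the ring on the implanted (inferior) half
        lower = (np.sin(tt) < -0.5) & (rr > 1.0) & (rr < 2.8)
        assert np.mean(d.values[lower]) < 0
        # opposite (superior) half near the mirrored track radius
        upper = (np.sin(tt) > 0.5) & (np.abs(rr - 3.35) < 0.2)
        assert d.values[upper].max() > 0

    def test_first_order_linearity(self, healthy_surface):
        # difference_map(a + c, a) matches the map of the small perturbation c
        eps = 1e-3  # um-scale perturbation
        pert = apply_icrs_effect(healthy_surface, DEFAULT_DESIGNS["sym"], eps)
        base = sagittal_map(healthy_surface, 6.0)
        d_small = difference_map(sagittal_map(pert, 6.0), base).values
        pert10 = apply_icrs_effect(healthy_surface, DEFAULT_DESIGNS["sym"], 10 * eps)
        d_big = difference_map(sagittal_map(pert10, 6.0), base).values
        assert np.allclose(d_big, 10 * d_small, atol=1e-4 + 1e-3 * np.abs(d_big))


class TestExtrema:
    def test_all_zero_map_tie_rule(self, sphere_surface):
        m = sagittal_map(sphere_surface, 6.0)
        m.values[:] = 0.0
        (kmax, loc_max), (kmin, loc_min) = extract_extrema(m)
        assert kmax == 0.0 and kmin == 0.0
        # smallest radius, then smallest angle -> the origin itself
        assert loc_max == (0.0, 0.0) and loc_min == (0.0, 0.0)

    def test_single_bump(self, sphere_surface):
        m = sagittal_map(sphere_surface, 6.0)
        m.values[:] = 0.0
        m.values[5, 10] = 3.0
        (kmax, loc), _ = extract_extrema(m)
        assert kmax == 3.0
        expected = (m.rs[10] * np.cos(m.thetas[5]), m.rs[10] * np.sin(m.thetas[5]))
        assert loc == pytest.approx(expected)

    def test_matches_exhaustive_scan(self, sphere_surface, rng):
        m = sagittal_map(sphere_surface, 6.0)
        m.values = rng.normal(size=m.values.shape)
        (kmax, _), (kmin, _) = extract_extrema(m)
        assert kmax == m.values.max() and kmin == m.values.min()


class TestDeltaAxialLength:
    def test_identical_zero(self, healthy_surface):
        assert delta_axial_length(healthy_surface, healthy_surface) == 0.0

    def test_uniform_recession(self, healthy_surface):
        # a 36 um posterior recession of the whole surface shortens the globe
        post = healthy_surface.copy()
        post.z = healthy_surface.z + 36e-3
        assert delta_axial_length(post, healthy_surface) == pytest.approx(-0.036)

    def test_apex_recession_reproduces_reference_convention(self, healthy_surface):
        # 40 um apex recession tapering outward -> dAL = -0.04 mm
        post = healthy_surface.copy()
        r = np.hypot(post.x, post.y)
        post.z = healthy_surface.z + 40e-3 * np.clip(1 - (r / 4) ** 2, 0, None)
        assert delta_axial_length(post, healthy_surface) == pytest.approx(-0.04)

    def test_sampling_mismatch_raises(self, healthy_surface, sphere_surface):
        with pytest.raises(ValueError, match="different"):
            delta_axial_length(healthy_surface, sphere_surface)
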
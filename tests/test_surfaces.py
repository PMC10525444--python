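"""Synthetic surface generator: biconic sampling, keratoconic cone, ICRS
emulation and the deterministic fixture set."""

import numpy as np
import pytest

from corneosim.geometry import BiconicDomainError, BiconicParams, biconic_sag
from corneosim.surfaces import (
    DEFAULT_CONE,
    DEFAULT_DESIGNS,
    ConeSpec,
    ICRSDesign,
    SurfaceSampling,
    _icrs_perturbation,
    add_kc_cone,
    add_measurement_noise,
    apply_icrs_effect,
    make_biconic_surface,
    write_fixture_set,
)

from conftest import HEALTHY_ANT


class TestBiconicSurface:
    def test_sphere_sag_closed_form(self):
        s = make_biconic_surface(BiconicParams(7.5, 7.5, 0, 0), 5.0, 0.25)
        i = np.argmin(np.abs(s.x - 2.5) + np.abs(s.y))
        assert s.x[i] == pytest.approx(2.5) and s.y[i] == 0.0
        assert s.z[i] == pytest.approx(7.5 - np.sqrt(7.5**2 - 2.5**2), abs=1e-12)

    def test_scalar_evaluation_matches_direct_formula(self):
        # independent scalar evaluation at (x, y) = (1, 0), Q = 0
        p = BiconicParams(7.37, 7.62, 0.0, 0.0)
        expected = (1.0 / 7.37) / (1.0 + np.sqrt(1.0 - 1.0 / 7.37**2))
        assert biconic_sag(1.0, 0.0, p) == pytest.approx(expected, rel=1e-14)

    def test_points_confined_to_zone(self, healthy_surface):
        r = np.hypot(healthy_surface.x, healthy_surface.y)
        assert r.max() <= 4.5 + 1e-9
        assert healthy_surface.n_points > 5000

    def test_domain_error_names_offending_pair(self):
        with pytest.raises(BiconicDomainError, match="Qx=1.5"):
            make_biconic_surface(BiconicParams(5.0, 5.0, 1.5, 1.5), 9.0, 0.1)

    def test_apex_at_origin_sag_increasing(self, healthy_surface):
        apex = np.argmin(np.hypot(healthy_surface.x, healthy_surface.y))
        assert healthy_surface.z[apex] == 0.0
        assert np.all(healthy_surface.z >= 0.0)


class TestKCCone:
    def test_zero_amplitude_is_identity(self, healthy_surface):
        out = add_kc_cone(healthy_surface, ConeSpec(amplitude=0.0))
        assert np.array_equal(out.z, healthy_surface.z)

    def test_bump_location_and_magnitude(self, healthy_surface):
        cone = ConeSpec(center=(0.0, -1.0), amplitude=50.0, width=1.5)
        out = add_kc_cone(healthy_surface, cone)
        dz = np.abs(out.z - healthy_surface.z)
        i = int(np.argmax(dz))
        assert (healthy_surface.x[i], healthy_surface.y[i]) == (0.0, -1.0)
        assert dz[i] == pytest.approx(50e-3, rel=1e-12)

    def test_most_elevated_point_moves_toward_cone(self, healthy_surface):
        # grid argmax oracle: the sag minimum after adding the cone
        out = add_kc_cone(healthy_surface, DEFAULT_CONE)
        expected = (out.x[np.argmin(out.z)], out.y[np.argmin(out.z)])
        assert out.most_elevated_point() == expected
        # displaced from the axis, toward the (inferior) cone centre
        assert expected[1] < 0

    def test_cone_outside_zone_rejected(self, healthy_surface):
        with pytest.raises(ValueError, match="outside"):
            add_kc_cone(healthy_surface, ConeSpec(center=(0.0, -6.0)))


class TestICRSEffect:
    def test_zero_gain_identity(self, healthy_surface):
        out = apply_icrs_effect(healthy_surface, DEFAULT_DESIGNS["sym"], 0.0)
        assert np.array_equal(out.z, healthy_surface.z)

    def test_negative_gain_rejected(self, healthy_surface):
        with pytest.raises(ValueError, match="gain"):
            apply_icrs_effect(healthy_surface, DEFAULT_DESIGNS["sym"], -1.0)

    def test_posterior_surface_rejected(self):
        post = make_biconic_surface(BiconicParams(7.91, 7.97, 0.63, 0.37),
                                    9.0, 0.2, surface_side="posterior")
        with pytest.raises(ValueError, match="anterior"):
            apply_icrs_effect(post, DEFAULT_DESIGNS["sym"])

    def test_conserves_elevation_outside_support(self, healthy_surface):
        out = apply_icrs_effect(healthy_surface, DEFAULT_DESIGNS["sym"], 250.0)
        r = np.hypot(healthy_surface.x, healthy_surface.y)
        outside = r > 4.2  # beyond the central extent, the track and its tail
        assert outside.any()
        assert np.array_equal(out.z[outside], healthy_surface.z[outside])

    def test_sym_track_magnitude_constant_along_arc(self):
        d = DEFAULT_DESIGNS["sym"]
        rc = d.optical_zone / 2 + 0.7 / 2
        angs = np.radians(np.linspace(-160, -20, 15))
        dz = _icrs_perturbation(rc * np.cos(angs), rc * np.sin(angs), d, 250.0,
                                components=("track",))
        assert np.ptp(dz) <= 1e-12 * np.abs(dz).max()

    def test_asym_thick_thin_ratio(self):
        # direct evaluation of the stated proportionality: (300*800)/(150*600)
        d = DEFAULT_DESIGNS["asym"]
        vals = {}
        for ang, w_um in ((d.orientation, 800.0),
                          (d.orientation - d.arc_length, 600.0)):
            th = np.radians(ang)
            rc = d.optical_zone / 2 + w_um * 1e-3 / 2
            vals[ang] = _icrs_perturbation(
                np.array([rc * np.cos(th)]), np.array([rc * np.sin(th)]),
                d, 250.0, components=("track",))[0]
        ratio = vals[d.orientation] / vals[d.orientation - d.arc_length]
        assert ratio == pytest.approx((300 * 800) / (150 * 600), rel=1e-9)

    def test_flattening_interior_steepening_opposite(self, healthy_surface):
        out = apply_icrs_effect(healthy_surface, DEFAULT_DESIGNS["sym"], 250.0)
        dz = out.z - healthy_surface.z
        # central optical zone recedes posteriorly (sag increases, flattening)
        r = np.hypot(out.x, out.y)
        assert np.all(dz[r < 2.0] > 0)
        # anterior lift over the arc track (inferior half)
        track = (np.abs(r - 3.35) < 0.2) & (out.y < -1)
        assert dz[track].min() < 0


class TestDesignValidation:
    def test_design_invariants(self):
        with pytest.raises(ValueError):
            ICRSDesign("bad", arc_length=0)
        with pytest.raises(ValueError):
            ICRSDesign("bad", start_thickness=-1)
        with pytest.raises(ValueError):
            ConeSpec(inner_weaken_fraction=0.9, outer_weaken_fraction=0.3)

    def test_six_reference_designs(self):
        assert set(DEFAULT_DESIGNS) == {"asym", "sym", "symMax", "symMin",
                                        "asymW", "asymTH"}
        asym = DEFAULT_DESIGNS["asym"]
        assert (asym.start_thickness, asym.end_thickness) == (150, 300)
        assert (asym.start_width, asym.end_width) == (600, 800)
        assert asym.arc_length == 160 and asym.optical_zone == 6.0

    def test_mean_cross_section(self):
        sym = DEFAULT_DESIGNS["sym"]
        assert sym.mean_cross_section_mm2 == pytest.approx(0.225 * 0.7, rel=1e-9)


class TestNoiseAndFixtures:
    def test_noise_seeded_and_optional(self, healthy_surface, rng):
        clean = add_measurement_noise(healthy_surface, 0.0, rng)
        assert np.array_equal(clean.z, healthy_surface.z)
        n1 = add_measurement_noise(healthy_surface, 1.0,
                                   np.random.default_rng(5))
        n2 = add_measurement_noise(healthy_surface, 1.0,
                                   np.random.default_rng(5))
        assert np.array_equal(n1.z, n2.z)
        assert np.std(n1.z - healthy_surface.z) == pytest.approx(1e-3, rel=0.1)

    def test_fixture_set_enumeration_and_determinism(self, tmp_path):
        kw = dict(grid_spacing=0.3)  # coarse grid keeps the fixture fast
        a = write_fixture_set(tmp_path / "a", seed=3, **kw)
        assert len(a) == 28  # 2 corneas x (1 pre + 6 post) x 2 sides
        sides = {(e["cornea"], e["scenario"], e["side"]) for e in a}
        assert len(sides) == 28
        write_fixture_set(tmp_path / "b", seed=3, **kw)
        for e in a:
            fa = (tmp_path / "a" / e["path"]).read_bytes()
            fb = (tmp_path / "b" / e["path"]).read_bytes()
            assert fa == fb

    def test_fixture_seed_changes_noisy_output(self, tmp_path):
        kw = dict(grid_spacing=0.4, noise_sigma_um=0.5)
        write_fixture_set(tmp_path / "a", seed=1, **kw)
        write_fixture_set(tmp_path / "b", seed=2, **kw)
        diffs = [
            (tmp_path / "a" / f).read_bytes() != (tmp_path / "b" / f).read_bytes()
            for f in ["healthy_pre_anterior.csv", "KC_sym_anterior.csv"]
        ]
        assert any(diffs)


def test_surface_invariants():
    with pytest.raises(ValueError, match="zone"):
        SurfaceSampling(np.array([0, 5.0, 1]), np.zeros(3), np.zeros(3),
                        zone_diameter=4.0)
    with pytest.raises(ValueError, match="equal length"):
        SurfaceSampling(np.zeros(3), np.zeros(2), np.zeros(3))
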
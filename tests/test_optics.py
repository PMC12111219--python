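import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hydrolens.materials import Measured, get_material
from hydrolens.optics import (
    InfeasibleDesignError,
    LensGeometry,
    RefractionObservation,
    SimulationConfig,
    SurfaceProfile,
    SwellTransform,
    build_profiles,
    expected_power,
    fit_circle_radius,
    iso_tolerance,
    power_error_curve,
    refractive_index_from_angles,
    snell_refraction_angle,
    solve_front_radius,
    swell_transform,
    thick_lens_power,
)


def make_material(registry, lef, ref, n_lab, sf=None, n_man=None, name="CTRL"):
    """Clone C77 with overridden measured/manufacturer values."""
    base = registry["C77"]
    return dataclasses.replace(
        base,
        name=name,
        manufacturer_swell_factor=sf or base.manufacturer_swell_factor,
        manufacturer_n=n_man or base.manufacturer_n,
        lef_24h=Measured(lef, 0.0),
        ref_24h=Measured(ref, 0.0),
        n_24h=Measured(n_lab, 0.0),
    )


# --- Snell refractometry ---------------------------------------------------


def test_no_refraction_means_unit_index():
    obs = RefractionObservation(theta_air=60.0, theta_gel=60.0)
    assert refractive_index_from_angles(obs) == pytest.approx(1.0)


def test_sixty_thirty_gives_sqrt_three():
    obs = RefractionObservation(theta_air=60.0, theta_gel=30.0)
    assert refractive_index_from_angles(obs) == pytest.approx(np.sqrt(3.0))


def test_forward_angle_arithmetic():
    assert snell_refraction_angle(1.0, 60.0) == pytest.approx(60.0)
    assert snell_refraction_angle(2.0, 30.0) == pytest.approx(
        np.degrees(np.arcsin(0.25))
    )


@given(n=st.floats(1.0001, 2.0), theta=st.floats(1.0, 89.0))
def test_snell_round_trip_to_machine_precision(n, theta):
    obs = RefractionObservation(theta, snell_refraction_angle(n, theta))
    assert refractive_index_from_angles(obs) == pytest.approx(n, abs=1e-12)


def test_refraction_observation_rejects_bending_away_from_normal():
    with pytest.raises(ValueError):
        RefractionObservation(theta_air=30.0, theta_gel=40.0)
    with pytest.raises(ValueError):
        snell_refraction_angle(0.9, 60.0)


# --- thick-lens power ------------------------------------------------------


def test_equal_curvatures_zero_thickness_cancel():
    g = LensGeometry(r_front=8.6, r_back=8.6, center_thickness=1e-9,
                     zone_diameter=8.0, n=1.4)
    assert thick_lens_power(g) == pytest.approx(0.0, abs=1e-6)


def test_near_zero_power_meniscus_arithmetic():
    g = LensGeometry(r_front=8.745, r_back=8.6, center_thickness=0.5,
                     zone_diameter=8.0, n=1.4)
    # F1 = 0.4/0.008745 = 45.74 D, F2 = -46.51 D, thickness term ~ +0.76 D
    assert thick_lens_power(g) == pytest.approx(0.0, abs=0.05)


def test_power_linear_in_index_contrast_at_zero_thickness():
    kw = dict(r_front=7.0, r_back=8.6, center_thickness=1e-12, zone_diameter=6.0)
    p_full = thick_lens_power(LensGeometry(n=1.4, **kw))
    p_half = thick_lens_power(LensGeometry(n=1.2, **kw))
    assert p_half == pytest.approx(p_full / 2.0, rel=1e-9)


def test_solve_front_radius_zero_power_zero_thickness_equals_back():
    assert solve_front_radius(0.0, 8.6, 0.0, 1.42) == pytest.approx(8.6, abs=1e-12)


@pytest.mark.parametrize("target", np.arange(-20.0, 20.1, 2.5))
def test_design_round_trip_reproduces_target(target):
    n = 1.4
    r = solve_front_radius(target, 8.6, 0.5, n)
    g = LensGeometry(r_front=r, r_back=8.6, center_thickness=0.5,
                     zone_diameter=6.0, n=n)
    assert thick_lens_power(g) == pytest.approx(target, abs=1e-9)


def test_unreachable_meniscus_power_is_infeasible():
    # a huge minus power would need non-positive front surface power
    with pytest.raises(InfeasibleDesignError):
        solve_front_radius(-60.0, 8.6, 0.5, 1.4)


# --- surface profiles and circle fitting -----------------------------------


def test_sag_zero_at_apex_even_in_x_and_matches_arithmetic():
    g = LensGeometry(r_front=8.6, r_back=8.6, center_thickness=0.5,
                     zone_diameter=8.0, n=1.4)
    front, back = build_profiles(g, n_points=101)
    mid = 50
    assert front.z[mid] == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(front.z, front.z[::-1], atol=1e-12)
    # z(4) = 8.6 - sqrt(8.6^2 - 16)
    assert np.max(front.z) == pytest.approx(8.6 - np.sqrt(8.6**2 - 16.0), abs=1e-9)
    assert np.allclose(front.z, back.z)


def test_zone_wider_than_cap_is_rejected():
    with pytest.raises(InfeasibleDesignError):
        LensGeometry(r_front=3.0, r_back=8.6, center_thickness=0.5,
                     zone_diameter=8.0, n=1.4)


def test_swell_transform_identity_similarity_and_inverse():
    x = np.linspace(-4, 4, 51)
    prof = SurfaceProfile(x=x, z=8.6 - np.sqrt(8.6**2 - x**2))
    ident = swell_transform(prof, SwellTransform(1.0, 1.0))
    assert np.array_equal(ident.x, prof.x) and np.array_equal(ident.z, prof.z)
    iso = swell_transform(prof, SwellTransform(1.2, 1.2))
    # points lie exactly on a sphere of radius 1.2 * 8.6
    r = 1.2 * 8.6
    assert np.allclose(iso.x**2 + (iso.z - r) ** 2, r**2, atol=1e-9)
    back = swell_transform(iso, SwellTransform(1 / 1.2, 1 / 1.2))
    assert np.allclose(back.x, prof.x) and np.allclose(back.z, prof.z)


def test_circle_fit_recovers_exact_radius():
    x = np.linspace(-4, 4, 81)
    prof = SurfaceProfile(x=x, z=8.6 - np.sqrt(8.6**2 - x**2))
    assert fit_circle_radius(prof) == pytest.approx(8.6, abs=1e-9)


def test_circle_fit_needs_three_noncollinear_points():
    with pytest.raises(ValueError):
        fit_circle_radius(SurfaceProfile(x=np.array([0.0, 1.0]), z=np.zeros(2)))
    with pytest.raises(ValueError):
        fit_circle_radius(SurfaceProfile(x=np.array([-1.0, 0.0, 1.0]), z=np.zeros(3)))


@pytest.mark.parametrize("half_chord", [2.0, 1.0, 0.5])
def test_anisotropic_fit_converges_to_apex_radius(half_chord):
    # sphere R scaled laterally by a, axially by b has apex radius a^2 R / b
    a, b, r = 1.1, 0.9, 8.6
    x = np.linspace(-half_chord, half_chord, 101)
    prof = swell_transform(
        SurfaceProfile(x=x, z=r - np.sqrt(r**2 - x**2)), SwellTransform(a, b)
    )
    target = a**2 * r / b
    tol = {2.0: 0.02, 1.0: 0.005, 0.5: 0.005}[half_chord] * target
    assert fit_circle_radius(prof) == pytest.approx(target, abs=tol)


# --- ISO tolerance bands ---------------------------------------------------


@pytest.mark.parametrize(
    "power, tol",
    [(5.0, 0.25), (-5.0, 0.25), (10.0, 0.25), (-15.0, 0.5), (20.0, 0.5), (25.0, 1.0)],
)
def test_iso_tolerance_bands(power, tol):
    assert iso_tolerance(power) == tol


# --- expected power & power-error curves -----------------------------------


def test_manufacturer_consistent_material_reproduces_every_target(registry):
    ctrl = make_material(registry, lef=1.66, ref=1.66, n_lab=1.38)
    curve = power_error_curve(ctrl, grid=np.arange(-20, 20.1, 5.0))
    assert curve.max_abs_error() < 1e-9
    assert curve.within_iso.all()
    assert curve.iso_compliant_fraction() == 1.0


def test_isotropic_swell_matches_closed_form(registry):
    # LEF = REF = s: fitted radii are exactly s x design radii, so the
    # full profile pipeline must agree with direct scaling to < 1e-6 D
    s_net = 1.05
    base = registry["C77"]
    mat = make_material(registry, lef=base.manufacturer_swell_factor * s_net,
                        ref=base.manufacturer_swell_factor * s_net, n_lab=1.372)
    for target in (-20.0, -5.0, 0.0, 5.0, 20.0):
        r_front = solve_front_radius(target, 8.6, 0.5, base.manufacturer_n)
        design = LensGeometry(r_front=r_front, r_back=8.6, center_thickness=0.5,
                              zone_diameter=8.0, n=base.manufacturer_n)
        via_pipeline = expected_power(design, mat, "24h")
        scaled = LensGeometry(
            r_front=r_front * s_net, r_back=8.6 * s_net,
            center_thickness=0.5 * s_net,
            zone_diameter=design.zone_diameter * s_net, n=1.372,
        )
        assert via_pipeline == pytest.approx(thick_lens_power(scaled), abs=1e-6)


def test_undefined_timepoint_propagates(registry):
    design = LensGeometry(r_front=8.745, r_back=8.6, center_thickness=0.5,
                          zone_diameter=8.0, n=1.38)
    with pytest.raises(ValueError):
        expected_power(design, registry["C77"], "12h")


def test_c77_power_error_bounded_at_extremes(registry):
    curve = power_error_curve(registry["C77"])
    assert curve.targets[0] == -20.0 and curve.targets[-1] == 20.0
    assert max(abs(curve.errors[0]), abs(curve.errors[-1])) <= 6.0


def test_c67_power_error_bounded_at_extremes(registry):
    curve = power_error_curve(registry["C67"])
    assert max(abs(curve.errors[0]), abs(curve.errors[-1])) <= 10.0


@pytest.mark.parametrize("name", ["C38", "C55", "C58", "C67", "C77"])
def test_error_growth_is_monotone_in_target_power(registry, name):
    curve = power_error_curve(registry[name], grid=np.arange(-20, 20.1, 1.0))
    diffs = np.diff(curve.errors)
    assert np.all(diffs >= -1e-9) or np.all(diffs <= 1e-9)


@pytest.mark.parametrize("name", ["C38", "C55", "C58", "C67", "C77"])
def test_every_material_exceeds_iso_somewhere(registry, name):
    curve = power_error_curve(registry[name])
    assert not curve.within_iso.all()
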
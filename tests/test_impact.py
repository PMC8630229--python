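"""Impact-force closed form against the brute-force vector projection, its
limiting cases, and the adhesion scaling."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import jumpland as jl
from jumpland.impact import (
    ImpactInputs,
    impact_force,
    incidence_angle,
    landing_velocity_vector,
    predicted_adhesion,
    safety_factor,
)
from jumpland.io import MarkerTrack, PlatformGeometry

MID_MASS_KG = (0.0359 + 0.0492) / 2.0  # midpoint of the studied mass range


def _projection_oracle(m, v, T, alpha_deg, phi_deg, g=9.81):
    """Numeric projection of the planar deceleration-force vector onto the
    surface normal, using omega = alpha - phi (independent of the closed
    form under test)."""
    omega = math.radians(alpha_deg - phi_deg)
    phi = math.radians(phi_deg)
    F = np.array(
        [m * (v / T) * math.cos(omega), m * (v / T) * math.sin(omega) + m * g]
    )
    e = np.array([math.sin(phi), math.cos(phi)])
    return float(F @ e)


def test_landing_velocity_vector_level_motion():
    n = 10
    pos = np.column_stack([-1.5 * np.arange(n) * 0.0005, np.zeros(n)])
    v = landing_velocity_vector(MarkerTrack("belly", pos, 0.0005), 5)
    np.testing.assert_allclose(v, [-1.5, 0.0], atol=1e-12)


def test_landing_velocity_vector_free_fall_component():
    # after 0.2 s of free fall the y-component is ~ g * 0.2
    g, dt = 9.81, 0.0005
    t = np.arange(500) * dt
    pos = np.column_stack([np.zeros_like(t), 0.5 * g * t**2])
    t0 = 400  # t = 0.2 s
    v = landing_velocity_vector(MarkerTrack("belly", pos, dt), t0)
    assert v[1] == pytest.approx(g * 0.2, rel=0.02)


def test_landing_velocity_requires_preceding_frame():
    pos = np.zeros((5, 2))
    with pytest.raises(ValueError):
        landing_velocity_vector(MarkerTrack("belly", pos + 0.1, 0.0005), 0)


def test_speed_matches_kinematics_series(vertical_noisy):
    # |Eq-11 vector| at t0 == frame-wise speed of the interval ending at t0
    trial, truth, geom = vertical_noisy
    belly = jl.smooth_track(trial.tracks["belly"])
    t0 = truth.contact_frame
    v = landing_velocity_vector(belly, t0)
    speed = jl.compute_velocity(belly).speed
    assert np.linalg.norm(v) == pytest.approx(speed[t0 - 1], abs=1e-9)


@pytest.mark.parametrize(
    "v,phi,expected",
    [
        ((-1.0, 0.0), 0.0, 0.0),  # motion parallel to the floor
        ((-1.0, 1.0), 0.0, 45.0),  # hand dot product: cos a = 1/sqrt(2)
        ((-1.0, 0.0), 90.0, 90.0),  # perpendicular collision with the wall
    ],
)
def test_incidence_angle_examples(v, phi, expected):
    geom = PlatformGeometry(incline_deg=phi)
    assert incidence_angle(np.array(v), geom) == pytest.approx(expected, abs=1e-9)


def test_incidence_angle_rejects_zero_velocity():
    with pytest.raises(ValueError):
        incidence_angle(np.zeros(2), PlatformGeometry(incline_deg=0.0))


def test_unnormalized_45_direction_vector_is_harmless():
    # the conventional h_45 = (-1, 1, 0) is unnormalized; the arccos
    # formula normalizes, so results equal the unit-vector computation
    geom = PlatformGeometry(incline_deg=45.0)
    v = np.array([-1.3, 0.4])
    h = geom.in_plane_3d[:2]
    a_unit = math.degrees(
        math.acos(v @ (h / np.linalg.norm(h)) / np.linalg.norm(v))
    )
    assert incidence_angle(v, geom) == pytest.approx(a_unit, abs=1e-12)


def test_resting_weight_limit():
    # v -> 0 on a horizontal platform: F_i -> m g
    res = impact_force(
        ImpactInputs(mass=0.04, speed=1e-9, duration=0.05, alpha_deg=30.0, incline_deg=0.0)
    )
    assert res.impact_force == pytest.approx(0.04 * 9.81, abs=1e-8)


def test_vertical_treatment_worked_example():
    """Perpendicular collision with the vertical platform at the studied
    group means reproduces the reported mean impact force (1.01 +/- 0.09 N)."""
    res = impact_force(
        ImpactInputs(
            mass=MID_MASS_KG, speed=1.66, duration=0.0697,
            alpha_deg=90.0, incline_deg=90.0,
        )
    )
    assert res.impact_force == pytest.approx(1.013386, abs=1e-5)
    assert abs(res.impact_force - 1.01) < 0.09
    assert res.gravitational_term == pytest.approx(0.0, abs=1e-12)
    assert res.v_perp == pytest.approx(1.66)


def test_closed_form_equals_projection_oracle(rng):
    for _ in range(2000):
        m = rng.uniform(0.01, 0.1)
        v = rng.uniform(0.1, 5.0)
        T = rng.uniform(0.005, 0.2)
        alpha = rng.uniform(0.0, 180.0)
        phi = rng.uniform(0.0, 90.0)
        g = rng.uniform(1.0, 20.0)
        res = impact_force(ImpactInputs(m, v, T, alpha, phi, g))
        assert abs(res.impact_force - _projection_oracle(m, v, T, alpha, phi, g)) < 1e-12


def test_expanded_trig_form_collapses_to_compact_form():
    # the four-term expansion in alpha and phi equals m(v/T)sin(alpha)
    # + m g cos(phi) on a grid of angles
    m, v, T, g = 0.042, 1.7, 0.05, 9.81
    for alpha in np.linspace(0.0, 180.0, 37):
        for phi in np.linspace(0.0, 90.0, 19):
            a, p = math.radians(alpha), math.radians(phi)
            expanded = m * (v / T) * (
                math.cos(a) * math.cos(p) * math.sin(p)
                + math.sin(p) * math.sin(a) * math.sin(p)
                + math.sin(a) * math.cos(p) * math.cos(p)
                - math.sin(p) * math.cos(a) * math.cos(p)
            ) + m * g * math.cos(p)
            compact = impact_force(
                ImpactInputs(m, v, max(T, 1e-9), alpha, phi, g)
            ).impact_force
            assert expanded == pytest.approx(compact, abs=1e-12)


def test_vertical_wall_removes_gravity():
    for g in (1.0, 9.81, 25.0):
        res = impact_force(ImpactInputs(0.04, 1.66, 0.07, 90.0, 90.0, g))
        assert res.impact_force == pytest.approx(0.04 * 1.66 / 0.07, abs=1e-12)


@given(
    st.floats(0.2, 4.9), st.floats(0.21, 5.0), st.floats(0.006, 0.199),
    st.floats(0.005, 0.198),
)
def test_monotone_in_speed_and_duration(v1, v2, T1, T2):
    """On the horizontal platform at fixed alpha, F_i increases with v and
    decreases with T."""
    v_lo, v_hi = sorted((v1, v2))
    T_lo, T_hi = sorted((T1, T2))
    f = lambda v, T: impact_force(ImpactInputs(0.04, v, T, 60.0, 0.0)).impact_force
    assert f(v_hi, T_lo) >= f(v_lo, T_lo) - 1e-12
    assert f(v_lo, T_hi) <= f(v_lo, T_lo) + 1e-12


@given(st.floats(0.0, 180.0), st.floats(0.0, 90.0))
def test_force_bounded_below_by_gravity_term(alpha, phi):
    res = impact_force(ImpactInputs(0.04, 1.5, 0.05, alpha, phi))
    assert res.impact_force >= 0.04 * 9.81 * math.cos(math.radians(phi)) - 1e-12


def test_adhesion_scaling_values():
    # midpoint mass -> ~10 N single-forelimb adhesion
    assert predicted_adhesion(MID_MASS_KG * 1000.0) == pytest.approx(10.1317, abs=2e-4)
    # closed-form evaluation at 1 g
    assert predicted_adhesion(1.0) == pytest.approx(10 ** (-0.69), rel=1e-12)


def test_adhesion_power_law_doubling():
    for m in (5.0, 20.0, 42.55):
        assert predicted_adhesion(2 * m) / predicted_adhesion(m) == pytest.approx(
            2 ** 1.041, rel=1e-12
        )


def test_adhesion_rejects_nonpositive_mass():
    with pytest.raises(ValueError):
        predicted_adhesion(0.0)


def test_safety_factor():
    assert safety_factor(10.0, 2.5) == pytest.approx(4.0)
    assert safety_factor(3.3, 3.3) == pytest.approx(1.0)
    assert safety_factor(10.0, 5.0) < safety_factor(10.0, 2.5)  # monotone
    with pytest.raises(ValueError):
        safety_factor(10.0, 0.0)
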
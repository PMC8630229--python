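"""Event detection, angles, curvature and take-off metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import jumpland as jl
import jumpland.landing as lm
from jumpland.io import MarkerTrack, PlatformGeometry, TrialRecording

DT = 0.0005


def _trial_from_positions(tracks_xy, fps=2000.0, **kw):
    tracks = {m: MarkerTrack(m, np.asarray(p, float), 1.0 / fps) for m, p in tracks_xy.items()}
    return TrialRecording(
        trial_id="t", individual_id="g", mass=0.042, treatment_deg=kw.pop("treatment", 0.0),
        fps=fps, tracks=tracks, **kw,
    )


def _descending_onto_floor(n=80, touch=57):
    """Belly touches a horizontal floor (y=0, approach from above) exactly
    at frame ``touch``; snout/tail ride alongside, higher up."""
    y = -0.002 * (touch - np.arange(n))  # y-down: rises through 0 at `touch`
    y = np.where(np.arange(n) > touch, y[touch], y)  # then rests on the floor
    x = -0.001 * np.arange(n)
    belly = np.column_stack([x, y])
    off = np.array([0.0, -0.03])
    return {
        "belly": belly, "snout": belly + off + [-0.05, 0], "tail_base": belly + off + [0.05, 0],
    }


def test_contact_detected_at_touch_frame():
    trial = _trial_from_positions(_descending_onto_floor())
    geom = PlatformGeometry(incline_deg=0.0)
    ev = lm.detect_first_contact(trial, geom, epsilon=1e-6)
    assert ev.frame == 57
    assert ev.part == "belly"
    assert not ev.annotated


def test_annotation_overrides_auto_detection():
    trial = _trial_from_positions(
        _descending_onto_floor(),
        first_contact_annotation=60,
        first_contact_part_annotation="forelimb",
    )
    geom = PlatformGeometry(incline_deg=0.0)
    ev = lm.detect_first_contact(trial, geom, epsilon=1e-6)
    assert ev.frame == 60 and ev.part == "forelimb" and ev.annotated


def test_no_contact_raises():
    tracks = _descending_onto_floor()
    for m in tracks:
        tracks[m] = tracks[m] - [0.0, 0.5]  # keep everything 0.5 m above
    trial = _trial_from_positions(tracks)
    with pytest.raises(lm.NoContactError):
        lm.detect_first_contact(trial, PlatformGeometry(incline_deg=0.0), 0.002)


def test_simulated_contact_detected_within_two_frames(vertical_study):
    for trial, truth, geom in vertical_study:
        sm = trial.with_tracks(
            {n: jl.smooth_track(t) for n, t in trial.tracks.items()}
        )
        ev = lm.detect_first_contact(sm, geom, epsilon=0.002)
        # the 2 mm threshold is crossed ~epsilon / v_perp before true touch,
        # which at ~1.66 m/s spans 2-3 frames at 2000 fps
        assert -3 <= ev.frame - truth.contact_frame <= 1


def test_landing_duration_is_argmin_of_belly_distance():
    # distance series 10,6,3,1,0.5,0.8,1.1 mm -> end at index 4, T = 4 dt
    d_mm = [10, 6, 3, 1, 0.5, 0.8, 1.1]
    belly = np.column_stack([np.zeros(7), -np.array(d_mm) * 1e-3])
    off = [0.0, -0.02]
    trial = _trial_from_positions(
        {"belly": belly, "snout": belly + off, "tail_base": belly + off}
    )
    T, end = lm.landing_duration(trial, PlatformGeometry(incline_deg=0.0), 0)
    assert end == 4
    assert T == pytest.approx(4 * DT)


def test_duration_tie_breaks_to_earliest_frame():
    d_mm = [5, 2, 1, 1, 3]
    belly = np.column_stack([np.zeros(5), -np.array(d_mm) * 1e-3])
    off = [0.0, -0.02]
    trial = _trial_from_positions(
        {"belly": belly, "snout": belly + off, "tail_base": belly + off}
    )
    _, end = lm.landing_duration(trial, PlatformGeometry(incline_deg=0.0), 0)
    assert end == 2


def test_truncated_landing_raises():
    d_mm = [10, 8, 6, 4, 2]
    belly = np.column_stack([np.zeros(5), -np.array(d_mm) * 1e-3])
    off = [0.0, -0.02]
    trial = _trial_from_positions(
        {"belly": belly, "snout": belly + off, "tail_base": belly + off}
    )
    with pytest.raises(lm.TruncatedLandingError):
        lm.landing_duration(trial, PlatformGeometry(incline_deg=0.0), 0)


def _head_trial(snout, eye):
    base = {
        "snout": [snout] * 2, "eye": [eye] * 2,
        "belly": [[0.05, 0.02]] * 2, "tail_base": [[0.1, 0.02]] * 2,
    }
    return _trial_from_positions(base)


def test_head_angle_horizontal_and_45():
    assert lm.head_angle(_head_trial([0.0, 0.0], [-0.01, 0.0]), 0) == pytest.approx(0.0)
    # snout 1 cm above the eye over 1 cm horizontal separation -> 45 deg
    assert lm.head_angle(_head_trial([0.0, 0.0], [0.01, 0.01]), 0) == pytest.approx(45.0)


def test_head_angle_missing_eye_is_none():
    trial = _trial_from_positions(_descending_onto_floor())
    assert lm.head_angle(trial, 0) is None


@given(st.floats(-30.0, 30.0), st.floats(5.0, 40.0))
def test_head_angle_rotation_equivariance(base_deg, delta_deg):
    """Rotating the snout about the eye adds exactly the rotation angle."""
    eye = np.array([0.3, -0.1])
    r = 0.015

    def snout_at(deg):
        a = math.radians(deg)
        # gecko travels -x: snout ahead of (at smaller x than) the eye
        return eye + r * np.array([-math.cos(a), -math.sin(a)])

    a0 = lm.head_angle(_head_trial(snout_at(base_deg), eye), 0)
    a1 = lm.head_angle(_head_trial(snout_at(base_deg + delta_deg), eye), 0)
    assert a1 - a0 == pytest.approx(delta_deg, abs=1e-9)


def test_aerial_rotation_telescopes_and_recovers_prescribed_ramp():
    trial, truth, geom = jl.simulate_jump(
        jl.preset_config("vertical", noise_sd=0.0, net_rotation_deg=15.0), rng=1
    )
    s = jl.analyze_trial(trial, geom)
    assert s.net_rotation_deg == pytest.approx(15.0, abs=1.0)
    # telescoping identity: landing angle = take-off angle + net rotation
    assert s.landing_angle_deg == pytest.approx(
        s.takeoff_angle_deg + s.net_rotation_deg, abs=1e-9
    )


def test_constant_attitude_flight_has_zero_net_rotation(vertical_clean):
    trial, truth, geom = vertical_clean
    s = jl.analyze_trial(trial, geom)
    assert truth.net_rotation_deg == 0.0
    assert s.net_rotation_deg == pytest.approx(0.0, abs=0.5)


def test_curvature_hand_geometry():
    # snout (0,0), tail (0.02, 0), belly (0.01, 0.01): q=0.01, p=0.02 -> 0.5
    trial = _trial_from_positions(
        {
            "snout": [[0.0, 0.0]] * 2,
            "tail_base": [[0.02, 0.0]] * 2,
            "belly": [[0.01, 0.01]] * 2,
        }
    )
    c = lm.body_curvature(trial, (0, 1))
    np.testing.assert_allclose(c.deflection, 0.01)
    np.testing.assert_allclose(c.chord, 0.02)
    np.testing.assert_allclose(c.curvature, 0.5)
    assert c.max_curvature == pytest.approx(0.5)


def test_collinear_markers_have_zero_curvature():
    trial = _trial_from_positions(
        {
            "snout": [[0.0, 0.0]] * 3,
            "belly": [[0.01, 0.0]] * 3,
            "tail_base": [[0.02, 0.0]] * 3,
        }
    )
    np.testing.assert_allclose(lm.body_curvature(trial, (0, 2)).curvature, 0.0)


def test_degenerate_chord_frames_are_skipped():
    trial = _trial_from_positions(
        {
            "snout": [[0.0, 0.0], [0.0, 0.0]],
            "tail_base": [[0.02, 0.0], [1e-5, 0.0]],  # 2nd frame degenerate
            "belly": [[0.01, 0.01]] * 2,
        }
    )
    c = lm.body_curvature(trial, (0, 1))
    assert list(c.skipped) == [1]
    assert len(c.curvature) == 1


@given(
    st.floats(-3.0, 3.0),
    st.floats(-1.0, 1.0),
    st.floats(-1.0, 1.0),
    st.floats(0.05, 20.0),
)
def test_curvature_invariant_under_similarity_transforms(theta, tx, ty, scale):
    snout = np.array([0.0, 0.0])
    tail = np.array([0.11, 0.01])
    belly = np.array([0.055, 0.03])
    R = scale * np.array(
        [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
    )
    t = np.array([tx, ty])

    def curv(s, b, bt):
        trial = _trial_from_positions(
            {"snout": [s] * 2, "belly": [b] * 2, "tail_base": [bt] * 2}
        )
        return lm.body_curvature(trial, (0, 0)).curvature[0]

    c0 = curv(snout, belly, tail)
    c1 = curv(R @ snout + t, R @ belly + t, R @ tail + t)
    assert c1 == pytest.approx(c0, abs=1e-9)


def test_takeoff_detection_monotone_in_epsilon():
    # tail slides along the take-off plane then ascends
    n = 60
    y = np.concatenate([np.zeros(30), -0.0005 * np.arange(1, 31)])
    tail = np.column_stack([-0.001 * np.arange(n), y])
    off = [0.0, -0.02]
    trial = _trial_from_positions(
        {"tail_base": tail, "belly": tail + off, "snout": tail + off}
    )
    plane = PlatformGeometry(incline_deg=0.0, anchor=(0.0, 0.0))
    frames = [
        lm.takeoff_velocity_frame(trial, plane, epsilon=e)
        for e in (0.0005, 0.001, 0.002, 0.005)
    ]
    assert frames == sorted(frames)
    assert frames[0] >= 29


def test_takeoff_speed_zero_for_stationary_trial():
    pos = np.tile([0.1, -0.05], (30, 1))
    trial = _trial_from_positions(
        {"belly": pos, "snout": pos + [-0.05, 0], "tail_base": pos + [0.05, 0]},
        last_contact_annotation=10,
    )
    from jumpland.kinematics import compute_velocity

    v = compute_velocity(trial.tracks["belly"])
    assert v.speed[trial.last_contact_annotation] == 0.0


def test_noise_free_takeoff_speed_recovery(vertical_clean):
    trial, truth, geom = vertical_clean
    s = jl.analyze_trial(trial, geom)
    assert s.takeoff_speed_ms == pytest.approx(truth.takeoff_speed, rel=0.01)
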
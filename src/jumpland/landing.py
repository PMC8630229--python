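"""Event detection and per-trial landing measurements.

Definitions (all on smoothed tracks, time re-anchored so that first contact
is t = 0):

* first contact t0 -- earliest frame at which any tracked marker lies
  within ``epsilon`` of the landing surface (a manual annotation always
  overrides the automatic rule, since limb contact is invisible to a
  three-marker midline);
* landing duration T -- time from first contact until the belly reaches
  its closest perpendicular distance to the surface (earliest frame on
  ties); the landing-end frame windows the other metrics;
* landing angle gamma -- signed angle of the snout-to-ventral-eye line
  above the horizontal at first contact (positive = snout up); the
  take-off angle is the same measurement at the last take-off contact;
* body curvature -- q / p, the perpendicular deflection q of the belly
  from the snout-tail-base chord over the chord length p (dimensionless
  and scale-free); the per-trial metric is the maximum over the landing
  window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np

from .io import PlatformGeometry, TrialRecording

__all__ = [
    "ContactEvent",
    "CurvatureSeries",
    "LandingSummary",
    "detect_first_contact",
    "landing_duration",
    "head_angle",
    "aerial_rotation",
    "body_curvature",
    "takeoff_velocity_frame",
    "NoContactError",
    "TruncatedLandingError",
]

# map auto-detectable markers onto the first-contact categories used for
# landings (forelimb contact cannot be detected from the midline markers)
_MARKER_TO_PART = {"snout": "snout", "eye": "snout", "belly": "belly", "tail_base": "hindlimb"}


class NoContactError(ValueError):
    """No marker ever comes within epsilon of the landing surface."""


class TruncatedLandingError(ValueError):
    """The recording ends while the belly is still approaching the surface."""


@dataclass(frozen=True)
class ContactEvent:
    frame: int
    part: str
    annotated: bool


def detect_first_contact(
    trial: TrialRecording,
    geom: PlatformGeometry,
    epsilon: float = 0.002,
) -> ContactEvent:
    """First frame at which any marker's perpendicular distance to the
    landing surface drops to <= epsilon.  An annotation wins outright."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if trial.first_contact_annotation is not None:
        part = trial.first_contact_part_annotation or "unknown"
        return ContactEvent(int(trial.first_contact_annotation), part, True)
    best: tuple[int, str] | None = None
    for name, track in trial.tracks.items():
        d = geom.signed_distance(track.positions)
        hit = np.nonzero(d <= epsilon)[0]
        if hit.size and (best is None or hit[0] < best[0]):
            best = (int(hit[0]), name)
    if best is None:
        raise NoContactError(
            f"trial {trial.trial_id!r}: no marker within {epsilon} m of the surface"
        )
    return ContactEvent(best[0], _MARKER_TO_PART.get(best[1], best[1]), False)


def landing_duration(
    trial: TrialRecording, geom: PlatformGeometry, t0: int
) -> tuple[float, int]:
    """Landing duration T (s) and the landing-end frame.

    The end is the argmin over frames >= t0 of the belly's perpendicular
    distance to the surface (earliest frame on exact ties).  A belly still
    strictly approaching at the final frame raises
    :class:`TruncatedLandingError`.
    """
    belly = trial.tracks["belly"]
    if not 0 <= t0 < belly.n_frames:
        raise ValueError(f"contact frame {t0} outside track")
    d = np.abs(geom.signed_distance(belly.positions[t0:]))
    end_rel = int(np.argmin(d))
    if end_rel == len(d) - 1 and len(d) > 1 and d[-1] < d[-2]:
        raise TruncatedLandingError(
            f"trial {trial.trial_id!r}: belly still approaching at the last frame"
        )
    end = t0 + end_rel
    return end_rel * belly.dt, end


def head_angle(trial: TrialRecording, frame: int) -> float | None:
    """Signed head-axis angle (degrees) at ``frame``: angle of the line
    through the snout and the ventral eye point above the horizontal,
    positive when the snout is above the eye.  Returns None when the eye
    marker is absent (angle unavailable, not an error)."""
    if "eye" not in trial.tracks:
        return None
    snout = trial.tracks["snout"].positions[frame]
    eye = trial.tracks["eye"].positions[frame]
    dx = eye[0] - snout[0]
    dy = eye[1] - snout[1]  # y-down: snout above eye => dy > 0
    if dx == 0.0 and dy == 0.0:
        return None
    ang = math.degrees(math.atan2(dy, dx))
    # undirected line: fold into (-90, 90]
    if ang <= -90.0:
        ang += 180.0
    elif ang > 90.0:
        ang -= 180.0
    return ang


def aerial_rotation(
    trial: TrialRecording, window: tuple[int, int]
) -> tuple[float | None, np.ndarray | None]:
    """Head-angle series across the aerial window (take-off frame to first
    contact) and the net rotation angle(contact) - angle(take-off)."""
    start, end = window
    if end < start:
        raise ValueError("empty aerial window")
    angles = [head_angle(trial, f) for f in range(start, end + 1)]
    if any(a is None for a in angles):
        return None, None
    arr = np.asarray(angles, dtype=float)
    return float(arr[-1] - arr[0]), arr


@dataclass(frozen=True)
class CurvatureSeries:
    """Per-frame body-curvature geometry over a window of frames."""

    frames: np.ndarray  # absolute frame indices
    chord: np.ndarray  # p, m
    deflection: np.ndarray  # q, m
    curvature: np.ndarray  # q / p
    skipped: np.ndarray  # frames dropped for a degenerate chord

    @property
    def max_curvature(self) -> float:
        if self.curvature.size == 0:
            raise ValueError("no valid curvature frames in window")
        return float(np.max(self.curvature))


_MIN_CHORD = 1e-4  # m; shorter chords are degenerate


def body_curvature(trial: TrialRecording, window: tuple[int, int]) -> CurvatureSeries:
    """q/p per frame over the inclusive frame window."""
    start, end = window
    sn = trial.tracks["snout"].positions[start : end + 1]
    bt = trial.tracks["tail_base"].positions[start : end + 1]
    be = trial.tracks["belly"].positions[start : end + 1]
    chord_vec = sn - bt
    p = np.linalg.norm(chord_vec, axis=1)
    ok = p >= _MIN_CHORD
    # perpendicular distance of the belly from the snout--tail_base line
    rel = be - bt
    cross = np.abs(chord_vec[:, 0] * rel[:, 1] - chord_vec[:, 1] * rel[:, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(ok, cross / p, np.nan)
        curv = np.where(ok, q / p, np.nan)
    frames = np.arange(start, end + 1)
    return CurvatureSeries(
        frames=frames[ok],
        chord=p[ok],
        deflection=q[ok],
        curvature=curv[ok],
        skipped=frames[~ok],
    )


def takeoff_velocity_frame(
    trial: TrialRecording,
    takeoff_geom: PlatformGeometry,
    epsilon: float = 0.002,
) -> int:
    """Frame of last contact with the take-off surface.

    Uses the annotation when present; otherwise the last frame at which the
    hindlimb-proxy marker (tail_base) lies within epsilon of the take-off
    plane.  Enlarging epsilon can only move the detected frame later.
    """
    if trial.last_contact_annotation is not None:
        return int(trial.last_contact_annotation)
    d = np.abs(takeoff_geom.signed_distance(trial.tracks["tail_base"].positions))
    hit = np.nonzero(d <= epsilon)[0]
    if hit.size == 0:
        raise NoContactError(
            f"trial {trial.trial_id!r}: tail_base never within {epsilon} m of take-off plane"
        )
    return int(hit[-1])


@dataclass(frozen=True)
class LandingSummary:
    """Every per-trial quantity the pipeline derives, one jump per row."""

    trial_id: str
    individual_id: str
    treatment_deg: float
    mass_kg: float
    fps: float
    first_contact_frame: int
    first_contact_part: str
    landing_end_frame: int
    landing_duration_s: float
    max_curvature: float
    peak_deceleration_ms2: float
    no_deceleration_flag: bool
    landing_speed_ms: float
    incidence_angle_deg: float
    v_perp_ms: float
    impact_force_n: float | None
    impact_inertial_term_n: float | None
    impact_gravitational_term_n: float | None
    landing_angle_deg: float | None = None
    takeoff_angle_deg: float | None = None
    takeoff_speed_ms: float | None = None
    net_rotation_deg: float | None = None

    def __post_init__(self) -> None:
        if not self.landing_duration_s > 0:
            raise ValueError("landing duration must be positive")
        if not 0.0 <= self.incidence_angle_deg <= 180.0:
            raise ValueError("incidence angle out of range")

    @property
    def first_contact_time_s(self) -> float:
        return self.first_contact_frame / self.fps

    def as_row(self) -> dict:
        return {
            "trial_id": self.trial_id,
            "individual_id": self.individual_id,
            "treatment_deg": self.treatment_deg,
            "mass_kg": self.mass_kg,
            "fps": self.fps,
            "first_contact_frame": self.first_contact_frame,
            "first_contact_time_s": self.first_contact_time_s,
            "first_contact_part": self.first_contact_part,
            "landing_end_frame": self.landing_end_frame,
            "landing_duration_s": self.landing_duration_s,
            "landing_angle_deg": self.landing_angle_deg,
            "takeoff_angle_deg": self.takeoff_angle_deg,
            "takeoff_speed_ms": self.takeoff_speed_ms,
            "net_rotation_deg": self.net_rotation_deg,
            "max_curvature": self.max_curvature,
            "peak_deceleration_ms2": self.peak_deceleration_ms2,
            "no_deceleration_flag": self.no_deceleration_flag,
            "landing_speed_ms": self.landing_speed_ms,
            "incidence_angle_deg": self.incidence_angle_deg,
            "v_perp_ms": self.v_perp_ms,
            "impact_force_n": self.impact_force_n,
            "impact_inertial_term_n": self.impact_inertial_term_n,
            "impact_gravitational_term_n": self.impact_gravitational_term_n,
        }
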
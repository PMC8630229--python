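"""Speed, acceleration and peak-deceleration extraction for marker tracks.

The differentiation scheme deliberately follows the frame-wise recipe used
for digitized high-speed video: per-frame displacement

    s_i = || r_{i+1} - r_i ||       (Euclidean norm, metres)

gives the frame-wise speed v_i = s_i / dt, and acceleration is the forward
difference of the speed, a_i = (v_{i+1} - v_i) / dt.  Speed is an unsigned
norm: a marker that reverses direction shows a speed minimum, not a sign
change, and a body part decelerating along its path shows negative a.
Peak deceleration over a window is -1 times the most negative acceleration.

Indexing: v_i spans positions [i, i+1]; a_i spans positions [i, i+2].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .io import MarkerTrack
from .smoothing import SmoothingSettings, smooth_series

__all__ = [
    "KinematicSeries",
    "smooth_track",
    "compute_velocity",
    "compute_acceleration",
    "max_deceleration",
    "PeakDeceleration",
]


@dataclass(frozen=True)
class KinematicSeries:
    """Displacement / speed / acceleration series for one marker.

    Lengths: len(speed) == n_frames - 1 and len(acceleration) == n_frames - 2.
    ``times`` are the frame times of the underlying positions.
    """

    marker_name: str
    times: np.ndarray
    displacement: np.ndarray  # m, frame-wise, >= 0
    speed: np.ndarray  # m/s
    acceleration: np.ndarray | None = None  # m/s^2

    def __post_init__(self) -> None:
        if np.any(self.displacement < 0):
            raise ValueError("displacement is a norm and cannot be negative")
        if len(self.speed) != len(self.times) - 1:
            raise ValueError("speed series must have length n_frames - 1")
        if self.acceleration is not None and len(self.acceleration) != len(self.speed) - 1:
            raise ValueError("acceleration series must have length n_frames - 2")


def smooth_track(
    track: MarkerTrack, settings: SmoothingSettings | None = None
) -> MarkerTrack:
    """Return a track of identical length and dt with x(t), y(t) smoothed by
    a quintic smoothing spline (shared GCV penalty across the two
    coordinates).  A degenerate all-identical track is returned unchanged."""
    if track.n_frames < 8:
        raise ValueError("smoothing a track requires at least 8 frames")
    if np.ptp(track.positions, axis=0).max() == 0.0:
        return track
    res = smooth_series(track.positions, settings)
    return MarkerTrack(track.marker_name, res.values, track.dt)


def compute_velocity(track: MarkerTrack) -> KinematicSeries:
    """Frame-wise speed of a (smoothed) track: Euclidean displacement per
    frame divided by the frame interval."""
    disp = np.linalg.norm(np.diff(track.positions, axis=0), axis=1)
    return KinematicSeries(
        marker_name=track.marker_name,
        times=track.times,
        displacement=disp,
        speed=disp / track.dt,
    )


def compute_acceleration(series: KinematicSeries) -> KinematicSeries:
    """Forward-difference acceleration of the speed series; decreasing speed
    yields negative values (deceleration)."""
    dt = float(series.times[1] - series.times[0])
    acc = np.diff(series.speed) / dt
    return KinematicSeries(
        marker_name=series.marker_name,
        times=series.times,
        displacement=series.displacement,
        speed=series.speed,
        acceleration=acc,
    )


class PeakDeceleration(NamedTuple):
    value: float  # m/s^2; -1 * min acceleration over the window
    decelerated: bool  # False flags a window with no deceleration at all

    def __float__(self) -> float:  # convenience for arithmetic in summaries
        return self.value


def max_deceleration(
    series: KinematicSeries, window: tuple[int, int]
) -> PeakDeceleration:
    """Peak deceleration over position-frame window [start, end] (inclusive).

    Acceleration sample a_i spans positions [i, i+2], so the usable indices
    are start .. end-2.  Returns -1 * min(a); if the marker never
    decelerates inside the window the value is non-positive and the
    ``decelerated`` flag is False.
    """
    if series.acceleration is None:
        raise ValueError("series has no acceleration; call compute_acceleration")
    start, end = window
    lo, hi = max(start, 0), min(end - 1, len(series.acceleration))
    if hi <= lo:
        raise ValueError(f"empty acceleration window {window}")
    seg = series.acceleration[lo:hi]
    amin = float(np.min(seg))
    return PeakDeceleration(value=-amin, decelerated=amin < 0)
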
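"""Data model, trajectory/summary file formats and analysis configuration.

Coordinate convention used throughout the package: x horizontal, y vertical
and increasing DOWNWARD, so gravitational acceleration is +y.  The animal
travels in the -x direction.  Positions are stored in metres, time in
seconds, 0-based frame indexing.  Readers normalize any declared input unit
(m / cm / mm / px with a scale) to this convention at read time.

Trajectory files are long-form delimited text::

    # jumpland trajectory v1
    # fps: 2000
    # units: m
    # individual: g1
    # treatment_deg: 90
    # mass_g: 42.1
    frame,time_s,marker,x,y
    0,0.0000,snout,0.31244,−0.05121
    ...

'#'-prefixed header lines carry trial metadata; explicit ``meta`` arguments
override them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MarkerTrack",
    "TrialRecording",
    "PlatformGeometry",
    "AnalysisConfig",
    "TrajectoryFormatError",
    "REQUIRED_MARKERS",
    "KNOWN_MARKERS",
    "read_trial",
    "write_trial",
    "write_summary",
    "read_summary",
]

REQUIRED_MARKERS = ("snout", "belly", "tail_base")
KNOWN_MARKERS = ("snout", "eye", "belly", "tail_base")

_UNIT_SCALE = {"m": 1.0, "cm": 0.01, "mm": 0.001}


class TrajectoryFormatError(ValueError):
    """A trajectory file violates the format contract."""


@dataclass(frozen=True)
class MarkerTrack:
    """Time series of one digitized marker: (x, y) positions in metres at a
    fixed frame interval ``dt`` (seconds)."""

    marker_name: str
    positions: np.ndarray  # (n, 2)
    dt: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] < 2:
            raise ValueError("positions must be an (n >= 2, 2) array")
        if not np.all(np.isfinite(pos)):
            raise TrajectoryFormatError(
                f"marker {self.marker_name!r} has non-finite coordinates"
            )
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        object.__setattr__(self, "positions", pos)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt

    @property
    def x(self) -> np.ndarray:
        return self.positions[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.positions[:, 1]


@dataclass(frozen=True)
class TrialRecording:
    """All marker tracks plus metadata for one jump."""

    trial_id: str
    individual_id: str
    mass: float  # kg
    treatment_deg: float  # landing surface incline
    fps: float
    tracks: Mapping[str, MarkerTrack]
    first_contact_annotation: int | None = None
    first_contact_part_annotation: str | None = None
    last_contact_annotation: int | None = None

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise ValueError("body mass must be positive")
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        missing = [m for m in REQUIRED_MARKERS if m not in self.tracks]
        if missing:
            raise TrajectoryFormatError(
                f"trial {self.trial_id!r} lacks required marker(s): "
                + ", ".join(missing)
            )
        lengths = {t.n_frames for t in self.tracks.values()}
        if len(lengths) != 1:
            raise TrajectoryFormatError("marker tracks differ in length")
        dts = {t.dt for t in self.tracks.values()}
        if len(dts) != 1:
            raise TrajectoryFormatError("marker tracks differ in dt")

    @property
    def dt(self) -> float:
        return 1.0 / self.fps

    @property
    def n_frames(self) -> int:
        return next(iter(self.tracks.values())).n_frames

    def with_tracks(self, tracks: Mapping[str, MarkerTrack]) -> "TrialRecording":
        return replace(self, tracks=dict(tracks))


@dataclass(frozen=True)
class PlatformGeometry:
    """Landing (or take-off) surface: an infinite line of incline ``incline_deg``
    through ``anchor``, with the standard experimental platform dimensions.

    ``approach_sign`` selects which side of the surface the animal
    approaches from; +1 matches steep platforms (45 deg ramp, 90 deg wall,
    approached from the open side) and -1 matches shallow platforms
    (animal above the surface).  The default follows the incline.
    """

    incline_deg: float
    anchor: tuple[float, float] = (0.0, 0.0)
    takeoff_height: float | None = None  # h_to, m
    landing_height: float | None = None  # h_l, m
    gap_distance: float | None = None  # d, m
    approach_sign: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.incline_deg <= 90.0:
            raise ValueError("incline must be between 0 and 90 degrees")
        if self.approach_sign is None:
            object.__setattr__(
                self, "approach_sign", 1 if self.incline_deg >= 45.0 else -1
            )
        elif self.approach_sign not in (-1, 1):
            raise ValueError("approach_sign must be +1 or -1")

    @property
    def in_plane(self) -> np.ndarray:
        """Unit in-plane direction (2-vector, y-down frame)."""
        phi = math.radians(self.incline_deg)
        return np.array([-math.cos(phi), math.sin(phi)])

    @property
    def in_plane_3d(self) -> np.ndarray:
        """In-plane direction as a 3-vector.  For the three standard
        treatments this is exactly the conventional (unnormalized)
        direction vector: (-1,0,0), (-1,1,0) or (0,1,0); normalization is
        irrelevant to the incidence-angle formula."""
        table = {0.0: (-1.0, 0.0, 0.0), 45.0: (-1.0, 1.0, 0.0), 90.0: (0.0, 1.0, 0.0)}
        if self.incline_deg in table:
            return np.array(table[self.incline_deg])
        return np.append(self.in_plane, 0.0)

    @property
    def outward_normal(self) -> np.ndarray:
        """Unit normal pointing toward the approaching animal."""
        phi = math.radians(self.incline_deg)
        return self.approach_sign * np.array([math.sin(phi), math.cos(phi)])

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Perpendicular distance(s) to the surface, positive on the
        approach side."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        d = (p - np.asarray(self.anchor)) @ self.outward_normal
        return d if np.asarray(points).ndim == 2 else float(d[0])


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the landing analysis."""

    g: float = 9.81  # m s^-2
    contact_epsilon: float = 0.002  # m, first-contact threshold
    smoothing_method: str = "gcv"
    smoothing_penalty: float | None = None
    landing_end_rule: str = "closest-approach"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.g > 0:
            raise ValueError("g must be positive")
        if not self.contact_epsilon > 0:
            raise ValueError("contact threshold must be positive")
        if self.landing_end_rule != "closest-approach":
            raise ValueError(
                f"unknown landing end rule {self.landing_end_rule!r}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> tuple["AnalysisConfig", PlatformGeometry | None]:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        geom = None
        if "platform" in raw:
            geom = PlatformGeometry(**raw.pop("platform"))
        return cls(**raw), geom

    def to_yaml(self, path: str | Path, geometry: PlatformGeometry | None = None) -> None:
        doc = {
            "g": self.g,
            "contact_epsilon": self.contact_epsilon,
            "smoothing_method": self.smoothing_method,
            "smoothing_penalty": self.smoothing_penalty,
            "landing_end_rule": self.landing_end_rule,
            "seed": self.seed,
        }
        if geometry is not None:
            doc["platform"] = {
                "incline_deg": geometry.incline_deg,
                "anchor": list(geometry.anchor),
                "takeoff_height": geometry.takeoff_height,
                "landing_height": geometry.landing_height,
                "gap_distance": geometry.gap_distance,
                "approach_sign": geometry.approach_sign,
            }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# ---------------------------------------------------------------------------
# trajectory files


def _parse_header(path: Path) -> dict:
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
    return meta


_META_NUMERIC = {
    "fps": float,
    "mass_g": float,
    "treatment_deg": float,
    "scale_m_per_unit": float,
    "first_contact_frame": int,
    "last_contact_frame": int,
}


def read_trial(path: str | Path, meta: Mapping | None = None) -> TrialRecording:
    """Read a trajectory file into a validated :class:`TrialRecording`.

    ``meta`` entries override header metadata.  Accepts the long form
    (columns frame, time_s, marker, x, y) or a wide form with per-marker
    ``<marker>_x`` / ``<marker>_y`` columns.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header = _parse_header(path)
    if meta:
        header.update(meta)
    for key, conv in _META_NUMERIC.items():
        if key in header and header[key] is not None and header[key] != "":
            header[key] = conv(header[key])

    if "fps" not in header:
        raise TrajectoryFormatError(f"{path}: fps missing from metadata")
    fps = float(header["fps"])
    units = str(header.get("units", "m"))
    if units == "px":
        if "scale_m_per_unit" not in header:
            raise TrajectoryFormatError(
                f"{path}: pixel coordinates need scale_m_per_unit metadata"
            )
        scale = float(header["scale_m_per_unit"])
    elif units in _UNIT_SCALE:
        scale = _UNIT_SCALE[units]
    else:
        raise TrajectoryFormatError(f"{path}: unknown units {units!r}")

    df = pd.read_csv(path, comment="#")
    tracks: dict[str, MarkerTrack] = {}
    if {"frame", "marker", "x", "y"}.issubset(df.columns):
        for name, grp in df.groupby("marker", sort=False):
            grp = grp.sort_values("frame")
            frames = grp["frame"].to_numpy()
            if len(frames) >= 2 and not np.array_equal(
                np.diff(frames), np.ones(len(frames) - 1, dtype=frames.dtype)
            ):
                raise TrajectoryFormatError(
                    f"{path}: marker {name!r} has non-uniform frame spacing"
                )
            xy = grp[["x", "y"]].to_numpy(dtype=float) * scale
            if not np.all(np.isfinite(xy)):
                raise TrajectoryFormatError(
                    f"{path}: marker {name!r} has non-finite coordinates"
                )
            tracks[str(name)] = MarkerTrack(str(name), xy, 1.0 / fps)
    else:
        found = [m for m in KNOWN_MARKERS if {f"{m}_x", f"{m}_y"}.issubset(df.columns)]
        if not found:
            raise TrajectoryFormatError(f"{path}: unrecognized column layout")
        for name in found:
            xy = df[[f"{name}_x", f"{name}_y"]].to_numpy(dtype=float) * scale
            if not np.all(np.isfinite(xy)):
                raise TrajectoryFormatError(
                    f"{path}: marker {name!r} has non-finite coordinates"
                )
            tracks[name] = MarkerTrack(name, xy, 1.0 / fps)

    mass_g = header.get("mass_g")
    if mass_g is None:
        raise TrajectoryFormatError(f"{path}: mass_g missing from metadata")
    part = header.get("first_contact_part") or None
    return TrialRecording(
        trial_id=str(header.get("trial_id", path.stem)),
        individual_id=str(header.get("individual", "unknown")),
        mass=float(mass_g) / 1000.0,
        treatment_deg=float(header.get("treatment_deg", 0.0)),
        fps=fps,
        tracks=tracks,
        first_contact_annotation=header.get("first_contact_frame"),
        first_contact_part_annotation=part,
        last_contact_annotation=header.get("last_contact_frame"),
    )


def write_trial(trial: TrialRecording, path: str | Path) -> None:
    """Write a trial in the long-form trajectory format (metres)."""
    path = Path(path)
    lines = [
        "# jumpland trajectory v1",
        "# convention: x horizontal, y down (gravity +y), units m",
        f"# trial_id: {trial.trial_id}",
        f"# individual: {trial.individual_id}",
        f"# treatment_deg: {trial.treatment_deg:g}",
        f"# mass_g: {trial.mass * 1000.0:.6f}",
        f"# fps: {trial.fps:g}",
        "# units: m",
    ]
    if trial.first_contact_annotation is not None:
        lines.append(f"# first_contact_frame: {trial.first_contact_annotation}")
    if trial.first_contact_part_annotation is not None:
        lines.append(f"# first_contact_part: {trial.first_contact_part_annotation}")
    if trial.last_contact_annotation is not None:
        lines.append(f"# last_contact_frame: {trial.last_contact_annotation}")
    lines.append("frame,time_s,marker,x,y")
    dt = trial.dt
    for name in KNOWN_MARKERS:
        if name not in trial.tracks:
            continue
        tr = trial.tracks[name]
        for i, (x, y) in enumerate(tr.positions):
            lines.append(f"{i},{i * dt:.9f},{name},{x:.10e},{y:.10e}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# per-trial summary table

SUMMARY_COLUMNS = [
    "trial_id",
    "individual_id",
    "treatment_deg",
    "mass_kg",
    "fps",
    "first_contact_frame",
    "first_contact_time_s",
    "first_contact_part",
    "landing_end_frame",
    "landing_duration_s",
    "landing_angle_deg",
    "takeoff_angle_deg",
    "takeoff_speed_ms",
    "net_rotation_deg",
    "max_curvature",
    "peak_deceleration_ms2",
    "no_deceleration_flag",
    "landing_speed_ms",
    "incidence_angle_deg",
    "v_perp_ms",
    "impact_force_n",
    "impact_inertial_term_n",
    "impact_gravitational_term_n",
]


def write_summary(summaries: Sequence, path: str | Path) -> pd.DataFrame:
    """Write one row per trial with every derived quantity.

    ``summaries`` is a sequence of :class:`jumpland.landing.LandingSummary`.
    The column schema is :data:`SUMMARY_COLUMNS`; missing optional metrics
    are written as empty fields.
    """
    if len(summaries) == 0:
        raise ValueError("refusing to write an empty summary table")
    rows = [s.as_row() for s in summaries]
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    df.to_csv(path, index=False, float_format="%.12g")
    return df


def read_summary(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
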
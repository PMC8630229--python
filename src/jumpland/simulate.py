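"""Forward simulator of jump-and-land trials with known ground truth.

Emulates 2000 fps digitized marker data (snout, ventral eye, belly, tail
base) for jumps onto horizontal, 45-degree and vertical landing platforms.
Treatment presets default to the experimentally reported group means for
contact speed, landing duration, peak deceleration, maximum body curvature
and landing angle, with the published platform geometry and body-size
ranges.

Construction, per trial (y-down coordinates, travel in -x):

* the belly follows exact projectile motion during flight; the flight is
  built BACKWARD from the prescribed contact state (speed v*, incidence
  angle alpha* against the platform), so take-off speed and angle are
  derived ground truths and energy bookkeeping (v_contact^2 = v_takeoff^2
  + 2 g * height drop) holds identically;
* a push-off phase (raised-cosine acceleration along the take-off
  direction over ~5 cm) precedes flight so that take-off is an interior
  event of the recording;
* after contact the belly speed decays with a gentle linear slope plus a
  raised-cosine deceleration pulse whose peak equals the preset peak
  deceleration exactly and which ends at the preset landing duration T*;
  the perpendicular approach rate is shaped (quarter-cosine plus a small
  constant creep, reversing at T*) so the belly's closest approach to the
  surface falls exactly at T*;
* snout / eye / tail-base ride on a rigid chord of length ~SVL with the
  configured pitch profile; the belly deflects from the chord so that
  curvature q/p ramps smoothly from a flight value to the preset maximum
  at T*;
* i.i.d. Gaussian digitization noise (default sd 0.5 mm) is added to every
  coordinate of every marker; a fixed seed gives bit-identical output.

The published take-off-speed means cannot serve as independent presets:
projectile motion conserves the horizontal velocity component, which for
the prescribed contact states already exceeds some of those means.  They
are retained in :data:`TAKEOFF_SPEED_REFERENCE_MS` for comparison only.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .impact import ImpactInputs, impact_force
from .io import MarkerTrack, PlatformGeometry, TrialRecording, write_trial

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "PRESETS",
    "MASS_RANGE_KG",
    "SVL_RANGE_M",
    "TAKEOFF_SPEED_REFERENCE_MS",
    "preset_config",
    "simulate_jump",
    "simulate_study",
]

# experimentally reported body-size ranges
MASS_RANGE_KG = (0.0359, 0.0492)
SVL_RANGE_M = (0.1137, 0.1274)

# reported take-off-speed treatment means (m/s); reference only, see module
# docstring
TAKEOFF_SPEED_REFERENCE_MS = {"horizontal": 1.75, "inclined": 1.44, "vertical": 1.41}


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of one simulated jump.

    Landing-phase presets (contact_speed, duration, peak_decel,
    max_curvature, landing_angle) default to the reported treatment means;
    the incidence angle is a simulator convention (it was not reported) —
    perpendicular for the vertical treatment, moderately oblique otherwise.
    """

    treatment: str = "vertical"
    incline_deg: float = 90.0
    takeoff_height: float = 0.528  # h_to, m
    landing_height: float = 0.428  # h_l, m
    gap_distance: float = 0.255  # d, m
    fps: float = 2000.0
    mass_kg: float = 0.04255  # midpoint of the reported range
    svl_m: float = 0.12
    head_length_m: float = 0.02
    contact_speed: float = 1.66  # v*, m/s
    incidence_deg: float = 90.0  # alpha*
    duration: float = 0.0697  # T*, s
    peak_decel: float = 120.0  # a*, m/s^2
    max_curvature: float = 0.51  # c*
    flight_curvature: float = 0.15  # skydiving-posture bow
    landing_angle_deg: float = 35.0  # gamma*, head pitch at contact
    net_rotation_deg: float = 0.0  # aerial pitch change (none observed)
    noise_sd: float = 0.0005  # m
    g: float = 9.81
    # landing-profile conventions
    gentle_fraction: float = 0.3  # share of speed shed outside the pulse
    residual_speed_frac: float = 0.05
    creep_speed: float = 0.08  # m/s, late perpendicular approach rate
    rebound_speed: float = 0.06  # m/s, separation rate after T*
    closest_distance: float = 0.001  # m, belly-plane distance at T*
    push_length: float = 0.05  # m
    flight_time: float | None = None  # s; derived from geometry if None
    post_time: float = 0.03  # s recorded beyond T*

    def __post_init__(self) -> None:
        for name in (
            "fps", "mass_kg", "svl_m", "contact_speed", "duration",
            "peak_decel", "max_curvature", "g", "push_length",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.incidence_deg < 180.0:
            raise ValueError("incidence angle must lie strictly in (0, 180)")
        if self.duration < 2.0 / self.fps:
            raise ValueError("landing duration shorter than two frames")


_PRESET_FIELDS = dict(
    horizontal=dict(
        treatment="horizontal", incline_deg=0.0,
        takeoff_height=0.520, landing_height=0.260, gap_distance=0.435,
        contact_speed=1.75, incidence_deg=60.0, duration=0.0177,
        peak_decel=1019.0, max_curvature=0.29, landing_angle_deg=30.2,
    ),
    inclined=dict(
        treatment="inclined", incline_deg=45.0,
        takeoff_height=0.520, landing_height=0.583, gap_distance=0.235,
        contact_speed=1.81, incidence_deg=65.0, duration=0.0446,
        peak_decel=449.0, max_curvature=0.35, landing_angle_deg=26.8,
    ),
    vertical=dict(
        treatment="vertical", incline_deg=90.0,
        takeoff_height=0.528, landing_height=0.428, gap_distance=0.255,
        contact_speed=1.66, incidence_deg=90.0, duration=0.0697,
        peak_decel=120.0, max_curvature=0.51, landing_angle_deg=35.0,
    ),
)

PRESETS = tuple(_PRESET_FIELDS)


def preset_config(name: str, **overrides) -> SimulationConfig:
    """Treatment preset ('horizontal' | 'inclined' | 'vertical') with
    optional field overrides."""
    if name not in _PRESET_FIELDS:
        raise KeyError(f"unknown preset {name!r}; choose from {PRESETS}")
    fields = dict(_PRESET_FIELDS[name])
    fields.update(overrides)
    return SimulationConfig(**fields)


@dataclass(frozen=True)
class GroundTruth:
    """True values of every quantity the analysis pipeline estimates."""

    trial_id: str
    treatment: str
    incline_deg: float
    mass_kg: float
    contact_frame: int
    takeoff_frame: int
    duration: float  # T*, s
    contact_speed: float  # v*, m/s
    incidence_deg: float  # alpha*
    v_perp: float  # v* sin(alpha*)
    peak_decel: float
    max_curvature: float
    landing_angle_deg: float
    takeoff_angle_deg: float  # head pitch at take-off
    net_rotation_deg: float
    takeoff_speed: float  # derived from backward ballistics
    takeoff_velocity_angle_deg: float  # flight-path angle above horizontal
    impact_force_n: float  # closed form on the true inputs
    first_contact_marker: str

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def _rc(u: np.ndarray) -> np.ndarray:
    """Raised-cosine ramp: 0 below 0, 1 above 1, smooth in between."""
    u = np.clip(u, 0.0, 1.0)
    return u - np.sin(2.0 * np.pi * u) / (2.0 * np.pi)


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perp_toward(u: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Unit vector perpendicular to u with a positive component along ref."""
    cand = np.array([-u[1], u[0]])
    return cand if float(cand @ ref) >= 0.0 else -cand


def _cumtrapz(f: np.ndarray, h: float) -> np.ndarray:
    out = np.empty_like(f)
    out[0] = 0.0
    np.cumsum(0.5 * (f[1:] + f[:-1]) * h, out=out[1:])
    return out


def simulate_jump(
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
    trial_id: str = "sim",
    individual_id: str = "sim",
) -> tuple[TrialRecording, GroundTruth, PlatformGeometry]:
    """Simulate one jump; returns the (noisy) recording, its ground truth
    and the landing-platform geometry (anchored at the contact point)."""
    rng = np.random.default_rng(rng)
    c = config
    dt = 1.0 / c.fps
    geom = PlatformGeometry(
        incline_deg=c.incline_deg,
        anchor=(0.0, 0.0),
        takeoff_height=c.takeoff_height,
        landing_height=c.landing_height,
        gap_distance=c.gap_distance,
    )
    h_hat = geom.in_plane
    e_hat = geom.outward_normal

    # --- contact state -----------------------------------------------------
    alpha = math.radians(c.incidence_deg)
    v_dir = math.cos(alpha) * h_hat - math.sin(alpha) * e_hat
    v_contact = c.contact_speed * v_dir

    # --- body geometry at contact ------------------------------------------
    beta_land = math.radians(c.landing_angle_deg)
    u_land = np.array([-math.cos(beta_land), -math.sin(beta_land)])
    w_land = _perp_toward(u_land, -e_hat)  # bow deflects toward the surface
    p0 = c.svl_m
    q0 = c.flight_curvature * p0
    offsets = {
        "snout": -q0 * w_land + 0.5 * p0 * u_land,
        "tail_base": -q0 * w_land - 0.5 * p0 * u_land,
        "belly": np.zeros(2),
    }
    offsets["eye"] = offsets["snout"] - c.head_length_m * u_land
    off_n = {m: float(o @ e_hat) for m, o in offsets.items()}
    contact_marker = min(off_n, key=off_n.get)
    s_belly0 = -off_n[contact_marker]  # belly-plane distance at contact
    r_contact = s_belly0 * e_hat  # anchor is the contact point

    # --- landing speed profile ---------------------------------------------
    v_end = c.residual_speed_frac * c.contact_speed
    dv = c.contact_speed - v_end
    a1 = c.gentle_fraction * dv / c.duration
    if c.peak_decel <= a1:
        raise ValueError("peak deceleration too small for the speed/duration preset")
    w_pulse = 2.0 * (1.0 - c.gentle_fraction) * dv / (c.peak_decel - a1)
    if w_pulse > c.duration:
        raise ValueError("peak deceleration too small: pulse exceeds the landing")
    t_pulse0 = c.duration - w_pulse  # pulse ends exactly at T*

    # --- perpendicular approach profile ------------------------------------
    v_perp_true = c.contact_speed * math.sin(alpha)
    budget = s_belly0 - min(c.closest_distance, 0.5 * s_belly0)
    v_creep = min(c.creep_speed, 0.5 * budget / c.duration)
    amp = max(v_perp_true - v_creep, 1e-9)
    t_quart = math.pi * max(budget - v_creep * c.duration, 0.0) / (2.0 * amp)
    t_quart = float(np.clip(t_quart, 4.0 * dt, c.duration))

    # --- sample the landing on a fine grid ----------------------------------
    sub = dt / 8.0
    n_land_frames = int(math.ceil((c.duration + c.post_time) / dt))
    tt = np.arange(n_land_frames * 8 + 1) * sub
    V = np.where(
        tt <= c.duration,
        c.contact_speed - a1 * tt - (1.0 - c.gentle_fraction) * dv
        * _rc((tt - t_pulse0) / w_pulse),
        v_end * np.exp(-(tt - c.duration) / 0.005) + c.rebound_speed,
    )
    V = np.maximum(V, 0.0)
    vn_plan = np.where(
        tt <= c.duration,
        -(amp * np.cos(np.clip(tt / t_quart, 0.0, 1.0) * (math.pi / 2.0)) + v_creep),
        c.rebound_speed * (1.0 - np.exp(-(tt - c.duration) / 0.002)),
    )
    vn = np.sign(vn_plan) * np.minimum(np.abs(vn_plan), V)
    tang_sign = 1.0 if math.cos(alpha) >= 0.0 else -1.0
    vs = tang_sign * np.sqrt(np.maximum(V**2 - vn**2, 0.0))
    s_land = s_belly0 + _cumtrapz(vn, sub)
    l_land = _cumtrapz(vs, sub)

    # --- flight (backward ballistics) and full marker assembly --------------
    # The flight time is shortened adaptively until the whole approach stays
    # clear of the (infinite) landing plane: a long backward-constructed
    # parabola can otherwise cross the plane's level far from the platform,
    # which a finite board would never intersect.
    grav = np.array([0.0, c.g])
    beta_to = c.landing_angle_deg - c.net_rotation_deg

    def _assemble(t_flight: float):
        v_takeoff = v_contact - grav * t_flight
        r_takeoff = r_contact - v_contact * t_flight + 0.5 * grav * t_flight**2
        v0 = float(np.linalg.norm(v_takeoff))
        takeoff_dir = v_takeoff / v0
        t_push = 2.0 * c.push_length / v0

        i_contact = int(math.ceil((t_flight + t_push) / dt)) + 2
        n_frames = i_contact + n_land_frames + 1
        times = (np.arange(n_frames) - i_contact) * dt
        belly = np.empty((n_frames, 2))

        in_land = times >= 0.0
        idx_land = np.round(times[in_land] / sub).astype(int)
        belly[in_land] = (
            s_land[idx_land][:, None] * e_hat + l_land[idx_land][:, None] * h_hat
        )
        in_flight = (times < 0.0) & (times >= -t_flight)
        tfc = times[in_flight][:, None]
        belly[in_flight] = r_contact + v_contact * tfc + 0.5 * grav * tfc**2
        in_push = times < -t_flight
        tau = times[in_push] + t_flight + t_push  # time since push start
        dist = v0 * t_push * _irc(np.clip(tau, 0.0, t_push) / t_push)
        belly[in_push] = r_takeoff + (dist - c.push_length)[:, None] * takeoff_dir

        beta = np.full(n_frames, c.landing_angle_deg)
        beta[in_push] = beta_to
        beta[in_flight] = beta_to + c.net_rotation_deg * (
            (times[in_flight] + t_flight) / t_flight
        )
        curvp = np.where(
            times < 0.0,
            c.flight_curvature,
            c.flight_curvature
            + (c.max_curvature - c.flight_curvature)
            * _smoothstep(times / c.duration),
        )
        b_rad = np.radians(beta)
        u_axis = np.stack([-np.cos(b_rad), -np.sin(b_rad)], axis=1)
        w_all = np.stack([-u_axis[:, 1], u_axis[:, 0]], axis=1)
        w_all[(w_all @ w_land) < 0.0] *= -1.0
        center = belly - (curvp * p0)[:, None] * w_all
        positions = {
            "belly": belly,
            "snout": center + 0.5 * p0 * u_axis,
            "tail_base": center - 0.5 * p0 * u_axis,
        }
        positions["eye"] = positions["snout"] - c.head_length_m * u_axis
        aux = dict(
            i_contact=i_contact,
            takeoff_frame=int(round(i_contact - t_flight / dt)),
            v0=v0,
            theta_to=math.degrees(math.atan2(-v_takeoff[1], -v_takeoff[0])),
        )
        return positions, aux

    if c.flight_time is not None:
        t_flight = c.flight_time
    else:
        vx = max(abs(v_contact[0]), 0.3)
        t_flight = float(np.clip(c.gap_distance / vx, 0.10, 0.25))
    margin = max(0.004, 6.0 * c.noise_sd)
    # frames this close to contact are legitimately inside the margin
    n_near = 4 + int(math.ceil(margin / (max(v_perp_true, 0.1) * dt)))
    positions = aux = None
    for _ in range(15):
        t_flight = max(round(t_flight / dt), 8) * dt  # take-off on the grid
        positions, aux = _assemble(t_flight)
        pre = slice(0, aux["i_contact"] - n_near)
        clearance = min(
            float(np.min(geom.signed_distance(p[pre]))) for p in positions.values()
        )
        if clearance > margin:
            break
        t_flight *= 0.85
    else:
        raise ValueError("no clear ballistic approach for this configuration")

    if c.noise_sd > 0.0:
        for name in positions:
            positions[name] = positions[name] + rng.normal(
                0.0, c.noise_sd, positions[name].shape
            )

    takeoff_frame = aux["takeoff_frame"]
    tracks = {
        name: MarkerTrack(name, pos, dt) for name, pos in positions.items()
    }
    trial = TrialRecording(
        trial_id=trial_id,
        individual_id=individual_id,
        mass=c.mass_kg,
        treatment_deg=c.incline_deg,
        fps=c.fps,
        tracks=tracks,
        last_contact_annotation=takeoff_frame,
    )
    fi = impact_force(
        ImpactInputs(
            mass=c.mass_kg,
            speed=c.contact_speed,
            duration=c.duration,
            alpha_deg=c.incidence_deg,
            incline_deg=c.incline_deg,
            g=c.g,
        )
    )
    truth = GroundTruth(
        trial_id=trial_id,
        treatment=c.treatment,
        incline_deg=c.incline_deg,
        mass_kg=c.mass_kg,
        contact_frame=aux["i_contact"],
        takeoff_frame=takeoff_frame,
        duration=c.duration,
        contact_speed=c.contact_speed,
        incidence_deg=c.incidence_deg,
        v_perp=fi.v_perp,
        peak_decel=c.peak_decel,
        max_curvature=c.max_curvature,
        landing_angle_deg=c.landing_angle_deg,
        takeoff_angle_deg=beta_to,
        net_rotation_deg=c.net_rotation_deg,
        takeoff_speed=aux["v0"],
        takeoff_velocity_angle_deg=aux["theta_to"],
        impact_force_n=fi.impact_force,
        first_contact_marker=contact_marker,
    )
    return trial, truth, geom


def _irc(u: np.ndarray) -> np.ndarray:
    """Integral of the raised-cosine ramp from 0 to u (u in [0, 1])."""
    u = np.clip(u, 0.0, 1.0)
    return 0.5 * u * u + (np.cos(2.0 * np.pi * u) - 1.0) / (4.0 * np.pi**2)


# ---------------------------------------------------------------------------
# study-level simulation


def _jitter_config(
    base: SimulationConfig, rng: np.random.Generator, cv: float
) -> SimulationConfig:
    """Per-trial biological variation: log-normal jitter on strictly
    positive landing quantities, normal on angles (clipped at 2.5 sd)."""
    if cv <= 0.0:
        return base
    sigma = math.sqrt(math.log(1.0 + cv * cv))

    def logn(x: float) -> float:
        z = float(np.clip(rng.standard_normal(), -2.5, 2.5))
        return x * math.exp(sigma * z - 0.5 * sigma * sigma)

    def norm(x: float, lo: float, hi: float) -> float:
        z = float(np.clip(rng.standard_normal(), -2.5, 2.5))
        return float(np.clip(x + cv * abs(x) * z, lo, hi))

    return replace(
        base,
        contact_speed=logn(base.contact_speed),
        duration=logn(base.duration),
        peak_decel=logn(base.peak_decel),
        max_curvature=logn(base.max_curvature),
        landing_angle_deg=norm(base.landing_angle_deg, -80.0, 80.0),
        incidence_deg=norm(base.incidence_deg, 5.0, 175.0),
    )


def simulate_study(
    treatments: Sequence[str] = PRESETS,
    n_individuals: int = 4,
    n_trials: int = 3,
    seed: int = 0,
    out_dir: str | Path | None = None,
    jitter_cv: float = 0.10,
    noise_sd: float = 0.0005,
    overrides: dict | None = None,
) -> list[tuple[TrialRecording, GroundTruth, PlatformGeometry]]:
    """Simulate a full study: ``n_trials`` jumps per individual per
    treatment, with per-individual body size drawn from the reported ranges
    and per-trial log-normal/normal jitter (coefficient of variation
    ``jitter_cv``) on the landing ground truths.

    When ``out_dir`` is given, writes one trajectory file and one
    ground-truth JSON sidecar per trial plus a ``manifest.csv``.
    """
    if n_individuals < 1 or n_trials < 1:
        raise ValueError("need at least one individual and one trial")
    rng = np.random.default_rng(seed)
    individuals = []
    for i in range(n_individuals):
        individuals.append(
            dict(
                individual_id=f"gecko{i + 1}",
                mass_kg=float(rng.uniform(*MASS_RANGE_KG)),
                svl_m=float(rng.uniform(*SVL_RANGE_M)),
            )
        )
    results = []
    manifest_rows = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    for treatment in treatments:
        for ind in individuals:
            for k in range(n_trials):
                base = preset_config(
                    treatment,
                    mass_kg=ind["mass_kg"],
                    svl_m=ind["svl_m"],
                    noise_sd=noise_sd,
                    **(overrides or {}),
                )
                cfg = _jitter_config(base, rng, jitter_cv)
                tid = f"{treatment}_{ind['individual_id']}_t{k + 1}"
                trial, truth, geom = simulate_jump(
                    cfg, rng, trial_id=tid, individual_id=ind["individual_id"]
                )
                results.append((trial, truth, geom))
                if out_path is not None:
                    traj = out_path / f"{tid}.csv"
                    side = out_path / f"{tid}.truth.json"
                    write_trial(trial, traj)
                    truth.to_json(side)
                    manifest_rows.append(
                        dict(
                            trial_id=tid,
                            individual=ind["individual_id"],
                            treatment=treatment,
                            treatment_deg=cfg.incline_deg,
                            mass_g=cfg.mass_kg * 1000.0,
                            fps=cfg.fps,
                            trajectory=traj.name,
                            truth=side.name,
                        )
                    )
    if out_path is not None:
        pd.DataFrame(manifest_rows).to_csv(out_path / "manifest.csv", index=False)
    return results
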
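"""End-to-end drivers: one trial -> LandingSummary; many trials -> study
statistics.

Per trial: smooth every marker track once (quintic spline, shared GCV
penalty per marker), detect first contact and the landing end, then derive
all landing metrics and the projected impact force from the smoothed
coordinates.  Per study: collect summaries, average trials per individual
x treatment, and push each metric through the assumption-gated comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import impact as imp
from . import landing as lm
from .io import AnalysisConfig, PlatformGeometry, TrialRecording, read_trial
from .kinematics import (
    compute_acceleration,
    compute_velocity,
    max_deceleration,
    smooth_track,
)
from .smoothing import SmoothingSettings
from .stats import TestReport, compare_inclines, regress

__all__ = ["analyze_trial", "analyze_study", "StudyResult", "STUDY_METRICS"]

# metric column -> offset applied before the log transform on the stats
# branch (the landing angle may be negative; a +3 degree shift precedes it)
STUDY_METRICS = {
    "takeoff_speed_ms": 0.0,
    "landing_angle_deg": 3.0,
    "net_rotation_deg": 90.0,
    "max_curvature": 0.0,
    "landing_speed_ms": 0.0,
    "peak_deceleration_ms2": 0.0,
    "landing_duration_s": 0.0,
    "impact_force_n": 0.0,
}


def _smoothed(trial: TrialRecording, config: AnalysisConfig) -> TrialRecording:
    settings = SmoothingSettings(
        method=config.smoothing_method, penalty=config.smoothing_penalty
    )
    return trial.with_tracks(
        {name: smooth_track(t, settings) for name, t in trial.tracks.items()}
    )


def analyze_trial(
    trial: TrialRecording,
    geometry: PlatformGeometry,
    config: AnalysisConfig | None = None,
    takeoff_geometry: PlatformGeometry | None = None,
) -> lm.LandingSummary:
    """Compute every landing metric for a single jump.

    ``takeoff_geometry`` enables auto-detection of the last take-off
    contact when the trial carries no annotation; without either, the
    take-off metrics are left empty.
    """
    config = config or AnalysisConfig()
    smoothed = _smoothed(trial, config)

    contact = lm.detect_first_contact(smoothed, geometry, config.contact_epsilon)
    t0 = contact.frame
    duration, end = lm.landing_duration(smoothed, geometry, t0)

    belly = smoothed.tracks["belly"]
    vel = compute_acceleration(compute_velocity(belly))
    peak = max_deceleration(vel, (t0, end))

    v_vec = imp.landing_velocity_vector(belly, t0)
    speed = float(np.linalg.norm(v_vec))
    alpha = imp.incidence_angle(v_vec, geometry)
    result = imp.impact_force(
        imp.ImpactInputs(
            mass=trial.mass,
            speed=speed,
            duration=duration,
            alpha_deg=alpha,
            incline_deg=geometry.incline_deg,
            g=config.g,
        )
    )

    curv = lm.body_curvature(smoothed, (t0, end))
    gamma = lm.head_angle(smoothed, t0)

    takeoff_angle = takeoff_speed = net_rot = None
    tko = None
    if smoothed.last_contact_annotation is not None:
        tko = int(smoothed.last_contact_annotation)
    elif takeoff_geometry is not None:
        try:
            tko = lm.takeoff_velocity_frame(
                smoothed, takeoff_geometry, config.contact_epsilon
            )
        except lm.NoContactError:
            tko = None
    if tko is not None and 0 < tko < t0:
        takeoff_angle = lm.head_angle(smoothed, tko)
        takeoff_speed = float(vel.speed[tko]) if tko < len(vel.speed) else None
        net_rot, _ = lm.aerial_rotation(smoothed, (tko, t0))

    return lm.LandingSummary(
        trial_id=trial.trial_id,
        individual_id=trial.individual_id,
        treatment_deg=trial.treatment_deg,
        mass_kg=trial.mass,
        fps=trial.fps,
        first_contact_frame=t0,
        first_contact_part=contact.part,
        landing_end_frame=end,
        landing_duration_s=duration,
        max_curvature=curv.max_curvature,
        peak_deceleration_ms2=peak.value,
        no_deceleration_flag=not peak.decelerated,
        landing_speed_ms=speed,
        incidence_angle_deg=alpha,
        v_perp_ms=result.v_perp,
        impact_force_n=result.impact_force,
        impact_inertial_term_n=result.inertial_term,
        impact_gravitational_term_n=result.gravitational_term,
        landing_angle_deg=gamma,
        takeoff_angle_deg=takeoff_angle,
        takeoff_speed_ms=takeoff_speed,
        net_rotation_deg=net_rot,
    )


@dataclass
class StudyResult:
    summaries: pd.DataFrame  # one row per trial
    reports: dict[str, TestReport]  # per metric
    regressions: dict[str, dict]  # named OLS fits


def analyze_study(
    trials: Sequence[tuple[TrialRecording, PlatformGeometry]],
    config: AnalysisConfig | None = None,
    metrics: Mapping[str, float] | None = None,
) -> StudyResult:
    """Analyze many trials and compare metrics across incline treatments.

    ``metrics`` maps summary columns to the log offset used on the
    transform branch (defaults to :data:`STUDY_METRICS`, restricted to
    columns that are actually populated).
    """
    config = config or AnalysisConfig()
    rows = [analyze_trial(t, g, config).as_row() for t, g in trials]
    df = pd.DataFrame(rows)

    metrics = dict(metrics if metrics is not None else STUDY_METRICS)
    reports: dict[str, TestReport] = {}
    comparable = (
        df["treatment_deg"].nunique() >= 2 and df["individual_id"].nunique() >= 2
    )
    for col, offset in metrics.items():
        if not comparable or col not in df.columns or df[col].isna().any():
            continue
        table = df[["individual_id", "treatment_deg", col]].rename(
            columns={col: "value"}
        )
        reports[col] = compare_inclines(table, metric=col, log_offset=offset)

    regressions: dict[str, dict] = {}
    if len(df) >= 3:
        regressions["curvature_vs_duration"] = regress(
            df["landing_duration_s"].to_numpy(), df["max_curvature"].to_numpy()
        )
        regressions["log_impact_vs_duration"] = regress(
            np.log10(df["impact_force_n"].to_numpy()),
            df["landing_duration_s"].to_numpy(),
        )
        for metric in ("landing_speed_ms", "landing_duration_s", "landing_angle_deg"):
            if df[metric].notna().all():
                regressions[f"{metric}_vs_mass"] = regress(
                    df[metric].to_numpy(), df["mass_kg"].to_numpy()
                )
    return StudyResult(summaries=df, reports=reports, regressions=regressions)


def load_manifest(
    manifest_path: str | Path,
) -> list[tuple[TrialRecording, PlatformGeometry]]:
    """Read a study manifest (as written by the simulator) into trial /
    geometry pairs; the landing platform is anchored at the origin."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    out = []
    for _, row in df.iterrows():
        trial = read_trial(manifest_path.parent / row["trajectory"])
        geom = PlatformGeometry(incline_deg=float(row["treatment_deg"]))
        out.append((trial, geom))
    return out
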
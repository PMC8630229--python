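"""Surface-incline-projected impact force of a jump landing.

The landing impact is modelled from the deceleration of the body's
approximate centre of mass (the belly marker).  With landing speed v,
landing duration T, body mass m, incidence angle alpha between the landing
velocity vector and the platform's in-plane direction, and platform incline
phi, the force projected on the surface normal collapses to the closed form

    F_i = m (v / T) sin(alpha) + m g cos(phi)

i.e. an inertial term (average deceleration v/T times the perpendicular
fraction of the motion) plus the gravitational projection.  The
perpendicular landing speed is v_perp = v sin(alpha).  Limiting cases:
a vertical wall (phi = 90) removes gravity from the impact entirely, and a
vanishing approach speed on a horizontal platform leaves the resting
weight m g.

The incidence angle comes from the platform's in-plane direction vector h:

    alpha = arccos( v . h / (|v| |h|) )

with h = (-1,0,0), (-1,1,0), (0,1,0) for the 0/45/90 degree treatments
(h may be unnormalized; the formula normalizes).  v/T is an
average-deceleration surrogate: the separately reported peak deceleration
(finite-difference route) is NOT substituted into the force equation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import MarkerTrack, PlatformGeometry

__all__ = [
    "ImpactInputs",
    "ImpactResult",
    "landing_velocity_vector",
    "incidence_angle",
    "impact_force",
    "predicted_adhesion",
    "safety_factor",
]


@dataclass(frozen=True)
class ImpactInputs:
    """Closed-form impact inputs.  Angles in degrees; omega = alpha - phi is
    the velocity vector's angle in the surface-aligned derivation."""

    mass: float  # kg
    speed: float  # m/s, belly speed at first contact
    duration: float  # s, landing duration T
    alpha_deg: float  # incidence angle, 0..180
    incline_deg: float  # platform incline phi, 0..90
    g: float = 9.81

    def __post_init__(self) -> None:
        if min(self.mass, self.speed, self.duration, self.g) <= 0:
            raise ValueError("mass, speed, duration and g must be positive")
        if not 0.0 <= self.alpha_deg <= 180.0:
            raise ValueError("incidence angle must lie in [0, 180] degrees")
        if not 0.0 <= self.incline_deg <= 90.0:
            raise ValueError("incline must lie in [0, 90] degrees")

    @property
    def omega_deg(self) -> float:
        return self.alpha_deg - self.incline_deg


@dataclass(frozen=True)
class ImpactResult:
    impact_force: float  # N
    v_perp: float  # m/s
    inertial_term: float  # m (v/T) sin alpha
    gravitational_term: float  # m g cos phi

    def __post_init__(self) -> None:
        # exact decomposition invariant
        assert math.isclose(
            self.impact_force,
            self.inertial_term + self.gravitational_term,
            rel_tol=0.0,
            abs_tol=1e-12,
        )


def landing_velocity_vector(belly: MarkerTrack, t0: int) -> np.ndarray:
    """Landing velocity 2-vector from the belly coordinates one frame before
    and directly at first contact (the track should already be smoothed)."""
    if t0 < 1:
        raise ValueError("first contact at frame 0: no preceding frame")
    if t0 >= belly.n_frames:
        raise ValueError("contact frame outside the track")
    return (belly.positions[t0] - belly.positions[t0 - 1]) / belly.dt


def incidence_angle(v: np.ndarray, geom: PlatformGeometry) -> float:
    """Angle (degrees, in [0, 180]) between the landing velocity vector and
    the platform's in-plane direction vector."""
    v = np.asarray(v, dtype=float)
    h = geom.in_plane_3d[:2]
    nv = float(np.linalg.norm(v))
    if nv == 0.0:
        raise ValueError("zero landing velocity has no incidence angle")
    c = float(np.dot(v, h) / (nv * np.linalg.norm(h)))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def _sind(deg: float) -> float:
    # exact at the axis angles so the limiting cases hold identically
    if deg % 180.0 == 0.0:
        return 0.0
    if deg % 360.0 == 90.0:
        return 1.0
    return math.sin(math.radians(deg))


def _cosd(deg: float) -> float:
    if deg % 180.0 == 90.0:
        return 0.0
    if deg % 360.0 == 0.0:
        return 1.0
    return math.cos(math.radians(deg))


def impact_force(inputs: ImpactInputs) -> ImpactResult:
    """Closed-form impact force with its inertial/gravitational terms."""
    inertial = inputs.mass * (inputs.speed / inputs.duration) * _sind(inputs.alpha_deg)
    gravitational = inputs.mass * inputs.g * _cosd(inputs.incline_deg)
    return ImpactResult(
        impact_force=inertial + gravitational,
        v_perp=inputs.speed * _sind(inputs.alpha_deg),
        inertial_term=inertial,
        gravitational_term=gravitational,
    )


# Griffing et al. scaling of single-forelimb frictional adhesion with body
# mass in C. ciliatus, read as a log10-log10 relation (the only reading
# consistent with the ~10 N figure it is quoted to produce):
#   log10(adhesion [N]) = 1.041 * log10(mass [g]) - 0.69
_ADHESION_SLOPE = 1.041
_ADHESION_INTERCEPT = -0.69


def predicted_adhesion(mass_g: float) -> float:
    """Predicted maximum single-forelimb frictional adhesion (N) for a
    crested gecko of ``mass_g`` grams."""
    if mass_g <= 0:
        raise ValueError("mass must be positive")
    return 10.0 ** (_ADHESION_SLOPE * math.log10(mass_g) + _ADHESION_INTERCEPT)


def safety_factor(adhesion: float, impact: float) -> float:
    """Available adhesive force over the force demanded at impact; values
    below 1 mean adhesive failure."""
    if impact <= 0:
        raise ValueError("impact force must be positive")
    return adhesion / impact
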
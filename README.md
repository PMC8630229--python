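# jumpland

Jump-landing biomechanics from digitized high-speed-video marker
trajectories, built around landings of pad-bearing geckos on landing
surfaces of different incline (horizontal, 45°, vertical).

Arboreal animals that leap across gaps must arrest their momentum on
whatever surface they hit.  For a gecko landing on a smooth surface the
cost of that arrest — the impact force pressing it against (or peeling it
off) the surface — depends on how fast it arrives, how long the landing
takes, and how the surface is tilted relative to the approach.  `jumpland`
turns 2-D marker tracks (snout, ventral eye, belly, tail base) into the
quantities a landing study needs and runs the treatment-level statistics,
for researchers analyzing digitized jump videos and for anyone who wants a
tested, simulated version of such a study.

## The model

Coordinates are x horizontal / y vertical-down (gravity positive), the
animal travelling in −x.  Per trial the pipeline computes, from
quintic-smoothing-spline coordinates (penalty by generalized
cross-validation):

- frame-wise speed v = s/Δt with s the Euclidean per-frame displacement,
  acceleration a = Δv/Δt, and the peak deceleration −min(a) over the
  landing;
- first contact t₀ (first frame any marker is within ε = 2 mm of the
  surface; manual annotations override), landing duration T (first contact
  to the belly's closest approach), landing angle γ (snout–eye line above
  horizontal), and body curvature q/p (belly deflection over snout–tail
  chord);
- the landing velocity vector **v** from the belly coordinates one frame
  before and at first contact, its incidence angle against the platform's
  in-plane direction **h**,

  α = arccos( **v**·**h** / |**v**||**h**| ),  with **h** = (−1,0,0),
  (−1,1,0), (0,1,0) for inclines φ = 0°, 45°, 90°;

- the surface-normal impact force

  F_i = m (v/T) sin α + m g cos φ,

  an inertial term (average deceleration v/T projected on the normal) plus
  the gravitational projection: a vertical wall (φ = 90°) removes gravity
  from the impact entirely, while v → 0 on the floor leaves the resting
  weight m g;
- single-forelimb frictional adhesion predicted from body mass by the
  log–log scaling 10^(1.041·log₁₀(mass in g) − 0.69), and the
  adhesion/impact safety factor.

Across trials, the statistics module averages trials per individual ×
treatment (pseudoreplication guard), gates on Shapiro–Wilk normality and
Levene variance homogeneity at α = 0.05, log-transforms and regates when a
gate fails, and routes to a repeated-measures ANOVA (random individual
intercept, dropped when a likelihood-ratio test does not support it) or a
Kruskal–Wallis test with Dunn's post hoc.  A forward simulator generates
2000 fps trials with known ground truth: ballistic flight into a
prescribed contact state, a shaped deceleration profile realizing the
preset landing duration and peak deceleration, a bowing body midline
realizing the preset maximum curvature, and Gaussian digitization noise
(0.5 mm default).

## Worked example

```python
from jumpland.impact import ImpactInputs, impact_force, predicted_adhesion, safety_factor

res = impact_force(ImpactInputs(mass=0.04255, speed=1.66, duration=0.0697,
                                alpha_deg=90.0, incline_deg=90.0))
print(f"F_i = {res.impact_force:.3f} N")
print(f"adhesion(42.55 g) = {predicted_adhesion(42.55):.2f} N")
print(f"safety factor = {safety_factor(predicted_adhesion(42.55), res.impact_force):.1f}")
```

prints

```
F_i = 1.013 N
adhesion(42.55 g) = 10.13 N
safety factor = 10.0
```

a 42.55 g gecko hitting a vertical wall perpendicularly at 1.66 m/s and
arresting over 69.7 ms experiences about 1 N of normal impact force — an
order of magnitude below what one forelimb's adhesion can hold.

End-to-end on synthetic data:

```bash
jumpland simulate --preset vertical --n-individuals 2 --n-trials 1 --seed 4 --out study
jumpland analyze-trial --trajectory study/vertical_gecko1_t1.csv --out out
# vertical_gecko1_t1: T = 72.0 ms, F_i = 0.94 N, curvature = 0.51
jumpland analyze-study --manifest study/manifest.csv --out results
```

The per-trial summary (one CSV row per jump) carries t₀, T, γ, take-off
speed/angle, net aerial rotation, maximum curvature, peak deceleration,
landing speed, α, v⊥, F_i and the first-contact body part;
`analyze-study` adds per-metric test reports (routing, omnibus and
post-hoc p-values, group mean ± SE) and the standard mass/curvature
regressions as JSON.

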
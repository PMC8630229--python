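# Methods

This note documents the models, conventions and numerical choices behind
`jumpland`, and what its synthetic-data tests do and do not establish.

## Coordinate and sign conventions

All computation uses x horizontal, y vertical increasing **downward**
(gravity +y), the animal travelling in −x, positions in metres, 0-based
frames, time = frame/fps.  Landing-phase time is re-anchored so first
contact is t = 0.  A landing surface is modelled as an infinite line of
incline φ through an anchor point; its in-plane direction is
h(φ) = (−cos φ, sin φ) — written as the conventional unnormalized
3-vectors (−1,0,0), (−1,1,0), (0,1,0) at 0/45/90° — and its outward unit
normal points toward the approaching animal (above the surface for
shallow inclines, on the open side for steep ones; `approach_sign`
overrides the default).  The incidence-angle formula normalizes
internally, so the unnormalized 45° vector is harmless (tested).

## Smoothing and differentiation

Digitization noise makes raw finite differences unusable at 2000 fps, so
each marker's x(t), y(t) are smoothed **once** by a penalized quintic
regression spline: degree-5 B-splines (≤ 120 basis functions, knots
uniform on the frame grid), penalty ∫f‴² chosen by generalized
cross-validation (GCV), jointly for x and y.  Design consequences:

- the penalty's null space contains quadratics, so a ballistic arc is
  never shrunk;
- a shared penalty per marker makes smoothing exactly equivariant under
  rotation and translation of the coordinate frame (tested to 1e-9);
- a fixed-penalty override exists for bitwise-reproducible runs.

Differentiation follows the frame-wise recipe exactly: speed is the
**norm** of the per-frame displacement over Δt (so direction reversals
produce speed minima, not sign changes), and acceleration is the forward
difference of speed.  Deceleration is negative acceleration; the per-trial
peak is −min(a) over the landing window, flagged if no deceleration
occurred.

**Known bias.** A single GCV penalty is chosen for the whole track, most
of which is smooth flight; the penalty that is optimal for positions
over-smooths brief deceleration pulses.  Quantified in the test suite: at
the default 0.5 mm noise the vertical-treatment peak deceleration is
recovered at ~0.75–0.80× its true value (noise-free: within ~2%), and the
horizontal treatment's ~2.4 ms pulse additionally exceeds the resolution
of the default basis (recovering it noise-free requires ~400 basis
functions, `SmoothingSettings(max_basis=...)`).  Landing duration,
curvature, contact speed and angles are insensitive to this.  Alternatives
(window-restricted smoothing; penalty selection by an unbiased-risk
criterion targeted at the second derivative) were evaluated and rejected
as noise-unstable.

## Landing metrics

- **First contact**: first frame any marker's perpendicular distance to
  the surface is ≤ ε (default ε = 2 mm, roughly toe-pad scale).  Because a
  marker approaching at v⊥ crosses the ε-shell ε/v⊥ before touching,
  detection runs ~2–3 frames early at typical approach speeds — a
  systematic, quantified bias of the threshold rule (annotations, which
  override detection, do not carry it).  Only snout/belly/tail-base
  categories can be auto-detected; forelimb/hindlimb first contact must be
  annotated (tail-base detections are reported as "hindlimb", the nearest
  anatomical category).
- **Landing duration**: first contact to the argmin of the belly's
  perpendicular surface distance (earliest frame on ties).  A belly still
  strictly approaching at the last frame is a "truncated landing" error.
- **Landing / take-off angle**: the undirected snout–ventral-eye line's
  angle above horizontal, folded into (−90°, 90°], positive = snout up;
  evaluated at first contact and at last take-off contact.  Net aerial
  rotation is the telescoped difference, so landing angle = take-off angle
  + net rotation identically.  Angles are reported signed; the +3° offset
  used before log-transforming the landing angle lives in the statistics
  layer only.
- **Curvature**: q/p with p the snout–tail-base chord and q the belly's
  perpendicular deflection from it; scale- and frame-invariant by
  construction; chords below 0.1 mm are skipped as degenerate.
- **Take-off**: last-contact frame from annotation, else the last frame
  the tail-base (hindlimb proxy) is within ε of the take-off plane;
  take-off speed is the smoothed belly speed at that frame.

## Impact force

F_i = m(v/T)·sin α + m·g·cos φ, with v the belly **speed** at first
contact (norm of the two-frame landing velocity vector), T the landing
duration, α from the arccos formula, φ the platform incline, g = 9.81 m/s²
by default.  v/T is an average-deceleration surrogate; the
finite-difference peak deceleration is reported alongside and never
substituted into the force equation.  Trigonometric factors are evaluated
exactly at multiples of 90° so the limiting cases (φ = 90° ⇒ ∂F_i/∂g = 0;
v → 0, φ = 0 ⇒ F_i = mg) hold identically.  The closed form is tested
against a brute-force projection of the planar force vector onto the
surface normal over 10⁵ random parameter draws (< 1e-10 N).

The adhesion scaling is read as log₁₀(adhesion in N) =
1.041·log₁₀(mass in g) − 0.69.  Read literally in linear units the printed
relation is dimensionally inconsistent with the ~10 N single-forelimb
figure it is cited to produce; the log–log reading reproduces that figure
at the midpoint of the studied 35.9–49.2 g mass range and is adopted.

## Statistics

Trials are averaged per individual × treatment before inference.  Gates:
Shapiro–Wilk per group and median-centred Levene across groups, both at
0.05; on failure the decadic log is applied (after the configured offset,
e.g. +3° for the landing angle; skipped if any shifted value is ≤ 0) and
the gates rerun; a second failure routes to Kruskal–Wallis on the raw
values (rank tests are invariant to the monotone transform), with Dunn's
test (pairwise rank-sum z with tie correction, unadjusted p by default) if
the omnibus test is significant, and a separate Kruskal–Wallis for the
individual effect.  On the parametric branch the random individual
intercept is kept only if a likelihood-ratio test of mixed model vs OLS on
χ²(1) supports it (conservative at the boundary); the omnibus is then a
repeated-measures ANOVA, otherwise a one-way ANOVA, with paired or
independent t contrasts under single-step Bonferroni adjustment.  Every
report records the gate p-values per stage, the transform and the route,
and identical input yields identical output.  Null calibration (500
simulated null datasets) puts the tree's omnibus type-I rate at ≈ 0.05.

## Synthetic data

The simulator emulates the study design: three incline treatments with
the published platform geometry, 4 individuals × 3 trials, body mass and
SVL drawn per individual from the studied ranges, 2000 fps.  Treatment
presets pin the landing-side ground truths to the reported group means —
contact speed 1.75/1.81/1.66 m/s, duration 17.7/44.6/69.7 ms, peak
deceleration 1019/449/120 m/s², maximum curvature 0.29/0.35/0.51, landing
angle 30.2/26.8/35.0° for horizontal/inclined/vertical.  Per-trial
biological variation is log-normal (CV 10% default) for positive
quantities and normal for angles; digitization noise is i.i.d. Gaussian,
sd 0.5 mm by default (manual-digitization error is unreported; this is a
labelled convention).

Choices where the real motion is unobserved, all pluggable per config
field:

- **Incidence angle** α* is not reported: 90° (perpendicular) for the
  vertical treatment, 60°/65° for horizontal/inclined, chosen for
  plausible ballistics.
- **Flight** is exact projectile motion constructed backward from the
  prescribed contact state, so energy bookkeeping holds identically and
  take-off speed/angle are *derived* ground truths.  The published
  take-off-speed means cannot be preset independently: projectile motion
  conserves horizontal velocity, which the prescribed contact states
  already exceed in some treatments.  The flight time is shortened
  adaptively until the whole approach clears the (infinite) surface plane
  — a long parabola may cross the plane's level far from where a finite
  board would be.
- **Deceleration profile**: a gentle linear decay carrying 30% of the
  speed loss plus a raised-cosine pulse carrying the rest, with pulse peak
  exactly the preset peak deceleration, ending at the preset duration T*.
  The reported peak/mean deceleration ratios (~5–10×) rule out a single
  full-width raised cosine.
- **Approach geometry**: the perpendicular approach rate follows a
  quarter-cosine plus a small constant creep, integrating to the belly's
  available approach distance, and reverses (0.06 m/s) at T*, so the
  closest approach is a well-defined interior minimum, as in the real
  protocol where digitization continued until motion toward the platform
  ended.  Recording continues 30 ms past T*.
- **Body**: a rigid chord of length SVL carries snout/tail-base (eye 2 cm
  behind the snout on the chord, so head angle equals body pitch); the
  belly's deflection from the chord ramps smoothly from a flight value of
  0.15 (skydiving posture) to the preset maximum at T*.  Pitch is constant
  in flight by default (no aerial rotation was observed) and frozen
  through the landing.

What passing recovery tests show: the pipeline's estimators are correct
and appropriately noise-robust for trajectories of this smoothness with
white digitization noise.  What they do not show: robustness to
correlated digitization error, marker occlusion/relabelling, tail motion
(the real tail keeps moving through landing and is not modelled), limb
kinematics, or surface compliance.

## Problem sizes

Simulated trials span ~500–800 frames.  Recovery experiments use 12
trials per treatment (the study's own per-treatment count); the null
calibration uses 500 datasets of 8 individuals × 3 treatments; the
projection-oracle check uses 10⁵ draws.  The full test suite runs in
about a minute; the acceptance script in under 30 s.
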
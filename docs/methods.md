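# Methods

This note records the model, the numerical choices and the design decisions
behind `trajkin`, and what the synthetic-data tests do and do not establish.

## Data model and preprocessing

A skeleton stream is a fixed-frequency sequence (frame *i* at time *i/f*) of
J labelled 3D joint positions in metres. Irregularly time-stamped input is
regularised by `resample` (linear interpolation) before analysis, because
all per-sample kinematic formulas assume constant *f*. Missing samples
(empty field or literal `NaN` in files) are linearly interpolated by
`fill_gaps` when the run is at most `max_gap` frames (default 5 — a
pragmatic bound for brief tracking losses, not a sensor specification);
longer runs are an error naming the joint and frame range. Runs touching
the stream boundary are filled by holding the nearest observed sample,
since linear interpolation is undefined there.

`smooth` applies a zero-phase 4th-order Butterworth low-pass (default
cutoff 6 Hz). Voluntary upper-limb motion is band-limited well below 6 Hz
while sensor jitter is broadband, so filtering before any differentiation
is standard motion-analysis practice; velocity estimates from unfiltered
depth-camera data are dominated by jitter (with 5 mm i.i.d. jitter at
30 Hz the speed-noise floor is several times the true hand speed).
Filtering is opt-in (`analyze_sequence(..., smooth_hz=6.0)`) so that
closed-form geometry tests can run on exact noise-free paths.

Units are metres internally everywhere; readers convert from declared
mm/cm, and the 41-parameter vector converts to its reporting units (mm,
cm², cm³, deg, m/s, deg/s, sr) only at assembly.

## Kinematic model

Nineteen LCS are built per frame from scratch (no temporal accumulation,
hence no drift). Each LCS recipe — origin joint (or midpoint), longitudinal
joint pair, reference joint pair — ships as an editable table
(`data/lcs_convention.csv`): Y = unit(long_to − long_from) (distal →
proximal), X = the reference direction orthogonalised against Y,
Z = X × Y. This is compatible in spirit with standard biomechanics
segment-frame recommendations but is necessarily a reduction: exact
anatomical frames cannot be constructed from 20 points. For arm segments
the primary reference (trunk-up) can become parallel to the segment axis
(arm hanging); within ~8° of parallel a per-segment fallback reference
(mediolateral) is used, and if both are degenerate the frame is an error
naming the LCS rather than a guess. The point-number ↔ joint mapping is
configuration data, not code, because a 25-joint skeleton should be a
config swap.

Link-length correction assumes the raw stick model supplies correct line
*orientation*: per frame, processing links root-outward, each child is
repositioned at the calibrated distance along the raw direction. Calibrated
lengths are the per-subject median child–parent distance over three static
calibration poses (median for robustness to jitter and brief losses). The
operation is idempotent and preserves directions exactly.

Relative trajectories pᵢ = Rₚᵀ(oᶜ − oₚ) are invariant under any rigid
transform of the global scene (verified by property test), except the one
global-parent entry, which transforms with the world by construction.

## The 41 parameters

* **Hodograph (params 1–9).** Forward differences define the speed
  sequence; the defining relation fixes only the length-N shape, so the
  last value is repeated. Standard deviations use the N−1 divisor. The
  step angle αᵢ = arcsin(2Sᵢ/(‖pᵢ‖‖pᵢ₊₁‖)) has its argument clamped to
  [−1, 1] against floating-point overshoot; steps subtending more than 90°
  are under-counted by the arcsin construction — documented, not corrected.
  Param 9 is mean speed over mean radius in deg/s, a mean angular rate
  consistent with Ω_Mean for near-circular motion.
* **Principal axes (params 10–30).** The point-mass inertia form
  (qᵀq)E − qqᵀ is used; the direction of maximum cloud spread is the
  minimum-inertia eigenvector. Eigenvector sign is fixed deterministically
  (largest-magnitude component positive). G2 = unit(p̄ × G1) is the printed
  construction — note G2 is *not* the second covariance axis; it is the
  normal of the plane containing G1 and the cloud-centre radius vector.
  When p̄ is (near-)parallel to G1 this is ill-posed: a deterministic
  perpendicular (smallest-component construction) is substituted and the
  affected entries flagged. Rhomboid area and diamond volume follow as
  LB₁LB₂/2 and S_mid·LB₃/3.
* **Sphere fit (params 31–37).** Kåsa algebraic solve
  ([2p | 1]·[c; k] = ‖p‖²) initialises a geometric Levenberg–Marquardt
  refinement of ‖pᵢ − c‖ − r. Coplanar/collinear clouds make the algebraic
  system singular (checked via its singular values); the fit is returned as
  NaN-with-flag, never as a silently enormous sphere, because planar wrist
  trajectories are common. Param 33 is the mean absolute radial residual,
  param 34 the standard deviation of signed residuals. The radius is
  reported in mm.
* **Hull metrics (params 38–41).** Convex hull via Qhull. The conic volume
  (apex at the LCS origin) is the signed tetrahedron sum over
  outward-oriented facets, which by the divergence theorem equals the hull
  volume for any apex position (cross-checked against `ConvexHull.volume`).
  The sphere solid angle is the closed-form cap 2π(1 − √(1 − (r/d)²)) for
  d > r, else 4π. The surface solid angle sums absolute
  van Oosterom–Strackee facet solid angles over facets whose outer side
  faces the origin, capped at 4π; an origin enclosed by the hull subtends
  4π. Coplanar clouds are flagged degenerate: the planar hull area is
  reported and the volume is 0.

The swept area Δ_N (the triangle-fan area) is not one of the 41 reported
parameters; it is computed and exported through the auxiliary channel.

Degenerate geometry never silently poisons a feature vector: affected
entries are NaN *with a flag*, and flagged entries are excluded from score
aggregation.

## Scoring

s = reference_mean / patient_value per (trajectory, parameter); a patient
value of zero gives a flagged, excluded score. Display values are clamped
to ±100 % so one outlier cannot dominate a star plot; raw values are kept
for longitudinal tracking. All weights default to 1 — no weight values are
published for this kind of panel, so unweighted means are the honest
default. The 17-member Ang(6)/Len(6)/Vol(5) display panel is a shipped,
clearly-marked package default (`data/default_panel.json`); signed
coordinate parameters (16–30) are excluded from it because ratios of signed
coordinates are not meaningful scores (opt-in via an explicit selection).
Contralateral scoring pairs `_L`/`_R` labels and is antisymmetric
(s ↔ 1/s) under side exchange.

## Validation statistics

RCP and CV are conventionally reported "as percentages" without a fixed
definition of the STD argument or the percentage base; here both default to
the std of paired differences over the pooled mean of both devices (the
usual method-comparison convention), with `basis="values"` as a switch.
Bonferroni correction is multiply-and-cap. Shapiro–Wilk delegates to
scipy's implementation.

## Synthetic motion generator

The generator emulates the study conditions the pipeline is meant for: a
20-joint skeleton at 30 Hz, a ~1 min wiping exercise (default duration
60 s) driven by mediolateral × inferior–superior wrist displacement
relative to the trunk, and three 3 s static calibration poses. The wrist
follows a Lissajous path (defaults: amplitudes 0.16/0.12 m, path
frequencies 0.25/0.20 Hz — chosen so the adult mean wrist speed after
standard filtering lands near 0.25 m/s, a realistic reaching speed); the
elbow follows by two-link IK (upper arm 0.30 m, forearm 0.25 m) with a
deterministic out-and-down bend. Lissajous paths were chosen over recorded
playback precisely because closed forms exist for their length, area and
axes, making the feature pipeline oracle-checkable.

Noise is i.i.d. isotropic Gaussian per joint per frame (default σ = 5 mm)
plus an optional depth-axis term (σ = 2 mm). This is deliberately the
simplest sensor model: real depth-camera error is temporally correlated,
pose-dependent and anisotropic, and real movement has physiological
variability and compensation strategies none of which are modelled. Group
differences are encoded purely as a speed multiplier
(adults 1.0 / elderly 0.57 / stroke 0.43, mirroring the clinically expected
ordering) with log-normal between-subject variability (speed CV 15 %,
amplitude CV 10 %, amplitude factor clipped to [0.7, 1.4] to stay inside
the arm's workspace). Passing tests therefore show the *pipeline* is
correct and the configured effect sizes are detectable at the configured
sample sizes — they do not show the scores discriminate real patient
populations.

All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical seeds give identical streams.

## Problem sizes used in tests

Unit and acceptance tests run the generator at 4–30 s duration (the
statistical checks use 6 s trials × 43 subjects × 20 replicates for power
and 4 s × 50 replicates for the null), sizes at which every check is
comfortably stable; the generator's 60 s default is unchanged.

## Known limitations

* LCS axes are a documented convention, not anatomical frames; absolute
  orientations are convention-dependent even though relative-trajectory
  invariants are not.
* The arcsin-based step angle saturates at 90° per step; grossly
  under-sampled fast rotations under-count Φ_N.
* The iterative sphere fit limits reproducibility of params 31–34/40 to
  about 10⁻⁶ relative on ill-conditioned (nearly planar) clouds.
* Joint-angle scoring consumes externally supplied angle tables; the
  package does not compute anatomical joint angles from the sparse
  skeleton.
* Smoothness (jerk-based) and frequency-domain descriptors are not
  implemented.
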
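# Methods

This note documents the models, conventions, and numerical choices behind
`gaitimpress`: what each stage assumes, which defaults matter, and what the
synthetic-data tests do and do not demonstrate about real data.

## Coordinate and cycle conventions

All positions are meters in the treadmill frame: x mediolateral, y
anterior–posterior with +y the walking direction, z vertical up, floor at
z = 0.  Readers re-axis on load if a capture system uses another convention.

The gait cycle is anchored at **right** foot contact: 0% and 100% are right
contacts, the left contact falls near 50%, left toe-off near 10%, right
toe-off near 60%.  This anchoring is forced by the phase windows the
features use (left push-off 0–10%, right push-off 50–60%, head-shake
windows 0–10 / 40–60 / 90–100% "around the foot contacts"): they are only
mutually consistent with a right-anchored cycle.  Phase windows are closed
intervals on the 101-point normalized grid (linear interpolation in time),
computed per cycle and then averaged across retained cycles.

## Preprocessing

* **Medial-marker reconstruction.** The medial elbow/knee/ankle markers are
  removed during walking; their position is expressed in the rigid local
  frame of three same-segment markers during a static calibration and
  re-applied per trial frame.  Accuracy depends on triad conditioning: with
  a well-spread triad and 1 mm jitter the RMS error is < 2 mm, but leg
  triads in this marker set are nearly collinear (all markers close to the
  segment axis), which amplifies noise geometrically to roughly 5–10 mm.
  The reference triads are configurable.
* **Joint centers.** Ankle, knee, and elbow are lateral–medial midpoints.
  The joints without marker pairs use calibration-free geometric rules
  collected in one policy object so alternative regressions can be swapped
  in: hip = greater trochanter displaced medially along the inter-ASIS axis
  by 25% of the inter-ASIS distance; lumbosacral = midpoint of the
  ASIS-pair and PSIS-pair centroids; thoracolumbar = centroid of sternum,
  T8, T12, and the two rib markers; neck = midpoint of C7 and sternum;
  shoulder = acromion displaced inferiorly by 0.17 × the trial-mean
  acromion-to-upper-arm-marker distance.  A vertical bias in an estimated
  center barely moves the alignment features, because A = r·sinθ equals the
  anterior–posterior offset of the distal end to first order.
* **Filtering.** A 4th-order Butterworth low-pass at 6 Hz, applied
  forward–backward (zero phase lag, DC gain exactly 1, −6 dB at the
  cut-off because the two passes square the magnitude response).  Centers
  are computed first and then filtered (a config switch filters markers
  first instead; the processing order is not fully determined by standard
  practice and changes results only marginally for band-limited motion).
* **Gaps.** Interior gaps of ≤ 10 frames are filled by cubic interpolation
  before filtering; longer gaps are an error, never imputed.

## Event detection and segmentation

Foot contact is the local maximum of the heel marker's anterior position
relative to the pelvis centroid; toe-off is the local minimum of the toe
marker's relative anterior position.  This coordinate-based definition is
the standard choice for treadmill data without force plates.  Detection
runs on the raw heel/toe markers smoothed at 6 Hz (independent of the
feature-filter settings), refines each extremum to sub-frame precision with
a three-point parabolic fit, and discards extrema within 0.25 s of the
recording boundary, where a peak lacks a full flank.  Candidate cycles are
consecutive right-contact pairs; a cycle whose left contact falls outside
30–70% of the cycle, or that does not contain exactly one toe-off per side,
is excluded and logged — never repaired, because silent repair would bias
stride-variability and symmetry estimates.

## Feature definitions and choices

The silhouette formalism uses F_i = |θ_i − θ̄_i| and A_i = r_i·sin θ_i with
θ̄_i taken over the retained-cycle frames (not the whole recording), r_i the
trial-mean segment length, and sagittal angles measured from the vertical,
positive posterior.  Plane assignment follows the physical reading of each
feature: lumbar curvature uses the sagittal component of the thoracolumbar
angle ("curving the back"), horizontal head shake the horizontal-plane head
yaw.  Head yaw is measured lab-frame from the ear-marker axis, which stays
well-defined when the head's long axis is vertical (a shoulder-relative
variant is a config option).

Decisions where the definitions left freedom:

* **Clearance** is the toe-height minimum over the middle 20–80% of each
  swing — the mid-swing local minimum — because the toe leaves the floor at
  zero height at toe-off, so an all-swing minimum would always be ≈ 0.  Toe
  height is low-passed at 10 Hz first (wide enough to preserve the
  mid-swing dip, narrow enough to suppress jitter), the floor reference is
  the median of stance-phase toe height (unbiased under jitter, unlike a
  low percentile), the per-side summary is the median over swings (robust),
  and the feature is the mean of the two sides divided by body height.
* **Knee extension** implements the (−1)·A_knee form; the sign-free variant
  is available behind a switch because the two appear interchangeably in
  common usage.  With the (−1) convention the value is negative (the ankle
  trails the knee at push-off) and increases toward zero as the push-off
  leg straightens.
* **Stride CV** uses the sample SD (n−1); **symmetry** is
  max(mean swing L, mean swing R)/min(...), ≥ 1 by construction; **cadence**
  counts both feet's contacts over the first-to-last-contact span
  ((count − 1)/span, avoiding fencepost bias); **backward arm swing**
  averages the left and right peaks; **WHR** averages the per-frame
  horizontal distance ratio over the trial.

## The synthetic walker

A planar-dominant parametric gait at belt speed 1.0 m/s: pelvis fixed in
the treadmill frame apart from small vertical heave (8 mm) and trunk sway
(15 mm); feet follow scheduled stance/swing trajectories; legs are 2-link
pendula solved by sagittal inverse kinematics (knee anterior); the trunk is
a double-link rigid body whose upper segment oscillates in the sagittal
plane; arms are rigid pendula with constant elbow flexion; the head tilts
forward by a constant angle and oscillates in yaw.  Segment lengths are
standard fractions of body height.  Stride-to-stride variability multiplies
each stride period by 1 + cv·ζ (ζ truncated normal); swing-time asymmetry
moves the left-contact phase to 10% + 40%·a for asymmetry ratio a.

Two generator properties are deliberate design, not accidents:

* **Band-limitedness.** All profiles are quintic smoothsteps and a Gaussian
  mid-swing dip with content well below the pipeline's 6 Hz cut-off, so the
  filter transmits the generated motion essentially unchanged and recovery
  errors reflect the estimation chain, not generator/filter mismatch.
* **Symmetric event corners.** Pelvis-relative foot excursions approach and
  leave each contact/toe-off extremum with equal and opposite slopes
  (±belt speed), so the smoothed, parabolic-refined event estimate is
  unbiased; the foot pitch profile has zero angular velocity at toe-off,
  making the toe-off angle insensitive to ±1-frame detection error.

The generator records ground truth for every feature it controls: closed
forms where they exist (e.g. lumbar curvature = 2/π × amplitude for a
sinusoid; arm-swing peak = r·sin(offset+amplitude); WHR = rib/trochanter
width), and otherwise values computed from its own internal joint schedule
(knee extension, head shake windows) — independent of the marker-based
estimation path under test.  Timing ground truths use the realized event
schedule restricted to the same 0.25 s boundary margin the detector uses,
so estimate and truth refer to the same strides.  Recorded true joint
centers are the policy-consistent centers of the noiseless markers.

What the walker does *not* emulate: soft-tissue artifact (marker jitter is
iid Gaussian), pelvic rotation and obliquity, double-support force
dynamics, out-of-sagittal limb motion, or footwear mechanics (the heel
condition only shifts parameter distributions).  Passing recovery tests
therefore demonstrates correctness of the estimation chain on band-limited
periodic gait, not robustness to every artifact of optical capture.

## Synthetic populations and ratings

Between-walker variation is driven by a latent "gait quality" factor g:
BMI and cadence load negatively, arm-swing offset and amplitude, head tilt,
and push-off posture (hip height as a fraction of leg length, the dedicated
knee-extension knob) positively, at |loading| ≈ 0.8 — strong intercorrelation
chosen to mirror cohorts where physique and health variables covary
strongly.  Condition presets follow the published group summaries (toe-off
37 ± 2.8° barefoot vs 54 ± 7.8° in heels; WHR 0.69 ± 0.034; slightly larger
lumbar flexion and smaller clearance in heels).  The same subjects appear
in both conditions.

Observer ratings come from a latent linear model: score = Σ w_f·x_f +
observer bias + noise, discretized by six fixed thresholds shared by all
observers (symmetric around the mean latent at ±0.25, ±0.75, ±1.25 before
shifting).  Rating noise SD 1.0 and observer-bias SD 0.3 give per-animation
mean-score reliabilities comparable to pooling 60 raters.  The default
planted weights (per feature SD) are −1 BMI, −1 cadence, +1 arm swing,
+1 head tilt, +1.25 knee extension — the sign structure of the reported
correlations, with knee extension slightly up-weighted because its measured
value also absorbs stride-geometry variance the other features do not.

## The SEM engine

Reticular formulation over observed + latent variables:
Σ(θ) = F(I−A)⁻¹S₀(I−A)⁻ᵀFᵀ.  ML fitting minimizes
F_ML = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p by L-BFGS-B with variance parameters
bounded below, non-PD Σ penalized, and seeded multi-start (default 10; 4 in
the large recovery sweeps).  χ² = (N−1)·F_ML at the optimum — the (N−1)
multiplier is used because it reproduces all four published RMSEA values
from the published (χ², df, N), which fixes the convention the original
software used.  Convergence = optimizer success (or gradient ∞-norm below
tolerance) plus a positive-definite implied covariance; non-convergence is
a reported outcome, not an exception.  Fit indices: GFI =
1 − tr[(Σ⁻¹S−I)²]/tr[(Σ⁻¹S)²]; AGFI = 1 − [p(p+1)/(2df)](1−GFI); CFI with
the closed-form independence baseline (Σ_b = diag(S), so
F_b = Σln S_ii − ln|S|); RMSEA = √(max(χ²−df,0)/(df(N−1))); AGFI and RMSEA
are reported as undefined at df = 0.

Identification defaults: multi-indicator latents fix their first loading to
1; a single-indicator latent fixes the loading to 1 and the indicator's
error variance to 0 (the indicator is the latent up to scale).

**The packaged models.** B1/H1 relate two gait-silhouette factors
(trunk: lumbar curvature and/or arm swing; head: tilt and/or shake) to the
attractiveness and femininity ratings; B2/H2 relate physique (BMI), trunk
silhouette, and a health factor (cadence, knee extension) with all latent
covariances free.  The published descriptions pin down most of the
structure; free-parameter counting from the prose alone yields df = 2/10/4/4
against printed df = 2/9/3/3, so the reconstruction adds the single most
standard extra parameter per mismatched model: a free disturbance
covariance between the two ratings in B2 and H2, and a head-silhouette →
attractiveness path in H1.  `SemSpec.validate(expected_df=...)` surfaces
any remaining mismatch rather than silently adjusting the spec.  B1 and H2
model the attractiveness↔femininity mutual relationship as a nonrecursive
directed pair; in B1 the loop is identified through the uncorrelated-
disturbance constraint, and in H2 through the instrument structure
(physique → attractiveness only, health → femininity only).

**Recovery-test populations.** `TRUE_PARAMS` holds plausible
standardized-scale population values near the published standardized
estimates where available.  For H2 the physique–health covariance is set to
0.75 with instrument paths of |0.40–0.45|: at the published 0.96 the two
factors are nearly collinear, the instruments nearly vanish, and the loop
becomes weakly identified — consistent with the published report that
combining the models failed to converge, but unsuitable as a ground truth
for a finite-sample recovery check.

## Problem sizes and tolerances

The test and acceptance runs use: 12 s trials at 100 Hz (≈ 10–11 strides)
for feature recovery — recovery is within 2% (zero noise) / 5% (1 mm
jitter) with near-zero truths compared at a 0.005 absolute floor; SEM
recovery at n = 2000 rows, 20 seeds per model (mean absolute parameter
error < 0.05); the end-to-end screen at the study scale of 17 walkers ×
2 trials × 2 conditions × 60 observers, 20 replicates.  These sizes keep
the full suite around a minute per major stage on one CPU while leaving the
statistical margins comfortable.

## Known limitations

* TRC and long-form CSV only; the binary C3D vendor format is out of scope.
* No means/intercept structure, multi-group fitting, ordinal (WLSMV)
  estimation, modification indices, or per-path standard errors in the SEM
  engine (bootstrap SEs can be layered on by resampling rows upstream).
* Likert ratings are treated as interval at aggregation, matching common
  practice; no polychoric option.
* The screen applies no multiple-testing correction across the ~40
  feature × score tests, matching the analysis it reproduces; treat
  selected sets as descriptive, not confirmatory.
* Missing ratings are supported only as missing-at-random row drops.
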
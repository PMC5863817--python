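# Methods

## The measurement model

An alternate cover test dissociates the two eyes: while one eye is
occluded it is released from binocular fusion and drifts to its full
(tropic + phoric) deviated position; when the occluder swaps, the newly
uncovered eye re-fixates the target with a saccade. The angular size of
that re-fixation step equals the ocular deviation. A goggle-mounted
camera tracks the pupil center through the exam, so the step can be
read off the gaze trace instead of being neutralized with hand-held
prisms.

The pipeline assumes:

* comitant, horizontal deviation — one angle describes the misalignment
  in the primary position, and only the horizontal trace channel feeds
  the measurement (the vertical channel is carried but unused);
* the deviation is below 50 prism diopters (PD), i.e. 26.57°, the
  working range of the protocol;
* the camera sees the covered eye (infrared tracking behind the
  occluder). A blanked-occluder mode exists in the simulator, but with
  an opaque occluder the pre-cover window is empty and cycles become
  unusable — measuring from uncover-onset dynamics is out of scope.

### Camera projection

The pupil-center pixel displacement under a rotation θ about the globe
center is modelled orthographically:

    dx_px = pixels_per_mm · (globe_diameter_mm / 2) · sin θ

with defaults globe 26 mm, pupil 5.5 mm, 10 px/mm on a 320×240 frame.
The inversion `θ = arcsin(dx / (s·R))` is exact and single-valued on
[−90°, 90°]; displacements outside the arcsin domain become gaps with a
warning. The true device's projection is unknown; sine is the
physically standard choice for rotation about a sphere's center under a
distant camera and is exactly invertible over the protocol's 0°–30°
range.

### Device calibration

A model eye is rotated 0°–30° in 2° steps, holding ≥ 5 s per step. The
simulator injects an affine device distortion: a true angle θ is
rendered at the readout angle `(θ − b) / a`, so ordinary least squares
of truth on readout recovers exactly (a, b). Affine is the right model
class here because the bench relationship is linear to R² ≈ 0.999; no
polynomial/spline calibration is attempted. The regression direction —
truth on readout — matches how the model is used (predict rotation from
the device value). Per-dwell readout values are medians over the dwell
with 0.5 s trimmed at each boundary, so rotation transients never touch
the statistic. When several bench repeats are available the per-angle
means are fitted, with pooled fitting available via plain array
concatenation.

Calibrated angles convert to prism diopters by `PD = 100·tan θ`
(1 PD = 1 cm at 1 m), with `arctan` as the exact inverse. Note the
conversion does not commute with averaging: the mean of per-subject PD
values differs from the PD of the mean angle, which matters when
comparing cohort summaries.

## Windows and aggregation

For each cover→uncover transition the newly uncovered eye's deviation
is `|median(pre) − median(settle)|` with

* pre window = last 1.0 s of the covered interval,
* settle window = 0.3–1.5 s after the transition,

both restricted to samples with confidence ≥ 0.5 and finite position.
The settle delay skips the re-fixation saccade (simulated at 50 ms, far
below 300 ms); medians rather than means make both windows robust to
residual blink samples and single-sample glitches. A window with fewer
than 10 valid samples marks the cycle unusable rather than raising. The
default protocol (5 cycles) yields 9 measurable transitions — the last
cover interval ends with the session, leaving no settle window.

Within a session the reported value is the **median of usable cycles**
(mean and first-cycle are selectable). Across repeated sessions the
**first** session value is the default selection rule, with the mean
available, since both rules are in clinical use for test-retest series.
Deviation signs are discarded: exodeviation magnitudes are reported
unsigned.

## Pupil detection

Per frame: Otsu's threshold computed on the darkest quartile of the
intensity histogram (fallback: 5th percentile when the dark tail is
degenerate), morphological opening (disk radius 2 px), then the largest
connected component that passes a circularity gate (≥ 0.6, via the
Crofton perimeter) and an area gate (25 %–400 % of the expected pupil
area when the geometry is known). The subpixel center is the
darkness-weighted centroid over the component dilated by 2 px — the
anti-aliased rim carries the subpixel information; an ellipse fit would
add robustness to partial occlusion but is unnecessary for step-height
measurement and is left as an extension. Confidence = circularity ×
area-plausibility, and `valid ⇔ confidence ≥ 0.25`; uniform or empty
frames return confidence 0, which is exactly the blink/cover signal the
downstream windows filter on. Coordinates are center-of-pixel, origin
top-left, x rightward, y downward; per-eye angles are positive
temporal-ward.

## Agreement statistics

* **Bland-Altman**: differences a−b, sample SD (n−1), limits mean ±
  1.96·SD. The multiplier is fixed at 1.96 (the conventional 95 %
  limits); no small-sample t correction.
* **ICC**: the default variant is ICC(2,1) — two-way random effects,
  absolute agreement, single measures — because inter-observer and
  test-retest questions here concern absolute agreement of single
  measurements. ICC(1,1) and ICC(3,1) are selectable. Confidence
  intervals use the McGraw–Wong F-based formulas (Satterthwaite
  degrees of freedom for ICC(2,1)); degenerate zero-variance cases
  (identical columns) return ICC 1 with a collapsed CI. Incomplete
  matrices are an error — no imputation.
* **Difference table**: absolute differences binned as [0,3), [3,5],
  (5,∞) PD — the middle bin closed on both ends so boundary values land
  in "3–5". Percentages are rounded half-up to one decimal with the
  middle bin set to the remainder so the printed column sums to exactly
  100.0, the convention used in clinical summary tables (pure half-up
  rounding of e.g. 4/34 gives 11.8 and a column sum of 100.1); the
  unadjusted percentages are retained alongside.

## Synthetic data: what it does and does not emulate

The subject simulator produces piecewise-constant traces with linear
50 ms saccade ramps, per-episode Gaussian jitter of the dissociated
angle (default SD 0.25°, emulating phoric instability), additive
Gaussian tracker noise (default SD 0.2°, matching the ~sub-degree
accuracy class of video eye trackers), and Poisson blinks (0.1 Hz,
100–300 ms, confidence-0 gaps). Defaults follow the clinical protocol:
120 Hz sampling, 10 s binocular lead, 5 s cover, 5 cycles. It does
**not** emulate smooth pursuit, nystagmus, vergence changes, head
movement, eyelid droop, pupil-size changes, or photorealistic iris
texture; passing the recovery tests therefore demonstrates the
correctness of the extraction logic under the stated noise model, not
clinical performance on real recordings.

The model-eye renderer draws an anti-aliased dark disc on a bright
field (levels 30/200 of 255). Its default frame rate is 10 Hz (4 Hz in
the fast test configurations): the dwell positions are static, so dwell
medians are independent of frame rate and a lower rate only shrinks the
rendered stack; the subject-trace simulator keeps the full 120 Hz.

## Numerical and design choices

* All randomness flows from `numpy.random.default_rng(seed)`; equal
  seeds give byte-identical sessions.
* Noiseless round trips are exact by construction: medians of constant
  windows, `arcsin∘sin` identity, OLS on exactly affine data (recovery
  to ~1e-9), `arctan∘tan` to 1e-12.
* A documented protocol ambiguity: the camera rate is stated as 120 Hz
  in the protocol and 150 Hz elsewhere in the source material's
  discussion; 120 Hz is the default and the rate is configurable. The
  step-height statistic is insensitive to it.
* Pipeline reports embed the calibration model, config hash, seed and
  package versions so converted values are auditable.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic
data: 200 sessions of 60 s at 120 Hz for parameter recovery, 16-dwell
model-eye sessions rendered at 4 Hz (320 frames) for the calibration
round trip, and 10–50 replicate draws for the statistics oracles. The
full suite completes in well under a minute on one CPU.
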
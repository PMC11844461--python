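# Methods

This note documents what lipstereo computes, the assumptions behind each
stage, the parameters that matter, and what the synthetic validation does
and does not establish about real recordings.

## Measurement model

Two synchronized cameras observe the face. A landmark tracker (external to
this package, behind the `TrackerAdapter` seam) supplies per-frame pixel
coordinates of named lip landmarks in each view. The pipeline converts
those to metric 3D and reduces them to one scalar signal, lip aperture
(LA): the Euclidean distance between the mid-sagittal upper- and lower-lip
vermilion-border points, in millimetres, per frame. LA is a distance, so it
is invariant to the choice of world frame and to any rigid head motion —
both facts are exploited throughout the validation.

### Camera model

Pinhole with 4-parameter distortion (k1, k2 radial; p1, p2 tangential) on
normalized coordinates. Higher-order radial and thin-prism terms are
deliberately omitted: the intended regime is a low-distortion rectilinear
lens, and the short model keeps the fixed-point distortion inversion
(tolerance 1e-10, ≤50 iterations) contractive and well conditioned. Pixel
coordinates are 0-based, origin top-left, y down. The world frame is the
left camera frame (left R = I, t = 0); millimetre units enter through the
calibration target (15 mm checkerboard squares).

### Calibration

The package consumes 3D–2D correspondences rather than images: corner
detection is a solved problem delegated to external tools, and
correspondences make calibration exactly testable. Each camera is resected
by normalized DLT — isotropic (centroid / √2, √3) normalization of both
point sets, SVD solution of the 2n×12 homogeneous system, de-normalization.
Projection matrices are homogeneous, so a scale convention is fixed for
comparison: Frobenius norm 1, positive determinant of the left 3×3 block.
Degeneracy (n < 6, coplanar world points) is detected from the
second-smallest singular value (ratio < 1e-9). Resectioning fits the
pinhole part only; exact recovery therefore assumes the distortion-free
regime, which the default rig models.

### Triangulation

Observations are undistorted to normalized coordinates first, so the
two-view DLT is exact for the pinhole part: with normalized observations
the effective projection matrices are [I|0] and [R|t]. The per-point 4×4
homogeneous system is solved by the smallest right singular vector;
|w| < 1e-12 (rays numerically parallel) is an error, as is a zero-baseline
rig. Whether the original study undistorted before triangulating is not
stated; undistort-first is this package's choice and is applied
consistently.

## Temporal pipeline

1. **Clap sync.** Candidate samples are gated by an amplitude threshold
   (default 0.5, full-scale units); the global |amplitude| maximum among
   candidates wins, ties to the earliest sample. The inter-camera offset is
   converted to video frames by rounding to nearest, half away from zero —
   a symmetric rule chosen to avoid directional bias; the sub-frame
   residual (up to ±0.5 frame ≈ ±8 ms at 60 Hz) is recorded and left to the
   fine alignment stage. Cross-correlation alignment and drift correction
   are out of scope.
2. **Upsampling.** The 60 Hz LA series is linearly interpolated to the
   250 Hz reference rate. Linear interpolation is shape preserving,
   monotone and exactly testable; cubic alternatives would change values by
   less than the jitter floor at these rates.
3. **Coarse alignment** matches the global LA maxima of the two series.
   Its resolution is set by the peak sharpness relative to the noise: at
   60 Hz a raised-cosine speech gesture drops ~0.7 mm per sample at the
   peak, so 0.1 mm noise cannot move the argmax; at 250 Hz the peak is
   ~0.04 mm/sample flat and the argmax may wander a couple of samples —
   which is exactly why a coarse stage alone is insufficient.
4. **Fine alignment** exhaustively searches integer shifts within ±50
   samples (±0.2 s at 250 Hz) of the coarse lag and keeps the shift with
   minimum RMSE over the overlap (≥10 samples required). Alignment runs on
   raw amplitudes, before normalization, matching the stated order of the
   procedure it reproduces. RMSE ties (within 1e-9 relative — exact float
   equality is not meaningful here) break to the smallest |lag|, then the
   more negative lag. The test series is the one shifted; the reference
   defines the time base.
5. **Segmentation.** Bilabial closures are local LA minima with prominence
   ≥ `min_prominence` (default 1 mm; the height of the lower flanking peak
   above the minimum) and pairwise separation ≥ `min_separation` (default
   0.1 s worth of samples; the deeper minimum survives a conflict),
   computed with standard peak finding on the negated signal. Minima are
   taken on the aligned *reference* segment, since the reference is the
   designated ground truth; the utterance window spans first→last minimum
   by default, with an explicit-selection mode for utterances with interior
   closures.
6. **Normalization** is strictly additive: the test series is shifted by
   the difference of window means. The physical justification is that the
   reference sensors and the video landmarks sit at slightly different
   anatomical spots, which to first order offsets LA by a constant; no gain
   is fitted.
7. **Metrics.** Precision is the sample SD (divisor N−1 — clips are samples
   of an ongoing process; the population-SD alternative differs by <1% at
   60 frames) of LA over a static-lip clip. Accuracy is the RMSE over the
   utterance window after alignment and normalization.

## Synthetic scenes

The simulator emulates the study conditions rather than any particular
tracker:

* **Gestures.** LA = baseline + raised-cosine opening bumps; closures
  (minima at the baseline) occur exactly at gesture boundaries. The
  "puppy" template has three adjacent gestures (two closures), the
  "buy-bobby-a-puppy" template five. Randomized parameterizations draw
  amplitudes 5–15 mm, durations 0.15–0.35 s and baselines 0–3 mm — the
  range of bilabial speech gestures. Static-lip scenes default to an 8 mm
  parted-lips aperture (the mannequin condition).
* **Geometry.** Ten lip landmarks in a face-local frame (the mid-sagittal
  pair separated vertically by exactly LA(t), flanking points with reduced
  excursion, static corners) plus a static support lattice, placed ~800 mm
  from a 600 mm-baseline rig; 5312×2988 px sensors at 60 Hz with a 3000 px
  focal length, a realistic rectilinear value for that sensor giving
  ≈0.27 mm/px at the face. Distortion defaults to zero.
* **Head motion** is a per-frame rigid transform: none, low-amplitude
  smooth wobble (posture adjustments), ±20° alternating yaw, or constant
  18°/s yaw (rotating display stand). Being rigid, none of them changes
  ground-truth LA.
* **Jitter.** Detector-like noise is iid Gaussian per frame and axis;
  tracker-like noise is AR(1) with stationary SD `sigma_px` and
  autocorrelation ρ (default 0.9). The magnitudes are free parameters with
  default 1 px — they are *not* estimates of any named tracker's error, and
  none of the validation depends on their specific values.
* **Reference stream.** The 250 Hz reference is the 60 Hz ground-truth LA
  *linearly resampled* to 250 Hz, plus a constant sensor-placement offset
  (default 1.5 mm, to exercise normalization), an optional start lag and
  optional iid noise. Defining the reference through the same resampling
  operator the pipeline uses makes the noise-free pipeline exactly
  self-consistent (RMSE at float precision), which is the property the
  deterministic tests need; an analytically sampled reference would add a
  ~0.05–0.1 mm interpolation residual that reflects the 60 Hz video rate,
  not an implementation defect.
* Everything stochastic is a pure function of (parameters, seed).

## What the validation shows — and does not

The synthetic experiments establish that the deterministic pipeline is
exact (geometry round-trip < 1e-6 mm; calibration recovery < 1e-9;
noise-free lag/offset/RMSE recovery exact), that head motion registers no
spurious lip motion (isometry floor < 1e-6 mm at 18°/s), and that measured
LA noise matches first-order propagation of pixel jitter to within 15%.
They do not — cannot — measure the accuracy of any neural tracker on real
faces: appearance, lighting, occlusion, rolling shutter and tracker bias
are all outside the simulation. Simulated pixel-jitter magnitudes bracket
plausible tracker behavior, but per-clip SD/RMSE numbers from the simulator
characterize the pipeline, not a tracker.

Problem sizes used by the test suite and acceptance script (1000 round-trip
points, 50 checkerboard frames, 200 jitter replicates per level, 100
alignment/sync replicates, 50 segmentation parameterizations) keep full
runs in seconds while holding Monte-Carlo error well inside the asserted
margins.

## Other conventions and edge cases

* Edge snapping (vertical-only, centered-difference gradient, default
  radius 5 px, threshold 0.1 intensity/px, ties to the nearest row then
  upward) addresses the specific failure mode of per-frame detectors
  placing the upper-lip point slightly below the vermilion border; only the
  snapped coordinate matters, so a 1D gradient maximum replaces a full 2D
  edge detector. It applies to image-based conditioning only — synthetic
  scenes carry no imagery.
* `ApertureSeries` does not enforce nonnegativity: additive normalization
  is a signed shift. All physical generators produce nonnegative series.
* Reports serialize floats at 9 significant digits; identical config + seed
  gives byte-identical report files.
* Landmark ids are configurable; only `upper_mid`/`lower_mid` are
  semantically required (they define LA).
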
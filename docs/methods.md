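# Methods

## Signal model

The package treats a B-mode ultrasound recording of a muscle as an ordered
stack of grayscale frames on [0, 1] at a known frame rate (nominally
40 fps; any positive rate is accepted, and every duration-valued parameter
is specified in seconds and converted with the actual rate). A manually
drawn simple polygon over the muscle belly — excluding the aponeuroses,
whose shearing dominates inter-frame change — is rasterized by a
pixel-center inclusion rule: a pixel belongs to the ROI iff its center lies
inside the polygon or on its boundary (boundary ties count as inside, for
determinism). RGB input frames are converted with BT.601 luma weights
(0.299 R + 0.587 G + 0.114 B)/255, the de facto video standard; exporters
may use other weight sets, but the NPD statistic is insensitive to the
choice because it differences the same conversion against itself.

The normalized pixel difference of the transition into frame *i* is the
mean absolute per-pixel intensity change over the ROI. The series for an
*n*-frame video has *n − 1* entries; entry *k* is timestamped at the later
frame, *t = (k + 1)/fps*. NPD is dimensionless, bounded in [0, 1],
homogeneous of degree one in the frame intensities, and identically zero
iff consecutive frames agree on the ROI. Because it averages thousands of
pixels, uncorrelated speckle contributes a stable noise floor rather than
variance: the series at rest is a tight stochastic baseline, and coherent
tissue motion (contraction onset, relaxation) produces transients an order
of magnitude farther from the floor than the baseline's own fluctuation.

## Threshold and detection

The activation threshold is learned from a resting baseline recording as
`T = mean + m·SD`, with the sample SD (*n − 1* denominator; the convention
is a choice — at baseline lengths of thousands of samples it is
indistinguishable from the population SD). The multiplier is 3 for NPD and
2 for the EMG envelope and smoothed torque. Threshold comparisons are
strict (`>`).

A sample *i* is a *verified peak* iff it exceeds T and at least
`ceil(0.70 · w)` of the *w* samples `i … i+w−1` do, where
`w = round(0.25 s × fps)` (10 samples at 40 fps, so 7 must exceed). The
70 % tolerance exists because genuine transients can dip briefly below
threshold. At the end of a recording the rule is applied to the remaining
samples with the same ceiling, rather than refusing detection. The window
span is defined as exactly *w* samples starting at *i*; an alternative
reading (*w + 1* samples) shifts the required count by at most one sample
and is not used.

A contraction event after a cue is detected in three stages, confined to
`[cue, next cue)`:

1. **Onset** — the first verified peak at or after the cue.
2. **Tensed interval** — after the onset peak's supra-threshold run, a
   continuous sub-threshold interval of at least 0.25 s must be observed
   (configurable; the floor prevents one broad transient from being split
   into onset + offset). Once such an interval has been seen it is not
   cancelled by later isolated supra-threshold blips that fail peak
   verification — those are precisely the random baseline excursions the
   verification window exists to reject, and making the quiet interval
   immediately precede the offset peak would let a single blip sample
   destroy an otherwise clean detection.
3. **Offset** — the first verified peak after the tensed interval.

An onset without an offset before the search horizon yields an incomplete
event; the event's peak NPD is the maximum over the detected span.

EMG is band-passed 5–500 Hz with a 5th-order Butterworth filter applied
forward-only (the filter it models runs causally inside an amplifier; the
induced group delay at the envelope scale is ≪ the 1 s hold), full-wave
rectified, and smoothed with a centered symmetric moving average over
0.01 s. Torque is smoothed the same way without filtering or
rectification. Moving-average windows are `round(duration × fs)` forced to
the nearest odd integer ≥ 1 so the filter stays symmetric (zero phase
shift); at the edges the half-width shrinks symmetrically, preserving
unity DC gain everywhere. Sustained activations are detected as the first
sample such that it and the following 1 s (`round(hold × fs)` samples)
stay above threshold; the hold rejects transient noise.

## Biofeedback classification

The trial statistic is the peak NPD over the recorded window (preparation
+ execution; 5 s in the 12 s trial protocol of 2 s rest, 1 s preparation,
4 s execution, 5 s rest). It is normalized by the MVC peak — the maximum
trial peak over the MVC-test attempts (maximum, not mean, because the MVC
test estimates the *ceiling* of fiber displacement) — and may exceed 1.
With relative bands (the default), the deviation `r = |x − target|/target`
classifies the trial: `r ≤ 0.10` successful, `r ≤ 0.20` acceptable, else
unsuccessful; boundaries are inclusive toward the better class. An
absolute-band mode (deviation not divided by the target) is provided
because the band semantics are a genuine modelling choice; relative is the
default as it matches feedback bars drawn at ±10 %/±20 % *of the target
value*. When a target must be derived from dynamometer-feedback training
trials, the mean of their normalized peaks is used — the median would
differ only under outliers, and five trials give little basis for
robust-location arguments. Session dispersion is summarized by the 25/50/75
percentiles of `|x − target|` with the linear-interpolation quantile
definition.

## Agreement and robustness analyses

Cross-modality agreement treats each cued trial as a boolean triple
(ultrasound, EMG, force plate). "All agree" means the triple is constant —
all three detected or none did; the single-modality rates (USI-only,
EMG∧FP-only) quantify differential sensitivity. The eight-pattern partition
is computed in full and checked to sum to 100 %. A Friedman test on
per-participant detection counts is delegated to
`scipy.stats.friedmanchisquare`. The ROI-robustness re-analysis re-runs
NPD extraction and trial classification under alternative ROI polygons
with the MVC calibration held fixed and reports the number of trials whose
class changed.

## Synthetic data generator

The generator produces the statistical structure the detector assumes, not
ultrasound physics:

- **Texture** — white Gaussian noise smoothed to a correlation length of
  3 px and rescaled to mean 0.5, SD 0.15: a static speckle-like pattern.
- **Motion** — a displacement applied through a feathered weight field over
  the muscle polygon (so only the muscle moves) with a mild depth gradient
  (deeper tissue moves more), i.e. a shear rather than a rigid shift. At
  each event onset the displacement ramps up by
  `contraction_shift_px × intensity` per frame (default 1.5 px/frame at
  full intensity) over a 0.3 s transition window, holds while the muscle is
  "tensed", and ramps back at the offset. At all times sub-pixel Gaussian
  jitter of SD 0.05 px/frame models resting physiological motion
  (capillary activity, micro-adjustments).
- **Noise** — additive zero-mean Gaussian, SD 0.02 intensity units per
  pixel per frame, clipped to [0, 1]. Real speckle is multiplicative and
  Rayleigh-like before log-compression; additive Gaussian on the
  log-compressed-looking texture is a deliberate simplification, sufficient
  because NPD only needs realistic frame-to-frame variability, not
  physically faithful granularity.

Defaults: 128 × 128 px at 40 fps, a trapezoidal muscle region spanning the
central band of the image. EMG is simulated as amplitude-modulated white
Gaussian noise (`amplitude = noise_sd + gain × activation(t)`, activation
edges ~100 ms), torque as a first-order lag (τ = 150 ms) of
`MVC torque × intensity` plus sensor noise (MVC torque default 100 N·m, a
typical plantarflexion maximum). Cue schedules use 2.5 s cues with i.i.d.
uniform 3.0–5.5 s inter-trial gaps; ground-truth profiles pad 2 s past the
last cue so the final relaxation transient is recorded. Every generator is
a pure function of (parameters, seed).

What passing tests on this generator do **not** show: robustness to probe
motion relative to the skin, to out-of-plane motion, to depth-dependent
attenuation or focal-zone effects, or to genuinely multiplicative speckle
statistics. They do show that the detection logic recovers events whenever
the real signal has the assumed structure — a quiet stochastic baseline
with transient excursions at state changes.

## Problem sizes and numerical choices

The validation suites use what a desk-scale re-analysis supports: a 120 s
baseline (4800 frames) for the resting false-positive check, 50
single-contraction trials (9 s each) for event recovery, 20 trials for the
three-modality agreement check, and smaller 64 × 64 frames in unit tests
where only the plumbing is under test. The vectorized NPD path is checked
against a scalar per-pixel loop to 1e-12. Rasterization uses shapely's
`covers` predicate (boundary-inclusive) against pixel-center coordinates;
an independent half-plane oracle cross-checks it on convex polygons.
Raw-binary video quantizes intensities to 8 bits, matching the 255-level
source data, so write/read round-trips are exact. CSV output uses 9
significant digits; serialization round-trips are verified to 1e-9.

## Known limitations

- The method cannot distinguish active contraction from passive movement,
  nor contraction from relaxation transients except by temporal order.
- Detection parameters (0.25 s window, 70 %, 1 s hold) were validated at
  40 fps; other frame rates are converted by duration but not re-validated.
- A single activation threshold per session assumes stationary resting
  statistics; probe or posture drift would invalidate the baseline.
- The EMG/torque detectors share the session baseline; per-task baselines
  are not modelled.
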
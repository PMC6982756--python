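# Methods

## Pipeline overview

The package models a real-time wearable pipeline with a fixed one-second
cadence: every second the sensing layer delivers exactly 20 triaxial
accelerometer samples (20 Hz, units of g, ±2 g full scale) and one mean
heart-rate value (bpm). Three computations run on that cadence:

1. feature extraction over the 20-sample window,
2. activity classification of the feature vector,
3. workload assessment of the window's mean heart rate.

Session-level aggregation (per-activity modal workload) runs offline after
a session ends.

## Windowed features

Windows are non-overlapping and exactly 20 samples long; a trailing
incomplete group is discarded (`floor(n/20)` windows from `n` samples). The
per-second record structure implies no overlap, and padding partial windows
would fabricate sensor data.

The 15 statistics are per-axis mean, standard deviation, variance and mean
absolute deviation, plus the three pairwise differences of axis means.
Variance and standard deviation use the **population** convention
(divide by n). With n fixed at 20 the sample/population choice is a pure
rescaling that the forest's thresholds absorb; the population form keeps
`var == std²` exact, which the test oracle asserts at 1e-9 relative. MAD is
the mean absolute deviation from the axis mean (not the median-based
statistic of the same acronym).

Feature order is fixed — means, stds, vars, MADs, mean differences — so an
exported model's feature indices are unambiguous. The pruned 11-feature set
removes ȳ, MAD(y), MAD(z) and x̄−ȳ, the four features ranked least
important by normalized Gini importance in the full-set forest.

## Classifier

Random forest with impurity-based defaults; the only tuned hyperparameter
is the tree count (default 24, the point past which the accuracy-vs-trees
curve is flat). kNN with 5 neighbours is retained as the comparison
baseline, operating on unstandardized features; because the retained
features span similar numeric ranges (all in g or g²) this is tolerable,
but kNN accuracy is sensitive to that choice where the forest is not.

The 70/30 train/validation split is stratified by class. Plain
randomization can leave a class absent from the validation fold at small n;
stratification removes that failure mode and only strengthens the split's
representativeness. One global seed drives everything; per-stage sub-seeds
(split, per-size training in sweeps, synthetic blocks) are derived
deterministically from it, so a run is reproducible from its manifest. The
size sweep reuses a single split across sizes, isolating the effect of the
tree count from split noise.

Ties in forest voting resolve to the first class in the alphabetical class
list (the arg-max convention of averaged class probabilities); the exported
JSON description documents this so the bundled interpreter reproduces live
predictions exactly, node thresholds surviving the JSON round-trip at full
float precision.

## Workload scoring (Frimat's criterion)

Indicator bins are integer-anchored half-open intervals — for ACC:
[10,15), [15,20), [20,25), [25,30), [30,∞) mapping to coefficients 1–5,
and analogously for the other indicators — which reproduces the printed
integer ranges exactly while leaving no holes for real-valued inputs.
Values below the lowest bin clamp to coefficient 1, preserving the printed
score floor of 5.

Two ambiguities in the printed method are resolved as follows:

- **RCC units.** The defining equation multiplies by 100 but the
  coefficient table spans 0.10–0.30, so the binned quantity must be the
  fraction ACC/(HRmax−HRrest). RCC is stored and binned as that fraction.
- **Score 11.** The published ranking lists 12–13 → "Very light" and
  ≤10 → "Minimum workload", skipping 11; 11 maps to "Very light" (the
  nearest band above), keeping category hardness monotone in score.

Mode tie-breaks are deterministic and conservative in the direction of
worker protection: resting-rate estimation takes the *smallest* modal value
(lower reference → higher measured cardiac cost), category aggregation
takes the *harder* modal category.

**A deliberate non-monotonicity.** ΔHR is implemented exactly as defined,
HRmax − HR̄, and binned as printed (larger ΔHR → larger coefficient). The
consequence is that the total score is *not* monotone in window heart
rate: once HR̄ exceeds HRmax − 40 the ΔHR coefficient starts falling faster
than the effort-driven coefficients rise (e.g. resting rate 70, age 27:
153 bpm scores 25, 154 bpm scores 24). The effort-driven coefficients
(ACC, RCC, HR̄) are individually monotone, and the suite asserts exactly
that; fidelity to the printed equations was chosen over reinterpreting the
ΔHR bin direction.

## Synthetic data generator

Per activity, each accelerometer axis is gravity projection + single
sinusoid + white Gaussian noise, clipped to ±2 g. This is the simplest
process that produces the per-axis mean and dispersion contrasts the
feature set can separate: posture sets the means (upright for resting,
jogging, squatting; prone for push-ups; supine for crunches — gravity on
the hip-mounted sensor's y or ±z axis), while oscillation frequency and
amplitude set the dispersions (jogging ~2.5 Hz, amplitude 0.8 g vertical;
squatting ~0.5 Hz, 0.4 g; push-ups 0.7 Hz and crunches 0.6 Hz, ~0.3 g on
the vertical-at-posture axis; resting oscillation-free with 0.03 g sensor
noise). Sinusoid phases are drawn per block from the seed so windows are
not phase-locked to window boundaries. Over a one-second window the std of
the oscillating axis is ≈ amplitude/√2 (sinusoid RMS), which the parameter
recovery test checks at 5%.

Heart rate follows a first-order relaxation,
HR(t+1) = HR(t) + (target − HR(t))/τ + ε, one step per second from the
subject's resting rate, with τ = 20 s (a plausible exercise-onset time
constant) and ε ~ N(0, 1.5 bpm). Activity targets: resting 70, squatting
110, crunches 115, push-ups 125, jogging 150 bpm. No published values
exist for any of these signal parameters; they were chosen once as
physiologically plausible and are tunable through a plain-text config file.

The default session script is the eight-block test routine — push-ups,
resting, jogging, resting, squatting, resting, crunches, resting, each
30 s — for a 27-year-old subject resting at 70 bpm.

**What passing tests show.** The generator produces well-separated feature
clusters by construction, so the ≥0.95 held-out accuracy benchmark (24
trees, 11 features, stratified 70/30, five seeds, three 240-second sessions
per seed ≈ 720 vectors) demonstrates that the pipeline's plumbing — 
windowing, feature math, split, training, evaluation, export — is correct,
*not* that the classifier would reach that accuracy on real sensor data,
where inter-subject variability, unplanned pauses and sensor artifacts
dominate. Real-data accuracy claims are outside what synthetic sessions
can support. Features deliberately not emulated: gait harmonics and
impact transients, orientation drift and sensor misplacement, HR
measurement dropouts, PPG motion artifacts.

## Numerical and degenerate-input choices

- Serialization keeps ≥ 9 significant digits (JSON repr round-trip; CSV
  `%.12g`), so read∘write is the identity within 1e-9.
- Records with other than 20 samples, unknown labels, or out-of-scale
  accelerations are rejected loudly rather than coerced or padded.
- Records may omit heart rate for recognition-only use; workload scoring
  rejects them.
- Resting-rate estimation rounds to integer bpm before taking the mode
  (half-up), making the mode well-defined on continuous inputs.
- A cardiac reserve of zero or less (HRrest ≥ 220 − Age) is a domain
  error, not a silent division.
- Feature matrices with a constant column are legal; a constant feature
  receives ~0 importance and is dropped first by pruning.

## Problem sizes

Defaults throughout target desk-scale runs: 240-second sessions, corpora
of three sessions (720 vectors), sweeps over a handful of tree counts in
tests with the full 2–100 sweep available through the CLI. These sizes
were chosen as the smallest at which every statistical claim in the test
suite is comfortably stable across seeds.

## Known limitations

- The accelerometer model is stationary within a block; activity
  transitions are instantaneous, so there are no ambiguous boundary
  windows — real streams have them.
- Workload scoring trusts the reported resting rate; no drift or
  re-estimation during a session.
- The kNN baseline does not standardize features; its reported accuracy
  should be read with that caveat.
- The exported model description covers random forests only; kNN models
  are not portable by design (the baseline is not deployed).
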
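# Methods

This note records the scientific and numerical choices behind `wearstate`:
what the pipeline computes, which parameters matter, what the synthetic
generator does and does not emulate, and where the design was genuinely
open.

## Signal model and unit conversion

Chest-unit streams (ECG, EMG, respiration, accelerometer, EDA,
temperature) are 700 Hz sequences of 16-bit offset-binary ADC words; the
wrist unit provides BVP at 64 Hz, triaxial acceleration at 32 Hz (units of
1/64 g) and EDA/temperature at 4 Hz. Conversion is affine:
`(raw/2^16 − 0.5)·V_CC` with V_CC = 3 for ECG (mV) and EMG (µV), and
`(raw/2^16 − 0.5)·100` for respiration (%). The bracket placement is the
only reading that makes midscale (2^15) the electrical zero of a bipolar
physiological signal, so that is what we implement. The accelerometer
scale is 9.81/64 m/s² per raw unit, derived from the stated 1/64 g
resolution; the scale is a `ConversionSpec` field, so any other published
factor (e.g. a ±2 g range term) can be substituted. BVP and temperature
have no conversion and pass through.

## Resampling

All streams are first placed on the common 700 Hz grid. Upsampling is
linear interpolation onto the target time grid (`hold` is available by
configuration); this handles the non-integer 32 → 700 Hz ratio (21.875×)
without repetition artifacts. Values past the final input sample hold that
sample (constant extrapolation) — the affected tail is under one input
sample period. Output length is `round(n · 700/f_native)`.

Downsampling to 10 Hz aggregates non-overlapping blocks of 70 samples by
the mean (median available); the trailing partial block is dropped rather
than padded. Labels aggregate by block mode. Two conventions were open and
are fixed as: mode ties break to the lowest class code (deterministic),
and a block whose labels are entirely the −1 unlabeled sentinel emits −1
(mixed blocks use the mode of the labeled samples only). Rows whose 10 Hz
label is −1 are removed from the feature matrix. No anti-aliasing filter
is applied before aggregation, matching the processing the pipeline
replicates.

## Peak detection and features

A peak is a sample strictly greater than its left neighbour, at least its
right neighbour (so plateaus yield their first sample), and above
`mean + k·sd` of the analysed window (default k = 1, computed per
minute). A refractory distance suppresses nearby peaks, keeping the larger
amplitude (earlier index on ties). Defaults at 10 Hz: minimum distance 3
samples for ECG/BVP (~0.3 s, the shortest credible interbeat interval), 2
for EMG bursts, 10 for respiration (~1 s between breaths). All are
`PeakParams` fields. The detector is verified against an exhaustive
brute-force oracle in the tests.

Minute features (per complete 600-sample minute, broadcast to its
samples): peak count; mean peak amplitude; `differ_mean`, read as the
*mean absolute* successive peak-amplitude difference, since a signed mean
telescopes to a degenerate endpoint difference (flagged open question —
an interval-based reading is also defensible); and for ECG the resting
rate, read as mean peaks per non-overlapping 1 s (10-sample) window,
which equals count/60. Empty minutes produce all-zero features rather
than missing values, keeping the matrix dense.

Subject-level accelerometer statistics use the wrist (not chest) device:
per-axis mean, population (1/N) standard deviation, excess kurtosis and
crest factor `max(x)/sqrt(Σx²/(N−1))`, plus pairwise correlations
computed as the 1/(N−1) mixed moment over population sds. Two printed
forms are dimensionally inconsistent and were normalized: kurtosis is
divided by σ⁴ (not σ²), and the mixed-moment correlation — which can
exceed |1| by a factor N/(N−1) — is clipped to [−1, 1]. The literal forms
remain available behind `printed_forms=True`. A zero-variance axis raises
an error naming the axis. The feature matrix is exactly 28 columns in
blocks {ECG 4, EMG 3, RESP 3, BVP 3, ACCL 15}.

## Architecture

The adaptive kernel rule is implemented as k = ⌈x/2⌉ for a branch with x
input features — the unique resolution of the printed rounding expression
consistent with all five published kernels (3→2, 4→2, 15→8). Convolutions
are valid (no padding), stride 1, with no pooling anywhere; this is the
only combination that reproduces the published per-layer output
dimensions, and the audit (`audit_table`) reproduces every published
parameter count exactly. Dropout rate is unpublished; the default is 0.25
after flatten and after the first dense layer of each branch (not in the
trunk), configurable. Weight initialization (also unpublished) is
Glorot-uniform from a seeded generator.

Because no deep-learning framework is part of the dependency set, the
network is realized directly in NumPy (`wearstate.nn`): einsum-based
valid convolutions, hand-derived backpropagation (verified against finite
differences in the tests), inverted dropout, and SGD/RMSprop/Adam with
the time-decay schedule `lr_t = lr/(1 + decay·t)`. At ~175k parameters
over ≤15-sample inputs this is fast on one CPU and keeps whole training
runs bit-reproducible from a single seed.

## Training regimes

Type I draws a uniform random 70/20/10 train/validation/test split;
fractional sizes round half-up for train and validation, remainder to
test (exact for the published pool of 880,590 → 616,413/176,118/88,059).
Type II holds one subject out entirely as the test set and splits the
rest 80/20; the published per-fold sizes are reproduced exactly by this
arithmetic for all 15 folds. Note the published tables imply a pool of
880,590 samples while the stated aggregate total is 573,480; the pipeline
takes n from its input, so both are supported, and we do not attempt to
resolve the discrepancy.

The loss is categorical cross-entropy with predictions clipped at 1e-12
(never an exception on a zero probability). The tuned hyperparameters
(lr 0.00125, β₁ 0.9765841, β₂ 0.8541287, decay 0.000235) are the Adam
defaults; β's are ignored for RMSprop/SGD since only Adam was tuned.
Batch size is unpublished; default 256. Class imbalance is left
unaddressed by default, replicating the source setup; a `class_weight`
option exists but is off. One departure from the source pipeline:
features are standardized to the training split's mean/sd before entering
the network (default, can be disabled) — raw feature scales span four
orders of magnitude (peak counts ~100 vs ECG amplitudes ~0.1 mV) and
gradient training across them is impractical otherwise.

## Hyperparameter search

The surrogate family behind the published Bayes-rule formulation is not
named; we use a Gaussian process with a Matérn-5/2 kernel plus a small
white-noise term (scikit-learn), behind an interface that admits a
density-ratio (TPE-style) replacement. The objective is maximized
(validation accuracy; the "minimize testing error" direction is a sign
flip handled internally). Each iteration scores 1,024 scrambled Sobol
candidates with the closed-form EI and evaluates the maximizer; the
initial design is a seeded Latin hypercube (≥2 points). Failed objective
evaluations are recorded in the trace and skipped by the surrogate.
Search bounds: learning rate [1e-5, 1e-2] on a log scale, β₁
[0.8, 0.999], β₂ [0.8, 0.9999], decay [0, 1e-3].

## Evaluation

Confusion rows are true classes, columns predictions (argmax of the
softmax; an optional per-class threshold vector exists but defaults to
plain argmax). Macro precision/recall/F1 are unweighted means across
classes. Zero-denominator metrics report 0 with an explicit flag and are
excluded from the corresponding macro average — never NaN.

## Synthetic cohort generator

The generator emulates the *statistical* structure the pipeline needs,
not physiological morphology. Per class: ECG is a train of narrow
von-Mises-shaped pulses at the class heart rate (defaults 70/80/105/55/65
bpm for baseline/amusement/stress/meditation/recovery) with beat-to-beat
jitter; BVP a sinusoid at the same rate; respiration a sinusoid at the
class breathing rate (14/18/24/7/11 breaths/min); EMG baseline noise plus
Poisson-timed half-sine bursts (8/15/30/3/6 per minute); accelerometer
variance scales with a class activity level (0.05/0.15/0.25/0.02/0.08 g)
with a shared-motion component giving nonzero axis correlations. Chest
streams are emitted as integer ADC units around midscale so unit
conversion is exercised; every adjacent class pair is separated by ≥ ~20 %
in heart or breathing rate so the minute features are discriminative.
Subjects differ by a multiplicative physiology factor N(1, 0.05), and all
randomness flows from one seed per subject.

Default class proportions follow the published benchmark distribution
(shares 0.479/0.204/0.114/0.065/0.138 of 573,480 aggregated samples);
default duration is 600 s per subject — a desk-scale choice (the source
cohort recorded ~100 min/subject). For training demonstrations we use
minute-aligned durations (`minute_aligned_durations`: 300/120/60/60/60 s
at 10 minutes) so minute-broadcast features are not mixed across a class
boundary inside one minute; with proportional (unaligned) schedules,
boundary minutes carry blended features and rare classes degrade first.

What passing tests therefore show: the pipeline arithmetic, the feature
definitions, the architecture audit, the optimizers and the split
machinery are correct, and the system can learn cleanly separable
rate-coded classes end to end. What they do not show: performance on real
wearable data, with motion artifacts, P-QRS-T morphology, drift,
inter-device clock skew or genuinely overlapping class physiology. The
published headline metrics (~97 % macro recall/precision) belong to the
real 15-subject dataset and are not reproduced here.

## Numerical conventions

- Cross-entropy clips predicted probabilities to [1e-12, 1]; reported
  loss is non-negative by construction.
- Peak ties (equal amplitude within the refractory distance) keep the
  earlier index; mode ties keep the lowest class code.
- Split sizes round half-up; remainders go to the test set.
- Correlation clipping to [−1, 1] happens after the 1/(N−1) mixed moment.
- All stochastic components (generator, initialization, shuffling,
  dropout, search) take explicit integer seeds; identical seeds give
  bit-identical results.

## Known limitations

- Type II folds on the 3-subject demonstration cohort train on only two
  subjects; cross-subject scores there are illustrative, not calibrated.
- The EMG burst model modulates the local mean rather than rectified
  high-frequency power, which is a simplification.
- The CSV recording bundle stores floats at 17 significant digits; exact
  bit-equality is only guaranteed by the HDF5 container.
- The generator does not model unlabeled transition spans by default
  (`unlabeled_lead_s` adds one at the recording start).
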
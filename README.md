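# wearstate

State-of-mind classification from multimodal wearable biosignals.

Affective state — whether a person is at baseline, amused, stressed,
meditating or recovering — leaves correlated traces across many
physiological channels, but no single biosignal carries a usable decision
threshold on its own. `wearstate` implements a complete pipeline for
classifying five such conditions from the two-device recording setup used
in wearable stress research: a chest-worn unit sampling ECG, EMG,
respiration, accelerometry, EDA and temperature at 700 Hz in raw 16-bit
ADC units, and a wrist-worn unit sampling blood volume pulse (64 Hz),
triaxial acceleration (32 Hz), EDA and temperature (4 Hz). It is a library
first (see `examples/`), with a thin `wearstate` CLI for shell use, and it
ships a synthetic cohort generator so the full pipeline runs end to end
with no external download.

## Pipeline

1. **Unit conversion** — chest ADC words map to SI units via
   `(raw / 2^16 − 0.5) · V_CC` (ECG → mV, EMG → µV, respiration → ±50 %
   displacement); the wrist accelerometer scales by 9.81/64 m/s² per raw
   unit (1/64 g resolution); BVP and temperature pass through.
2. **Frequency harmonization** — low-rate wrist streams are interpolated
   up to the 700 Hz chest grid, then every stream is aggregated to 10 Hz
   by averaging blocks of 70 samples; labels take the per-block mode.
3. **Feature engineering** — for ECG, EMG, respiration and BVP, peaks
   (local maxima above a `mean + k·sd` threshold, with a refractory
   minimum distance) are counted per minute and summarized into peak
   count, mean peak amplitude, mean absolute successive amplitude
   difference, and (ECG) peaks per second; the wrist accelerometer
   contributes 15 subject-level statistics (per-axis mean, sd, kurtosis,
   crest factor; pairwise correlations). Result: a 28-column matrix in
   five channel blocks {ECG 4, EMG 3, RESP 3, BVP 3, ACCL 15}.
4. **Model** — a five-branch 1-D CNN. Each branch applies two valid
   stride-1 convolutions (128 then 64 filters) whose kernel length is the
   adaptive rule *k = ⌈x/2⌉* for *x* input features, then
   flatten → dropout → dense 64 → dropout → dense 32; the five 32-unit
   outputs concatenate (width 160) into dense 32 → softmax 5. Training
   minimizes categorical cross-entropy with Adam (tuned defaults:
   lr 0.00125, β₁ 0.9765841, β₂ 0.8541287, decay 0.000235), RMSprop or
   SGD — all implemented in NumPy with seeded, bit-reproducible runs.
5. **Regimes & evaluation** — Type I: randomized 70/20/10
   train/val/test; Type II: leave-one-subject-out with an 80/20 split of
   the remainder. Reports are confusion matrices plus per-class and
   unweighted macro precision/recall/F1.
6. **Hyperparameter search** — sequential model-based optimization: a
   Matérn-5/2 Gaussian-process surrogate with the expected-improvement
   acquisition EI(x) = E[max(f(x) − f*, 0)] over learning rate (log
   scale), β₁, β₂ and decay.

## Worked example

```python
from wearstate import (assemble_feature_matrix, build_model, generate_cohort,
                       split_type1, train_model, OptimizerConfig)
from wearstate.synthetic import CohortParams, minute_aligned_durations

params = CohortParams(n_subjects=3,
                      class_durations_s=minute_aligned_durations(600), seed=7)
ds = assemble_feature_matrix(generate_cohort(params))   # (18000, 28) at 10 Hz
plan = split_type1(ds.n_samples, seed=1)
model = train_model(build_model(), ds, plan, OptimizerConfig(epochs=5), seed=1)
print(model.evaluate(ds, plan.test).macro_recall)
```

Running `examples/04_train_type1.py` (exactly this setup) prints a
training history that reaches train/validation accuracy 1.0 within one
epoch and ends with

```
test accuracy 1.0000, macro recall 1.0000
```

because the synthetic classes are separated by ≥ ~20 % in heart or
breathing rate and Type I shares minutes between train and test. The
cross-subject fold in `examples/05_leave_one_subject_out.py` is the honest
generalization test and scores substantially lower (accuracy 0.70 on the
held-out subject with only two training subjects), mirroring the gap
between randomized and subject-held-out evaluation on real cohorts.

The model audit (`examples/03_model_audit.py`, or `wearstate audit-model`)
prints the layer table — e.g. the accelerometer branch's first
convolution holds 128·(8·1)+128 = 1152 parameters and the concatenated
width is 160 — for 174,693 trainable parameters in total.

## Layout

- `src/wearstate/` — `io` (containers & HDF5/CSV formats), `units`,
  `resample`, `features`, `network` (declarative spec + audit), `nn`
  (NumPy forward/backward + optimizers), `training`, `smbo`,
  `evaluation`, `synthetic`, `cli`.
- `examples/` — one short narrative script per capability.
- `tests/` — unit, property and acceptance tests (pytest + hypothesis).
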
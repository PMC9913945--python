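# Methods

## Problem and data model

The package classifies subjects as healthy controls or schizophrenia
patients from averaged event-related potentials (ERPs) recorded during a
visual cued Go/NoGo task, together with four behavioral summaries. The
unit of analysis is the per-subject, per-condition, per-channel averaged
waveform (µV, 250 Hz, 19-channel 10–20 montage); single trials, raw EEG,
and artifact handling are upstream of this package and out of scope.

Five conditions are fixed: plus1 (P3cue, T5/O1/O2/T6, 320–520 ms after
the first stimulus), plus2 (CNV, P3/Pz/P4, 900–1080 ms after the first
stimulus), nogo (P300 NoGo, C3/Cz/C4/P3/Pz/P4, 300–500 ms after the
second stimulus), go (P3b, same channels, 250–450 ms), and ph (P3a,
C3/Cz/C4, 160–220 ms), for 22 channel-signals in total. Intervals are
half-open in samples, with millisecond→sample conversion by round-half-
to-even at the stated sampling rate; at 250 Hz the five intervals span
50/45/50/50/15 samples. The interchange format is long CSV
(`subject_id,group,condition,channel,time_ms,amplitude_uv`, times
relative to the condition's reference stimulus, amplitudes written at
6 decimals so file round-trips are exact).

## Window feature extraction

A signal of length `L` samples is windowed with window size `W` ms and
start-to-start shift of `S` % of the window:
`w = max(1, round(W·fs/1000))`, `s = max(1, round(w·S/100))`, windows at
`0, s, 2s, …` while they fit; a trailing remainder shorter than `w` is
dropped (no partial windows, so per-window statistics stay comparable).
The 1-sample floor keeps a 5 ms window representable at 250 Hz. Per
window the min/max/mean is emitted; per signal the global mean/max/min
and the serial numbers of the extremum windows are appended (3n + 5
features per signal; 986 ERP features at the default parameters).
Tie-breaking for the extremum-window features is first (lowest-index)
window. If the global extremum falls only in dropped remainder samples,
the feature falls back to the first window attaining the best
window-level extremum; the two rules coincide whenever the extremum is
inside any window. The `argmaxwin`/`argminwin` type tokens extend the
`{condition}_{channel}_{type}_{window}` template, and these index-valued
columns pass through the same scaler as everything else (the table is
scaled as one block, behavioral columns included).

Default per-condition window parameters are the best configuration
reported for this task — plus1 (49 ms, 50 %), plus2 (5, 50),
nogo (49, 100), go (20, 100), ph (5, 100) — giving 7/45/4/10/15 windows.
A coarse `smoke_window_params()` set (half-interval windows, 100 %
shift, 237 features with behavior) is provided for fast end-to-end runs
and is what the recovery benchmark uses.

## Classifiers

Logistic regression (L1/L2), k-nearest neighbors (probability = vote
fraction), RBF-kernel SVM, and a per-paradigm stacking ensemble. SVM
defaults follow the reported optimum: `gamma` scaled as
1/(n_features × feature variance) and C = 1/3; kNN uses 11 neighbors;
logreg C = 1. Class imbalance (132/68 by design) is handled by
inverse-frequency class weights or seeded minority upsampling; the two
give cross-validated F1 within 0.05 of each other on the default
synthetic cohort, consistent with their reported equivalence.

SVM class probabilities come from Platt (sigmoid) scaling of the
decision values, fitted by Newton iterations on the training rows with
Platt's regularized targets. Calibration is fitted on the same training
data as the SVM — a deliberate simplification (no inner calibration
split); thresholds are nevertheless chosen on out-of-fold predictions,
see below. Calibration is computed lazily so that hard-label scoring
inside feature selection never pays for it.

The stacking model fits one logistic regression per feature group (the
five conditions plus the behavior block) and an SVM meta-model on the
base probabilities. Meta-features are out-of-fold probabilities from a
seeded stratified inner split, so the meta-model never consumes a
probability produced by a base model trained on the same subject; base
models are refitted on all training rows for inference.

## Feature selection

- **Random-probe Shapley filter**: one standard-normal probe column is
  appended (seeded); after fitting, each feature's global importance is
  the mean |Shapley attribution| of the patient-class probability over
  training rows (permutation estimator, seeded background subsample of
  up to 100 rows, 8 permutations by default); features strictly above
  the probe importance are kept, the probe never is. The filter is most
  meaningful with a sparsity-inducing model: under L1 logistic
  regression, pure-noise tables yield empty or near-empty keeps, while
  dense L2 weights give every noise feature ~50 % odds of beating the
  probe.
- **Sequential feature selection**: greedy backward elimination (accept
  a removal while the inner-CV score does not decrease) or forward
  addition (require strict improvement), scored by seeded stratified
  inner CV (default 5 folds, F1). Candidate ties break by
  lexicographically smallest feature name — deterministic and cheap;
  attribution-based tie-breaking was rejected on cost grounds (ties are
  the common case with fold-averaged F1, and each would need a full
  Shapley pass over the candidate model). An optional `max_steps` cap
  bounds the number of accepted moves for budgeted runs; default is
  unlimited. Hyperparameters are held fixed during SFS (they come from
  the surrounding grid point). Scoring uses a pre-scaled per-fold
  matrix cache: all supported scalers are per-column, so column
  statistics are independent of the candidate subset and the cached
  scores equal the naive recomputation exactly.
- **Truncated SVD**: uncentered rank-k projection with k the smallest
  component count reaching a cumulative explained-variance fraction
  (default 0.95; retained for completeness — it underperformed the
  other strategies in the original application).

All selection is fitted strictly inside training folds; retained sets
may differ across outer folds.

## Evaluation

Stratified 10-fold outer CV (seeded shuffle). Per fold: extract → scale
→ select → fit on training rows only; choose the decision threshold on
out-of-fold predictions *within the training side* (an inner stratified
5-fold split, refitting the model per inner fold with the selected
features held fixed) — never on the test fold. The balanced threshold
minimizes |TPR − TNR| over midpoints of sorted unique probabilities,
ties broken by larger TPR + TNR, then smaller threshold. Sensitivity =
TPR over patients, specificity = TNR over controls, F1 with patient
positive, AUC by the rank statistic with half-credit for ties. Metrics
are reported as mean ± SD over folds; per-fold test confusion counts
are summed into one matrix whose row sums equal the true group sizes.

Grid search evaluates fully explicit pipeline configurations (window
parameters × selection × model hyperparameters × scaler) and ranks by
mean F1, ties by mean AUC, then fewer selected features; failing points
(e.g. a window larger than an interval) are recorded and skipped.
Window-feature extraction is per-subject and fits nothing, so the
feature table is built once per grid point rather than per fold; this
is an exact optimization, not an approximation.

`ERPClassifier`/`CrossValidationResults` wrap these functions in a
model-object API (construct from a dataset, `fit()` → results with
`summary()`); the functional layer remains public.

## Shapley attribution

Interventional Shapley values with respect to a background sample:
coalition value = mean model output over the background with coalition
columns replaced by the explained row. Two estimators: exact subset
enumeration for ≤ 12 features, and a seeded permutation estimator
(telescoping passes, additive by construction per permutation). For
linear models the exact estimator satisfies the null-player axiom
bit-exactly and symmetry to machine rounding (~1e-16 summation-order
effects inside the model's own dot product); the permutation estimator
converges to the exact values as permutations grow. Global importance
is the mean |attribution| over explained rows; the direction summary is
the Spearman correlation between feature values and signed
attributions (positive = larger values push toward the patient class),
with constant features flagged and reported as 0.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
at the study's design sizes (132 healthy, 68 patients):

- One Gaussian-bump component per condition, centred at the interval
  midpoint, temporal SD = interval/4, fixed channel topography, one
  per-subject amplitude draw per component
  (`N(group mean, 0.25·mean)`, truncated at 0) shared across that
  component's channels, plus i.i.d. Gaussian residual noise
  (SD 1.5 µV) on the averages. Waveforms cover the interval plus
  100 ms margins.
- Peak amplitudes are calibration choices (none are published):
  healthy 8/6/8/8/7 µV for plus1/plus2/nogo/go/ph with patient values
  5/3.5/5/5.5/4.5 µV — attenuation of roughly a third, matching the
  direction (not magnitude) of reported P300-family and CNV reductions;
  plus2 is negative (CNV). Against 1.5 µV noise and 25 % between-
  subject spread this leaves real group overlap per feature, so
  recovery is non-trivial but achievable.
- Behavior is drawn per subject from group normal models with the
  published group means/SDs (misses 1.6±2.8 vs 9.4±11.4 %, false
  clicks 0.7±1.3 vs 2.0±6.7 %, RT 379±79 vs 416±92 ms, RT variability
  8.4±2.6 vs 12.0±4.8), clipped to valid ranges. The published "±" is
  read as SD: plugging SDs into the two-level ANOVA reproduces the
  published F statistics (55.5/8.8/47.4 vs printed 56.7/8.9/48.5, ≤3 %
  off given rounded inputs), whereas an SE reading does not. The
  published RT header unit ("%") is treated as the obvious typo for
  ms, and RT variability as the coefficient of variation in percent
  (100·SD/mean), the only reading consistent with its magnitudes.
- `effect_scale` interpolates every patient parameter (component
  amplitudes and behavioral means/SDs) toward the healthy values;
  at 0 the groups are drawn from identical distributions. Scaling the
  behavioral gap as well is deliberate: a null cohort must be null
  everywhere or chance-level AUC is impossible.
- Randomness: one seed, per-subject substreams keyed (seed, subject
  index), so cohorts are bit-reproducible and early subjects are
  unchanged when counts grow. Amplitudes are quantized to 1e-6 µV so
  CSV round-trips are exact.
- Not emulated: 1/f background spectra, latency jitter, cross-channel
  noise covariance, medication effects, age/sex structure. Passing
  recovery tests therefore shows the pipeline recovers group structure
  of this form without leaking; it says nothing about clinical
  performance on real EEG.

Trial-level simulation (for testing the behavioral summaries) emits Go
misses and NoGo false presses as Bernoulli draws from the subject's
rates, with RTs from `N(rt, CV·rt)` clipped into the 200–1000 ms
validity window.

## Behavioral statistics

A press is valid within 200–1000 ms of the target stimulus; misses are
Go (A-A) trials without a valid press, false clicks are NoGo (A-P)
trials with any press; RT statistics use valid Go presses only. The
group comparison is the classical one-way two-level ANOVA (F on 1 and
n−2 df), computable from raw values or from summary statistics via the
identical closed form, and algebraically equal to the squared pooled
two-sample t. Its simulated type-I error rate at α = 0.05 is verified
at ~5 % over 1,000 null replicates.

## Problem sizes and numerical choices

The recovery benchmark uses the coarse smoke window parameters,
backward SFS capped at 3 accepted removals with 3 inner folds, and 10
outer folds on the 200-subject cohort (~2 minutes); the null-safety
check uses logistic regression without selection over 5 cohort seeds
(threshold-free AUC, identical fold machinery). The full Table-style
default parameters (986 features) are used wherever nothing is fitted
per candidate (counts, extraction, I/O). Degenerate cases: windows
larger than a signal raise a named error; single-class splits raise;
constant columns survive scaling (zero-variance guard in the scaler);
probe filters that keep nothing fall back to the full feature set with
a warning status inside pipeline dispatch.

## Known limitations

- The synthetic generator is a statistical stand-in; reported recovery
  metrics characterize the pipeline, not any clinical population.
- Backward SFS from the full 986-feature table without a step cap is
  O(p²) model fits and is impractical on one CPU; the cap trades
  optimality of the selected set for bounded runtime.
- The probe-Shapley filter's behavior depends on the paired model's
  regularization (see above); with dense models it is close to a coin
  flip per feature under the null.
- Only the RBF kernel is exercised by default for the SVM; other
  kernels are accepted via configuration but untuned.
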
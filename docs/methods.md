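# Methods

## Problem

Short-horizon forecasting of interstitial glucose from continuous glucose
monitoring (CGM) in type 2 diabetes: given the last six 5-min samples
(t0..t5, a 25-min window), predict the glucose concentration 15, 30 or 60
minutes after t5. The package implements two forecasters:

* **unimodal** — sequence only: BiLSTM → self-attention → 1D CNN →
  dense regressor with sigmoid output on Min-Max-scaled glucose;
* **multimodal** — the same sequence encoder fused (feature-axis
  concatenation followed by a fully connected layer, `Z3 = G(Z1 ⊕ Z2)`)
  with a dense encoder of static, unscaled baseline health-record
  variables (age, sex, HbA1c, anthropometrics, lipids, ...), organised in
  seven nested availability sets (set 0 = age + sex up to set 6 with 14
  variables).

## Model

The LSTM cell is the standard gated recurrence: forget/input/output gates
`σ(θ·[h_prev, x_t] + b)`, candidate state `tanh(θ_c·[h_prev, x_t] + b_c)`,
cell update `C_t = f ⊙ C_{t-1} + i ⊙ C̃_t`, hidden state
`h_t = o ⊙ tanh(C_t)`. The BiLSTM runs matched cells forward (t0→t5) and
backward (t5→t0) and concatenates per-step hidden states, giving a
(6 × 2H) sequence. Self-attention is parameter-free: the sequence is its
own query and value, scores are plain dot products, weights are row-wise
softmax (each row sums to 1), outputs are weight-averaged sequence rows.
The 1D convolution (kernel 3, stride 1, no padding, 100 filters by
default) yields `floor((6 − 3)/1) + 1 = 4` positions of ReLU feature maps,
flattened to `Z1` (4 × filters). Weights are Glorot-uniform initialised
(`U(±√(6/(fan_in + fan_out)))`), biases zero. Dropout: 10% after the CNN,
a separate 20% "stacked" rate after the fusion layer; both active only in
training mode.

Because no deep-learning framework is part of the dependency set, the
network and its training loop are implemented directly on a small
reverse-mode automatic-differentiation core (`cgmcast.nn.autodiff`) over
numpy arrays. A finite-difference gradient check on a miniature network is
part of the test suite (relative agreement better than 1e-4).

### Objectives

Default training loss is mean squared error on scaled targets, minimised
with Adam (lr 1e-3, batch 64, 50 epochs by default; all configurable and
fully seeded — identical seeds give bit-identical parameters). A listwise
log-likelihood objective `Σ_i (Ŷ_i − log Σ_{j∈t_i} exp Ŷ_j)` is also
implemented (`loss_listwise_loglik`); for a scalar single-horizon regressor its
candidate set degenerates to a singleton, where each term is identically
zero, so when selected for training the candidate set of a window is taken
as all windows of the same subject in the mini-batch. It is provided for
completeness; the evaluation studies train with MSE.

## Preprocessing

* Both sensor dialects are mapped to a common 5-min grid: 15-min series
  are upsampled by linear interpolation (a missing neighbour keeps the
  in-between points missing); 1-min series are downsampled to
  non-overlapping 5-min bin means labelled by bin start (robust to 1-min
  noise; plain decimation is available as an option).
* Patients with more than 50% missing data are excluded — strictly:
  exactly 50% is retained. The expected-sample denominator is
  `span/native_interval + 1`, computed on the native grid.
* Interior gaps are filled by linear interpolation; leading/trailing
  missing samples are dropped, not extrapolated (extrapolation would
  fabricate data). Gap locations are kept as metadata.
* Min-Max scaling to [0, 1] is fitted on training data only, per
  cross-validation fold (fitting globally would leak the test day's range);
  test values outside the training range map outside [0, 1] and are not
  clipped. A degenerate (constant) fit maps everything to 0 with a warning.
* An augmented Dickey-Fuller check (constant-only regression, fixed lag
  order, embedded large-sample 5% critical value −2.86) is provided as a
  stationarity QC flag; it never gates the pipeline.

## Windowing and validation

Windows slide with stride one. A window is dropped when its input+target
span crosses a calendar-day boundary or an imputed gap longer than 15 min;
windows containing any shorter imputed run are kept but flagged. The day
label of a window is the calendar date of its target, so leave-one-day-out
folds (one fold per distinct date, pooled across patients; train = all
other days, before and after) are leakage-free by construction. Each fold
retrains from a fresh fold-derived seed. Day folds are cohort-wide rather
than per patient (a configurable choice; the population-model reading).

## Metrics

The literature this package follows uses "MAPE" both for the mean absolute
percentage error `100·mean(|A−P|/A)` and for the mean absolute point error
in mg/dL. Both are computed side by side under unambiguous names
(`mape_percent`, `mean_absolute_point_error`), overall and stratified by
the *actual* glucose into hyperglycaemic (>180 mg/dL) and hypoglycaemic
(<70 mg/dL) subsets; empty strata are undefined (NaN), never zero.
Architecture comparisons use a paired two-sided t-test on per-point
absolute errors (the models score identical test points); all-zero
differences give p = 1, constant nonzero differences are flagged
degenerate.

## Clinical evaluation

The type-2 Parkes (consensus) error grid partitions the
(reference, predicted) plane on [0, 550]² mg/dL into zones A–E of
increasing clinical risk. The zone polygons ship as a versioned CSV
(`cgmcast/data/parkes_vertices_t2.csv`) whose provenance is recorded in
its header; the original publications print no machine-readable
coordinates, so the file follows the published real-coordinate
digitisation lineage and is swappable. Classification is point-in-polygon
with zones tested in A→E order, so boundary points resolve to the more
accurate zone. The test suite checks the diagonal, lattice totality,
severity monotonicity away from the diagonal, and agreement with an
independent boundary-band classifier.

AGP statistics use the standard conventions: cumulative time-in-range
bands (<54, <70, 70–180, >180, >250 mg/dL) over observed (non-imputed)
samples; mean glucose; GMI(%) = 3.31 + 0.02392 × mean glucose (the
ADAG-derived relation, consistent with the reference pair
146.1 mg/dL → 6.8%); %CV = 100 × sample SD / mean.

## Synthetic cohort generator

Real CGM cohorts of this kind are not redistributable, so `cgmcast.synth`
fabricates cohorts with the same statistical skeleton:

* **Population**: 40 patients by default, 15 on a 1-min-sampled sensor
  ("sensor1") and 25 on a 15-min-sampled sensor ("sensor2"), monitored
  8–28 days. (Published descriptions of such devices disagree on the
  native rates; the native interval is therefore a generator parameter.)
* **Baseline records**: every variable is a truncated normal at its
  published cohort mean ± SD (e.g. age 67 ± 9 y, HbA1c 7.42 ± 1.11%,
  weight 80.42 ± 28.46 kg); sex is Bernoulli with 55% female. Nested
  variable-availability attrition reproduces the seven availability sets,
  scaled to the population size.
* **Glucose dynamics**: `g(t) = B + A·sin(2πt/24h + φ) + Σ M_k·k(t−t_k) +
  ε(t)`, clamped to [40, 400] mg/dL. The basal level is tied to HbA1c via
  the ADAG estimated-average-glucose relation `eAG = 28.7·HbA1c − 46.7`,
  attenuated by `baseline_effect_scale` (0 = no baseline signal in the
  traces, 1 = full slope) — this is the channel that gives the multimodal
  branch something real to learn. Circadian amplitude U(8, 25) mg/dL with
  random phase; three meals near 08:00/13:00/20:00 (±45 min daily jitter)
  with amplitudes U(30, 70) mg/dL and a gamma-like response kernel
  `k(u) = (u/τ)·e^{1−u/τ}`, τ = 60 min; AR(1) noise with coefficient 0.9
  at 5-min steps (innovation SD per patient U(2, 8) mg/dL), rescaled to
  preserve autocorrelation and stationary variance on other grids.
* **Missingness**: contiguous dropout-like gaps (geometric lengths, mean 6
  samples) until the target fraction is met within ±2 points.

What the generator does *not* emulate: true glucose–insulin physiology,
meal/exercise/medication covariates, sensor calibration error or drift,
inter-day habit changes, device-specific noise spectra. Passing the
end-to-end tests therefore shows that the pipeline learns genuine
covariate-modulated structure from realistic-looking CGM data — not that
the clinical numbers would transfer to a real cohort.

## Scaled end-to-end study

`cgmcast.study.run_synthetic_study` is the desk-scale analogue of the full
cohort experiment: 12 patients (4 + 8 per sensor) × 10 days,
`baseline_effect_scale = 1`, 5% missingness, attrition off, variable set 1
(age, sex, HbA1c); a slimmed network (16 LSTM units/direction, 24 filters,
fusion width 32) trained 40 epochs (batch 128, lr 3e-3) on up to 12,000
training windows per fold; 2 of the 10 leave-one-day-out folds evaluated
per horizon. These sizes are the package's chosen desk-scale defaults; the
architecture, preprocessing and validation protocol are identical to the
full-scale configuration. Expected qualitative findings, reproduced by the
acceptance tests: error grows with horizon; at 60 min the multimodal model
is at least on par with (typically better than) the unimodal one and both
beat last-value persistence.

## Numerical choices and edge cases

* Timestamps are ISO-8601, indices 0-based; windows use half-open
  day-boundary conventions via the target's calendar date.
* Duplicate (patient, timestamp) rows collapse to their mean.
* The cell-state update uses elementwise addition; the conv output length
  uses the standard valid-convolution formula.
* Attention input must be finite; non-finite values are rejected rather
  than propagated through softmax.
* Zero-variance paired tests and degenerate scalers have explicit rules
  (see above) instead of NaN surprises.
* All randomness flows from integer seeds through
  `numpy.random.Generator`; cohort generation, parameter initialisation,
  batching and dropout are reproducible bit-for-bit.

## Known limitations

* The forecaster sees only the 6-sample window — no time-of-day input —
  so circadian and meal excursions beyond the window's evidence are
  irreducible error; gains over persistence are modest at 60 min by
  construction.
* The listwise objective is under-determined for scalar regression (see
  Objectives) and is not used by the default studies.
* The Parkes vertex digitisation is one published lineage among minor
  variants; swap the CSV to use another.
* Training is pure-numpy on CPU; it is sized for cohorts of tens of
  patients, not hundreds.
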
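# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices and the known limitations of `glucast`.

## Problem setting

The package targets short-term blood-glucose forecasting for children with
type 1 diabetes (T1D) in a supervised sports-camp setting: one week of
continuous or intermittently scanned glucose monitoring (CGM at 5-min,
isCGM at 15-min cadence plus manual scans), a logbook of self-monitored
blood glucose (SMBG), insulin doses (IE), carbohydrate intake (grams,
labelled fast/slow/mixed absorption) and physical-activity sessions
(minutes), plus eleven static characteristics per child (gender, age,
weight, height, BMI, diabetes duration, HbA1c, basal-insulin share, total
daily basal, total daily dose and calculated total daily dose, the last two
in U/kg/day). A hand-selected six-feature subset (gender, age, weight, BMI,
diabetes duration, basal-insulin share) is available as an alternative
conditioning set.

Forecasts are made at horizons of 30, 60 and 120 minutes (6, 12 and 24
steps on a 5-min grid) by a *population model*: one network trained on the
pooled data of all participants.

## Preprocessing

Sensor and SMBG glucose are merged into one measurement per timestamp: at a
sensor/SMBG collision the SMBG value wins; among residual duplicates the
lower value is kept. The merged series is resampled to a gapless 5-min grid
by time-weighted linear interpolation of glucose; insulin, carbohydrate and
activity entries are summed into the half-open window (t − 5 min, t] —
"assigned to the next time stamp" — with an activity session of D minutes
spread at up to 5 min per grid step so the feature sums to D. Days are
anchored at 7:00 a.m.; series are clipped from the first anchored 7:00 to
6:55 a.m. of the last day (a 6-day series has exactly 1728 points, 288 per
day).

Grid-edge policy: grid times outside the glucose measurement hull take the
nearest measurement's value only within one device cadence; a grid
extending further is rejected (no extrapolation). Sensor gaps longer than
1 h are interpolated across but logged for audit.

The chronological split takes the last `round(0.1666 · T)` points as the
test set — one full day for a 6-day series — the preceding equal-sized
block as validation, and the remainder (4 days) for training.

**Standardization.** Each `SplitSeries` carries a per-participant
standardizer fitted on its own training segment. The population model,
however, standardizes all features (and the static vectors) with *pooled*
training statistics across participants. This is deliberate: per-participant
standardization removes between-child level and scale differences, which
are precisely the heterogeneity the static characteristics explain; a
population model standardized per participant sees almost no exploitable
static signal. Predictions are inverse-transformed to mmol/l before any
metric is computed.

## Models

Three recurrent cells (vanilla RNN, GRU, LSTM) in stacks of {3, 5} layers
of {16, 32} units, each optionally *dilated*: layer *l* reads its own state
from 2^(l−1) steps back (schedule 1, 2, 4, …). Dilation is implemented as a
per-layer lagged recurrence (a ring buffer of the last 2^(l−1) states)
rather than the sub-sequence reshaping trick — mathematically the same skip
pattern, simpler to keep stateful across chunk boundaries.

All recurrent layers use the dual-bias convention (separate input-side and
recurrent-side bias per gate; for the GRU the recurrent candidate bias sits
inside the reset gate, so the two are genuinely distinct). Under this
convention the hyperparameter grid spans 1 505 (RNN 3×16) to 39 073
(LSTM 5×32) trainable parameters (reported as "1.5k" to "39k").

Static integration strategies:

* **init** — `h₋₁ = MLP_init(s)`: one feed-forward network with a single
  ReLU hidden layer, hidden and output width equal to the layer width; its
  output initializes *every* layer's state (LSTMs use a distinct,
  equally-sized network for the cell state). A per-layer variant with an
  initializer of output width `n_layers · n_units` was considered and
  rejected in favour of the shared-state convention, whose parameter
  range with static integration runs from 1 889 for RNN 3×16 with 6
  statics up to 46 583 ≈ 47k for LSTM 5×32 with 11 statics.
* **cat** — `ŷ_t = MLP_head(o_t, MLP_cat(s))`: `MLP_cat` has one hidden
  layer of width `2·#s` and output width 2; `MLP_head` has hidden widths
  `2·#h` and `#h` (ReLU throughout).
* **both** — init and cat combined.
* **none** — for completeness the plain models use a single linear layer
  from the hidden width to the output; this keeps the plain models at the
  small end of the parameter range.

Models run sequence-to-sequence: the output at input step *t* estimates
glucose at *t + horizon*. Hidden state persists across consecutive calls
until an explicit reset.

An optional quantile head emits one output per level
Q = {0.02, 0.1, 0.25, 0.5, 0.75, 0.9, 0.98} and is trained with the pinball
loss `QL(y, ŷ, q) = q(y − ŷ)₊ + (1 − q)(ŷ − y)₊` summed over levels and
averaged over samples. Raw quantile outputs may cross; they are monotonised
by sorting at inference (training uses the raw outputs). The point forecast
is the median channel.

The numerical core (dense/recurrent layers with hand-derived gradients,
Adam with L2 weight decay) is implemented directly on numpy arrays; all
gradients are verified against central finite differences in the test
suite's construction checks and were cross-checked during development.

## Training

Population training uses two nested loops: epochs outside, participants
inside, with the participant order reshuffled (seeded) every epoch. The
hidden state is reset before each participant — to zeros, or from the
static vector under init/both. "Batch size 256" is realised as truncated
backpropagation through contiguous 256-step chunks of one participant's
training segment (one gradient step per chunk, state carried forward), which
preserves the memory of the cell state across the segment. The optimizer is
Adam (learning rate 1e-3, L2 weight decay 1e-3 added to the gradient).
Recurrent models train for a fixed number of epochs (200 in the full
profile); early stopping (patience 5, minimum delta 1e-4) is exposed as an
option intended for quantile-head runs. The validation loss reported per
epoch is the mean of per-participant mean losses (equal participant
weighting). Gradients do not flow across chunk boundaries, but the
state-buffer gradient of the first chunk after a reset is propagated into
the initializer MLPs so the init pathway actually trains.

Grid search trains every (depth, width) grid point for every seed and picks
the configuration with the lowest mean final validation loss; ties break by
fewer parameters, then lexicographic configuration order.

## Evaluation

Two protocols score one anchored test day: *full day* with a 2-h lookup
window (the first 24 test inputs only update the hidden state) and *night*
with a 12-h window (144 inputs, so scored predictions are fed by inputs
from 7 p.m. to 6:55 a.m.). Warm-up is indexed on the **input** step: a
prediction is scored when its input index is ≥ the warm-up length and its
target stays inside the day (a target-indexed reading would shift the
scored set by the horizon; the input-indexed reading is used consistently).
A 288-point day with 144 warm-up steps and a 6-step horizon yields 138
scored predictions.

Metrics: RMSE (mmol/l), MAPE (×100, i.e. percent) and R² (can be negative),
all computed on inverse-standardized values. Pooled aggregation
concatenates all participants' scored points per seed, computes the metric,
and reports mean ± standard error over seeds (SD/√n_seeds, with n_seeds = 3
by default). Participant-level aggregation first averages over seeds per
participant, then reports mean and SD across participants.

Baselines: *identity* predicts glucose at t + h as the value at t; the
*linear* model is a single affine map from the seven features at t, trained
with the same population scheme.

**Parkes consensus error grid.** Zones A–E of increasing clinical risk are
assigned by point-in-polygon tests against the widely published type-1
vertex coordinates (mg/dl; digitisation by Pfützner et al., J Diabetes Sci
Technol 2013). mmol/l is converted at 18.016 mg/dl per mmol/l (glucose
molar mass). The published boundary polylines end at 550 mg/dl; terminal
segments are extended along their final slope so values up to the sensor
saturation limit (33.3 mmol/l ≈ 600 mg/dl) classify. Cumulative regions are
tested from safest outward, so boundary points land in the safer zone. The
grid kind is exposed (`grid_kind="type1"`) for future variants.

## Synthetic cohort generator

The restricted study data cannot be redistributed, so the generator
emulates the camp conditions: 14 children (5 CGM, 9 isCGM), 6 study days
(one child truncated to the last 4 days), structured morning and afternoon
activity sessions on days 2–6 plus a day-1 outing, and a fixed daily meal
pattern.

Static characteristics are drawn from truncated normals matching the
reference cohort summary statistics the generator targets (age 11.2 ± 2.1 in [7.5, 13.9] years, BMI
19.5 ± 4.2, weight 45.1 ± 16.5 kg, height 149.4 ± 14.1 cm, diabetes
duration 3.8 ± 2.8 y, HbA1c 7.2 ± 0.8 %, basal share 46.1 ± 12.5 %,
calculated total daily dose 0.90 ± 0.39 U/kg/d); BMI is recomputed from the
sampled weight and height (re-drawn until anatomically plausible), and the
female fraction is 5/14 in expectation.

The latent 1-min glucose trajectory is

    g(t) = baseline(t) + Σ_m grams_m · Kc(t − t_m) · carb_gain
                       − S(t) · Σ_b dose_b · Ki(t − t_b) · isf
                       − activity drain + AR(1) noise,

clipped to (1.0, 33.3) mmol/l. Kernels are peak-normalised log-normal
impulse responses with times-to-peak 30 min (fast carbs), 60 min (mixed),
120 min (slow) and 75 min (short-acting insulin); long-acting insulin
contributes a sustained near-flat offset. These shapes and constants are
generator parameters (`GeneratorParams`), not claims about physiology.

The circadian baseline level follows the ADAG HbA1c↔mean-glucose
relationship (slope 1.59 mmol/l per %), with a dawn-phenomenon bump whose
amplitude grows with age. The insulin-sensitivity factor S(t) combines a
static gain — monotone increasing in age, decreasing in BMI, mildly
increasing in basal share, clipped to [0.4, 1.6] (correlation with age
above 0.3 across a large cohort) — with an activity-triggered relative
elevation (~0.5 per hour of exercise) decaying over 24 h. Meal boluses are
dosed with *population-average* rules (500-rule carb ratio on the child's
total daily dose) while the realised effect uses the child's own
sensitivity: this dosing/response mismatch is one channel through which the
statics shape the observable dynamics. The AR(1) noise is a second channel:
its lag-1 coefficient at 5-min scale is 0.95 at the mean age and increases
by 0.012 per year (younger children show more labile glycemia), and its
stationary SD (1.0 mmol/l) scales with HbA1c. With noise disabled, carb and
insulin responses superpose linearly (clipping is the only nonlinearity),
which the tests exploit.

The observation process samples the trajectory at device cadence with
additive sensor noise (SD 0.3 mmol/l); isCGM children receive additional
scan-time records (~8/day while awake). SMBG records are emitted at the
camp protocol's triggers — sensor below 3.9 mmol/l, sensor above
15 mmol/l, before and after each activity session, hourly during sessions —
plus a Bernoulli symptom-driven check (p = 0.3 per 15-min block) when
latent glucose is below 4.5 mmol/l, since symptomatic hypoglycemia itself
is unobservable. A configurable fraction of duplicate sensor timestamps is
injected to exercise the merging rules. When latent glucose falls below
3.6 mmol/l the camp staff administer ~15 g of fast carbs (45-min
refractory); this rescue feedback is on for cohort generation and off for
the linearity-preserving single-response API. Hybrid closed-loop pumps are
excluded from the study population and are simply never generated.
Timestamps are timezone-naive local clock times (single-site study; the
7 a.m. day anchor is a local convention).

### What the generator does and does not emulate

It reproduces the *structure* of the study data — cadences, triggers,
schedules, static distributions, statics-dependent dynamics — but not real
CGM physics (compression lows, sensor drift, calibration error), real meal
variety, or behavioural feedback beyond the hypoglycemia rescue. Passing
the directional tests on this cohort shows the pipeline and models behave
as the method intends under known dynamics; it does not certify clinical
performance on real pediatric data.

## Study sizes and reproducibility

The default end-to-end study (`glucast.experiments.run_trend_study` and
`scripts/acceptance.py`) trains the smallest grid point (vanilla RNN,
3 layers × 16 units) with and without static concatenation, at horizons 30
and 120 min, for 3 seeds × 25 epochs on the full 14-child, 6-day cohort —
a size chosen so the complete study runs in a few minutes on one CPU core
while the directional effects (static integration helps at 30 min; error
grows with horizon) are stable across seeds. The full hyperparameter grid
({3,5} × {16,32}, 200 epochs) is available as the CLI's `paper` profile. All randomness (cohort, initialisation, shuffling) derives from
explicit seeds; identical configs re-run to identical results.

## Known limitations

* The generator's kernels are phenomenological; no claim of physiological
  fidelity (a UVA/Padova-style simulator is out of scope).
* The linear baseline and recurrent models share the chunked training
  scheme; very short segments (shorter than the horizon) are skipped with
  a warning rather than padded.
* Quantile-head training is exposed and tested at the loss level, but the
  shipped study profiles train point forecasters only.
* Transformer-style forecasters (e.g. the Temporal Fusion Transformer) are
  out of scope; only the quantile loss and the 24/144-step look-back
  configuration associated with that model family appear here.
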
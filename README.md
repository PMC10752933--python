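# glucast

Blood-glucose forecasting for children with type 1 diabetes (T1D), built
around the setting of a supervised sports camp: continuous glucose
monitoring (CGM/isCGM) streams merged with a logbook of insulin doses,
carbohydrate intake, physical activity and fingerstick measurements, plus
static participant characteristics (age, BMI, basal-insulin share, …).

Forecasting for exercising children is harder than the widely studied adult
setting: insulin requirements vary with age and development, and physical
activity has both an immediate glucose-lowering effect and a long-lasting
effect on insulin sensitivity. The package is for researchers who want a
fully tested, reproducible pipeline for this problem — including a
synthetic cohort generator, because real pediatric datasets of this kind
are privacy-restricted.

## What it provides

* **Synthetic camp cohorts** (`glucast.synthetic`) — latent 1-min glucose
  trajectories driven by meal/insulin/activity impulse responses on a
  circadian baseline, observed through realistic sensor cadences, SMBG
  trigger rules and logbook events; static characteristics drawn from the
  published cohort distributions, and dynamics that genuinely depend on
  them.
* **Preprocessing** (`glucast.preprocessing`) — merging with
  SMBG-overrides-sensor and lower-duplicate-wins rules, time-weighted
  interpolation onto a gapless 5-min grid, event summation "to the next
  time stamp", 7 a.m. day anchoring, and the chronological 16.66 % /
  16.66 % validation/test split (one full 288-point test day per child).
* **Models** (`glucast.models`) — stateful vanilla and dilated RNN/GRU/LSTM
  stacks (dilation 2^(l−1) in layer l) with four static-integration
  strategies: `none`, hidden-state initialisation (`init`,
  h₋₁ = MLP_init(s)), output concatenation (`cat`,
  ŷₜ = MLP_head(oₜ, MLP_cat(s))) and `both`; optional quantile head with
  the pinball loss over Q = {0.02, 0.1, 0.25, 0.5, 0.75, 0.9, 0.98}.
  Implemented directly in numpy with hand-derived gradients.
* **Training** (`glucast.training`) — population-model training (epochs ×
  shuffled participants, hidden-state reset per participant, truncated BPTT
  over contiguous 256-step chunks, Adam with learning rate 1e-3 and weight
  decay 1e-3) and grid search over {3, 5} layers × {16, 32} units.
* **Evaluation** (`glucast.evaluation`, `glucast.parkes`) — RMSE / MAPE /
  R² in mmol/l, full-day (2-h warm-up) and night (12-h warm-up, 7 p.m.–6:55
  a.m.) protocols, pooled and per-participant aggregation over seeds, and
  Parkes consensus error grids (type 1) with zone percentages and figures.
* **CLI** (`glucast run|generate|preprocess|train|evaluate|report`) —
  config-driven, reproducible experiment bundles with metrics tables,
  Parkes figures, a leaderboard and a run manifest.

## Worked example

Train the smallest grid configuration with static concatenation on a
synthetic cohort and score the full-day 30-min protocol:

```python
from glucast import RecurrentConfig, build_model, count_parameters
from glucast.experiments import build_synthetic_cohort
from glucast.training import TrainingPlan, train_population
from glucast.evaluation import (EvaluationProtocol, EvaluationReport,
                                evaluate, baseline_identity)

cohort = build_synthetic_cohort(seed=1)          # 14 children, 6 days
config = RecurrentConfig("rnn", n_layers=3, n_units=16,
                         integration="cat", static_dim=6, horizon=6)
print("parameters:", count_parameters(build_model(config)))

plan = TrainingPlan(epochs=25, seeds=(1,))
run = train_population(plan, cohort, config, seed=1)

protocol = EvaluationProtocol(horizon_min=30, window_label="full_day")
report = EvaluationReport(protocol=protocol, entries=[
    evaluate(run.model, split, protocol,
             statics=cohort.static_vector(pid), seed=1,
             standardizer=cohort.standardizer_for(pid))
    for pid, split in cohort.splits.items()])
print(f"RNN+cat  test RMSE: {report.pooled()['rmse'][0]:.2f} mmol/l")

ident = EvaluationReport(protocol=protocol, entries=[
    baseline_identity(split.test, protocol)
    for split in cohort.splits.values()])
print(f"identity test RMSE: {ident.pooled()['rmse'][0]:.2f} mmol/l")
print("Parkes zones:", report.parkes())
```

Output:

```
parameters: 2751
RNN+cat  test RMSE: 1.01 mmol/l
identity test RMSE: 1.76 mmol/l
Parkes zones: {'A': 88.79, 'B': 9.04, 'C': 2.13, 'D': 0.03, 'E': 0.0}
```

The trained forecaster roughly halves the naive identity baseline's error,
and ~98 % of its predictions fall in the clinically benign Parkes zones A
and B. The same study run without static integration (`integration="none"`)
gives a higher RMSE — conditioning on the child's characteristics helps the
population model, most visibly at the 30-min horizon — and errors grow
substantially from the 30-min to the 120-min horizon.

The full pipeline is also available from the shell:

```sh
glucast run --seed 1 --out my_run            # fast profile
glucast run --profile paper --out full_run   # full grid, 200 epochs
```

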
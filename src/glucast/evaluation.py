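"""Metrics, evaluation protocols and result aggregation.

Two protocols score one anchored test day per participant:

* ``full_day`` — a 2-h lookup window: the first 24 test inputs only update
  the hidden state and are not scored;
* ``night`` — a 12-h lookup window (144 inputs), so scored predictions are
  fed by inputs from 7 p.m. onward (the test day starts 7 a.m.).

Warm-up is indexed on the *input* step: a prediction is scored when its
input index is at least ``warmup_steps`` and its target stays inside the
day. Metrics (RMSE in mmol/l, MAPE in percent, R²) are computed on
inverse-standardized values. Pooled aggregation concatenates all
participants' scored points per seed before computing the metric and
reports mean ± standard error over seeds; participant-level aggregation
averages over seeds per participant first and then reports mean and SD
across participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import ForecastModel
from .parkes import ZONES, parkes_report
from .types import FEATURES, RegularSeries, SplitSeries

_GLUCOSE = FEATURES.index("glucose")


# ---------------------------------------------------------------------------
# metrics


def _check_pair(y: np.ndarray, y_hat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {y_hat.shape}")
    if y.size < 2:
        raise ValueError("need at least two points")
    return y, y_hat


def rmse(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Root mean squared error, same units as ``y`` (mmol/l here)."""
    y, y_hat = _check_pair(y, y_hat)
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def mape(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean absolute percentage error, reported ×100."""
    y, y_hat = _check_pair(y, y_hat)
    if np.any(y == 0):
        raise ValueError("mape undefined for zero reference values")
    return float(100.0 * np.mean(np.abs(y - y_hat) / np.abs(y)))


def r2(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Coefficient of determination; may be negative."""
    y, y_hat = _check_pair(y, y_hat)
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# protocols


@dataclass(frozen=True)
class EvaluationProtocol:
    """Scoring window on the test day."""

    horizon_min: int = 30  # 30 / 60 / 120
    window_label: str = "full_day"  # or "night"

    def __post_init__(self) -> None:
        if self.horizon_min not in (30, 60, 120):
            raise ValueError("horizon must be 30, 60 or 120 minutes")
        if self.window_label not in ("full_day", "night"):
            raise ValueError("window_label must be 'full_day' or 'night'")

    @property
    def horizon_steps(self) -> int:
        return self.horizon_min // 5

    @property
    def warmup_steps(self) -> int:
        """Lookup window in 5-min steps: 2 h for the full day, 12 h at
        night."""
        return 24 if self.window_label == "full_day" else 144


@dataclass
class EvalEntry:
    """Scored test-day forecasts of one (model, seed, participant)."""

    participant_id: str
    seed: int
    protocol: EvaluationProtocol
    references: np.ndarray  # mmol/l
    predictions: np.ndarray  # mmol/l

    @property
    def rmse(self) -> float:
        return rmse(self.references, self.predictions)

    @property
    def mape(self) -> float:
        return mape(self.references, self.predictions)

    @property
    def r2(self) -> float:
        return r2(self.references, self.predictions)


def _scored_indices(n_test: int, protocol: EvaluationProtocol) -> tuple[int, int]:
    h = protocol.horizon_steps
    w = protocol.warmup_steps
    if n_test < w + h + 2:
        raise ValueError(
            f"test day of {n_test} points too short for warmup {w} + horizon {h}"
        )
    return w, n_test - h


def evaluate(
    model: ForecastModel,
    split: SplitSeries,
    protocol: EvaluationProtocol,
    statics: np.ndarray | None = None,
    seed: int = 0,
    standardizer=None,
) -> EvalEntry:
    """Score a trained model on one participant's test day.

    The model is reset, the whole day is passed statefully, and predictions
    whose input index is at least ``warmup_steps`` (and whose target lies in
    the day) are scored against inverse-standardized glucose. Pass the
    cohort's pooled ``standardizer`` when the model was trained as a
    population model; defaults to the participant's own.
    """
    test = split.test
    h = protocol.horizon_steps
    lo, hi = _scored_indices(len(test), protocol)
    standardizer = standardizer or split.standardizer
    z = standardizer.transform(test.values())
    model.reset(statics if model.config.integration != "none" else None)
    out = model.predict(z[: len(test) - h], statics)
    preds_std = model.point_predictions(out)
    y_hat = standardizer.inverse_glucose(preds_std[lo:hi])
    y_ref = test.glucose[lo + h : hi + h]
    return EvalEntry(
        participant_id=test.participant_id,
        seed=seed,
        protocol=protocol,
        references=y_ref,
        predictions=y_hat,
    )


# ---------------------------------------------------------------------------
# baselines


def baseline_identity(
    test: RegularSeries, protocol: EvaluationProtocol
) -> EvalEntry:
    """Identity baseline: the forecast at ``t + horizon`` is glucose at
    ``t``."""
    h = protocol.horizon_steps
    lo, hi = _scored_indices(len(test), protocol)
    g = test.glucose
    return EvalEntry(
        participant_id=test.participant_id,
        seed=0,
        protocol=protocol,
        references=g[lo + h : hi + h],
        predictions=g[lo:hi],
    )


class LinearForecaster:
    """One-layer affine map from the seven features at ``t`` to glucose at
    ``t + horizon`` — the linear reference model. Duck-types the forecaster
    interface used by the training loop (stateless)."""

    def __init__(self, config, n_features: int = 7, seed: int = 0):
        from ._nn import Dense

        self.config = config
        self.n_features = n_features
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 307]))
        self.head = Dense(n_features, 1, rng)

    def reset(self, s=None) -> None:  # stateless
        pass

    def forward(self, window, s=None, train: bool = False):
        return self.head.forward(np.asarray(window, dtype=float), train=train)

    def predict(self, window, s=None):
        return self.forward(window, s)

    def point_predictions(self, out):
        return out[:, 0]

    def backward(self, d_out) -> None:
        self.head.backward(d_out)

    def parameters(self):
        return self.head.parameters()


def baseline_linear(
    cohort,
    plan,
    protocol: EvaluationProtocol,
    seed: int = 0,
    epochs: int | None = None,
) -> dict[str, EvalEntry]:
    """Train the linear reference model with the population scheme and score
    it per participant."""
    from .models import RecurrentConfig
    from .training import train_population

    config = RecurrentConfig(
        cell="rnn", n_layers=1, n_units=1, horizon=protocol.horizon_steps
    )
    model = LinearForecaster(config, seed=seed)
    run = train_population(
        plan, cohort, config, seed, model=model, epochs=epochs
    )
    return {
        pid: evaluate(
            run.model,
            split,
            protocol,
            seed=seed,
            standardizer=cohort.standardizer_for(pid),
        )
        for pid, split in cohort.splits.items()
    }


# ---------------------------------------------------------------------------
# aggregation


@dataclass
class EvaluationReport:
    """Per-participant entries for several seeds plus aggregate tables."""

    protocol: EvaluationProtocol
    entries: list[EvalEntry] = field(default_factory=list)

    def per_participant_frame(self) -> pd.DataFrame:
        rows = [
            {
                "participant_id": e.participant_id,
                "seed": e.seed,
                "rmse": e.rmse,
                "mape": e.mape,
                "r2": e.r2,
            }
            for e in self.entries
        ]
        return pd.DataFrame(rows)

    def pooled(self) -> dict[str, tuple[float, float]]:
        """Per seed, concatenate all participants' scored points, compute
        each metric, then report (mean, standard error) over seeds."""
        seeds = sorted({e.seed for e in self.entries})
        per_seed = {"rmse": [], "mape": [], "r2": []}
        for s in seeds:
            sel = [e for e in self.entries if e.seed == s]
            refs = np.concatenate([e.references for e in sel])
            preds = np.concatenate([e.predictions for e in sel])
            per_seed["rmse"].append(rmse(refs, preds))
            per_seed["mape"].append(mape(refs, preds))
            per_seed["r2"].append(r2(refs, preds))
        out = {}
        n = max(len(seeds), 1)
        for k, v in per_seed.items():
            v = np.asarray(v)
            out[k] = (float(v.mean()), float(v.std(ddof=0) / np.sqrt(n)))
        return out

    def participant_average(self) -> dict[str, tuple[float, float]]:
        """Two-stage aggregation: per-participant mean over seeds, then mean
        and SD across participants."""
        frame = self.per_participant_frame()
        means = frame.groupby("participant_id")[["rmse", "mape", "r2"]].mean()
        return {
            k: (float(means[k].mean()), float(means[k].std(ddof=0)))
            for k in ("rmse", "mape", "r2")
        }

    def parkes(self, plot_path=None, title: str | None = None) -> dict[str, float]:
        refs = np.concatenate([e.references for e in self.entries])
        preds = np.concatenate([e.predictions for e in self.entries])
        preds = np.clip(preds, 0.1, 33.3)  # grid domain
        return parkes_report(refs, preds, plot_path=plot_path, title=title)


__all__ = [
    "rmse",
    "mape",
    "r2",
    "EvaluationProtocol",
    "EvalEntry",
    "evaluate",
    "baseline_identity",
    "LinearForecaster",
    "baseline_linear",
    "EvaluationReport",
    "ZONES",
]
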
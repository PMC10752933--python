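"""Population-model training across participants.

One model is trained on the pooled training segments of all participants
with two nested loops: epochs outside, participants inside, the participant
order reshuffled at the start of every epoch. The hidden state is reset
before each participant — to zeros, or from the static vector when the
integration strategy asks for it — and the participant's training segment is
then traversed statefully in contiguous chunks of ``batch_size`` steps
(truncated backpropagation per chunk). The optimizer is Adam with learning
rate 1e-3 and L2 weight decay 1e-3; the loss is the mean squared error on
standardized glucose, or the pinball loss for quantile heads. The validation
loss aggregated each epoch is the mean of per-participant mean losses.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from ._nn import Adam
from .models import (
    ForecastModel,
    RecurrentConfig,
    build_model,
    count_parameters,
    quantile_loss,
    quantile_loss_grad,
)
from .types import FEATURES, ParticipantStatics, SplitSeries, Standardizer

logger = logging.getLogger(__name__)

_GLUCOSE = FEATURES.index("glucose")


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""

    def __init__(self, epoch: int, participant_id: str):
        super().__init__(
            f"non-finite loss at epoch {epoch}, participant {participant_id}"
        )
        self.epoch = epoch
        self.participant_id = participant_id


@dataclass(frozen=True)
class TrainingPlan:
    """Optimization hyperparameters shared by all recurrent models."""

    learning_rate: float = 1e-3
    weight_decay: float = 1e-3
    batch_size: int = 256
    epochs: int = 200
    seeds: tuple[int, ...] = (0, 1, 2)
    early_stopping: bool = False  # used for quantile-head runs only
    patience: int = 5
    min_delta: float = 1e-4


@dataclass
class TrainRun:
    """Result of one (config, seed) training run."""

    config: RecurrentConfig
    seed: int
    model: ForecastModel
    train_losses: list[float]
    val_losses: list[float]

    @property
    def final_val_loss(self) -> float:
        return self.val_losses[-1] if self.val_losses else float("inf")


@dataclass
class FitResult:
    """Grid-search outcome: selected config plus the full leaderboard."""

    best_config: RecurrentConfig
    leaderboard: pd.DataFrame  # one row per config: mean val loss, params
    runs: dict[tuple, list[TrainRun]]  # config key -> runs per seed

    def best_runs(self) -> list[TrainRun]:
        return self.runs[_config_key(self.best_config)]


@dataclass
class Cohort:
    """Preprocessed cohort: per-participant splits plus static vectors.

    The population model standardizes all features on the pooled training
    data of every participant (``standardizer``), so between-child level
    and scale differences stay visible to the model — they are exactly what
    the static features explain. Static vectors are likewise z-scored
    across the cohort.
    """

    splits: dict[str, SplitSeries]
    statics: dict[str, np.ndarray] = field(default_factory=dict)
    standardizer: "Standardizer | None" = None

    @classmethod
    def assemble(
        cls,
        splits: dict[str, SplitSeries],
        statics: dict[str, ParticipantStatics] | None = None,
        subset: str = "all",
    ) -> "Cohort":
        vectors: dict[str, np.ndarray] = {}
        if statics:
            raw = {pid: st.vector(subset) for pid, st in statics.items()}
            mat = np.array(list(raw.values()))
            mean = mat.mean(axis=0)
            sd = mat.std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
            vectors = {pid: (v - mean) / sd for pid, v in raw.items()}
        pooled = Standardizer.fit(
            np.concatenate([s.train.values() for s in splits.values()], axis=0)
        )
        return cls(splits=splits, statics=vectors, standardizer=pooled)

    @property
    def participant_ids(self) -> list[str]:
        return list(self.splits)

    def static_vector(self, pid: str) -> np.ndarray | None:
        return self.statics.get(pid)

    def standardizer_for(self, pid: str) -> "Standardizer":
        return self.standardizer or self.splits[pid].standardizer


def make_supervised_pairs(
    split: SplitSeries, horizon: int, standardizer: "Standardizer | None" = None
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Standardized (input, target) arrays per segment.

    For each step ``t`` with ``t + horizon`` inside the same segment the
    target is standardized glucose at ``t + horizon``; pairs never straddle
    segment boundaries. A segment shorter than the horizon yields an empty
    stream (flagged in the log).
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    standardizer = standardizer or split.standardizer
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name in ("train", "validation", "test"):
        seg = getattr(split, name)
        z = standardizer.transform(seg.values())
        if len(z) <= horizon:
            logger.warning(
                "%s segment of %s shorter than horizon %d: empty pair stream",
                name,
                split.participant_id,
                horizon,
            )
            out[name] = (z[:0], z[:0, _GLUCOSE])
            continue
        out[name] = (z[:-horizon], z[horizon:, _GLUCOSE])
    return out


def _chunk_bounds(n: int, size: int) -> list[tuple[int, int]]:
    return [(i, min(i + size, n)) for i in range(0, n, size)]


def _loss_and_grad(
    model: ForecastModel, preds: np.ndarray, targets: np.ndarray
) -> tuple[float, np.ndarray]:
    if model.config.quantile_head:
        loss = quantile_loss(targets, preds, model.config.quantiles)
        grad = quantile_loss_grad(targets, preds, model.config.quantiles)
        return loss, grad
    err = preds[:, 0] - targets
    loss = float(np.mean(err**2))
    grad = (2.0 * err / len(err))[:, None]
    return loss, grad


def _segment_loss(
    model: ForecastModel, cohort: Cohort, pairs, segment: str
) -> float:
    """Mean of per-participant mean losses on a segment (stateful pass per
    participant after a fresh reset)."""
    losses = []
    for pid in cohort.participant_ids:
        X, y = pairs[pid][segment]
        if len(X) == 0:
            continue
        model.reset(cohort.static_vector(pid) if model.config.integration != "none" else None)
        preds = model.forward(X, cohort.static_vector(pid))
        loss, _ = _loss_and_grad(model, preds, y)
        losses.append(loss)
    return float(np.mean(losses)) if losses else float("nan")


def train_population(
    plan: TrainingPlan,
    cohort: Cohort,
    config: RecurrentConfig,
    seed: int,
    *,
    model: ForecastModel | None = None,
    epochs: int | None = None,
) -> TrainRun:
    """Train one population model; deterministic given ``seed``."""
    for pid, split in cohort.splits.items():
        if len(split.train) == 0 or len(split.validation) == 0:
            raise ValueError(f"participant {pid} has an empty train/validation segment")
    if model is None:
        model = build_model(config, seed=seed)
    opt = Adam(
        model.parameters(), lr=plan.learning_rate, weight_decay=plan.weight_decay
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 211]))
    pairs = {
        pid: make_supervised_pairs(split, config.horizon, cohort.standardizer_for(pid))
        for pid, split in cohort.splits.items()
    }
    pids = cohort.participant_ids
    n_epochs = plan.epochs if epochs is None else epochs

    train_losses: list[float] = []
    val_losses: list[float] = []
    best_val = float("inf")
    stale = 0
    for epoch in range(n_epochs):
        order = [pids[i] for i in rng.permutation(len(pids))]
        epoch_losses = []
        for pid in order:
            X, y = pairs[pid]["train"]
            if len(X) == 0:
                continue
            s = cohort.static_vector(pid) if config.integration != "none" else None
            model.reset(s)
            for a, b in _chunk_bounds(len(X), plan.batch_size):
                preds = model.forward(X[a:b], s, train=True)
                loss, grad = _loss_and_grad(model, preds, y[a:b])
                if not np.isfinite(loss):
                    raise TrainingDivergedError(epoch, pid)
                opt.zero_grad()
                model.backward(grad)
                opt.step()
                epoch_losses.append(loss)
        train_losses.append(float(np.mean(epoch_losses)))
        val_losses.append(_segment_loss(model, cohort, pairs, "validation"))
        if plan.early_stopping:
            if val_losses[-1] < best_val - plan.min_delta:
                best_val = val_losses[-1]
                stale = 0
            else:
                stale += 1
                if stale >= plan.patience:
                    break
    return TrainRun(
        config=config,
        seed=seed,
        model=model,
        train_losses=train_losses,
        val_losses=val_losses,
    )


def _config_key(config: RecurrentConfig) -> tuple:
    return (
        config.cell,
        config.n_layers,
        config.n_units,
        config.dilated,
        config.integration,
        config.static_dim,
        config.horizon,
        config.quantile_head,
    )


#: The hyperparameter grid of the recurrent families: depth x width.
RECURRENT_GRID = tuple(itertools.product((3, 5), (16, 32)))


def grid_search(
    plan: TrainingPlan,
    cohort: Cohort,
    template: RecurrentConfig,
    *,
    grid: tuple[tuple[int, int], ...] = RECURRENT_GRID,
    epochs: int | None = None,
) -> FitResult:
    """Train every (n_layers, n_units) grid point for every seed and select
    the config minimizing the mean final validation loss; ties broken by
    fewer parameters, then lexicographic config order."""
    if not grid:
        raise ValueError("empty hyperparameter grid")
    runs: dict[tuple, list[TrainRun]] = {}
    rows = []
    for n_layers, n_units in grid:
        config = replace(template, n_layers=n_layers, n_units=n_units)
        config_runs = [
            train_population(plan, cohort, config, seed, epochs=epochs)
            for seed in plan.seeds
        ]
        runs[_config_key(config)] = config_runs
        val = float(np.mean([r.final_val_loss for r in config_runs]))
        rows.append(
            {
                "cell": config.cell,
                "n_layers": n_layers,
                "n_units": n_units,
                "dilated": config.dilated,
                "integration": config.integration,
                "val_loss": val,
                "n_parameters": count_parameters(config_runs[0].model),
            }
        )
    leaderboard = pd.DataFrame(rows).sort_values(
        ["val_loss", "n_parameters", "cell", "n_layers", "n_units"],
        kind="stable",
    ).reset_index(drop=True)
    best = leaderboard.iloc[0]
    best_config = replace(
        template, n_layers=int(best["n_layers"]), n_units=int(best["n_units"])
    )
    return FitResult(best_config=best_config, leaderboard=leaderboard, runs=runs)


__all__ = [
    "TrainingPlan",
    "TrainingDivergedError",
    "TrainRun",
    "FitResult",
    "Cohort",
    "make_supervised_pairs",
    "train_population",
    "grid_search",
    "RECURRENT_GRID",
]
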
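"""Recurrent glucose forecasters with static-feature conditioning.

Three families of stateful sequence models (vanilla RNN, GRU, LSTM), each
optionally dilated — layer ``l`` then reads its own state from ``2**(l-1)``
steps back — and four strategies for conditioning on a child's static
characteristics:

``none``
    the recurrent stack sees only the seven time-varying features;
``init``
    the initial hidden state is produced from the static vector by a
    one-hidden-layer ReLU network (``h_{-1} = MLP_init(s)``); LSTMs use a
    distinct, equally sized network for the initial cell state;
``cat``
    the static vector is compressed by ``MLP_cat`` (one hidden layer of
    width ``2 * n_statics``, output width 2) and concatenated with the
    recurrent output before a two-hidden-layer head (widths ``2 * units``
    and ``units``);
``both``
    ``init`` and ``cat`` combined.

Models run sequence-to-sequence: the output at input step ``t`` estimates
glucose at step ``t + horizon``. With a quantile head the model emits one
output per quantile level and is trained with the pinball loss; raw
quantile outputs are monotonised by sorting at inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._nn import MLP, Dense, Param, RecurrentLayer

#: Quantile levels used by the quantile head.
DEFAULT_QUANTILES = (0.02, 0.1, 0.25, 0.5, 0.75, 0.9, 0.98)

CELLS = ("rnn", "gru", "lstm")
INTEGRATIONS = ("none", "init", "cat", "both")


@dataclass(frozen=True)
class RecurrentConfig:
    """Architecture of one recurrent forecaster."""

    cell: str = "rnn"
    n_layers: int = 3
    n_units: int = 16
    dilated: bool = False
    integration: str = "none"
    static_dim: int = 0
    horizon: int = 6  # grid steps of 5 min: 6/12/24 = 30/60/120 min
    quantile_head: bool = False
    quantiles: tuple[float, ...] = DEFAULT_QUANTILES

    def __post_init__(self) -> None:
        if self.cell not in CELLS:
            raise ValueError(f"cell must be one of {CELLS}, got {self.cell!r}")
        if self.integration not in INTEGRATIONS:
            raise ValueError(
                f"integration must be one of {INTEGRATIONS}, got {self.integration!r}"
            )
        if self.n_layers < 1 or self.n_units < 1:
            raise ValueError("n_layers and n_units must be positive")
        if self.integration != "none" and self.static_dim <= 0:
            raise ValueError("static integration requires static_dim > 0")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if self.quantile_head:
            q = self.quantiles
            if not all(0.0 < a < 1.0 for a in q) or list(q) != sorted(set(q)):
                raise ValueError("quantiles must be strictly increasing in (0, 1)")
            if 0.5 not in q:
                raise ValueError("quantiles must contain the median (0.5)")

    @property
    def n_outputs(self) -> int:
        return len(self.quantiles) if self.quantile_head else 1

    def dilation_schedule(self) -> list[int]:
        """Dilation per layer: 1, 2, 4, ... when dilated, else all ones."""
        if self.dilated:
            return [2**l for l in range(self.n_layers)]
        return [1] * self.n_layers


class ForecastModel:
    """A configured stateful recurrent forecaster."""

    def __init__(self, config: RecurrentConfig, n_features: int = 7, seed: int = 0):
        self.config = config
        self.n_features = n_features
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 101]))
        u = config.n_units
        dil = config.dilation_schedule()
        self.layers = [
            RecurrentLayer(
                config.cell,
                n_features if l == 0 else u,
                u,
                dil[l],
                rng,
            )
            for l in range(config.n_layers)
        ]
        self.mlp_init_h: MLP | None = None
        self.mlp_init_c: MLP | None = None
        self.mlp_cat: MLP | None = None
        if config.integration in ("init", "both"):
            self.mlp_init_h = MLP([config.static_dim, u, u], rng)
            if config.cell == "lstm":
                self.mlp_init_c = MLP([config.static_dim, u, u], rng)
        if config.integration in ("cat", "both"):
            self.mlp_cat = MLP([config.static_dim, 2 * config.static_dim, 2], rng)
            self.head: MLP | Dense = MLP([u + 2, 2 * u, u, config.n_outputs], rng)
        else:
            self.head = Dense(u, config.n_outputs, rng)
        self._init_pending = False  # init-MLP grads flow on first chunk only
        self._static: np.ndarray | None = None

    # -- state --------------------------------------------------------------

    def reset(self, s: np.ndarray | None = None) -> None:
        """Reset hidden (and cell) state.

        With integration in {init, both} the state is set from the static
        vector through the initialiser network(s); otherwise to zeros.
        """
        cfg = self.config
        if cfg.integration in ("init", "both"):
            if s is None:
                raise ValueError("static vector required for init/both integration")
            s = np.asarray(s, dtype=float)
            if s.shape != (cfg.static_dim,):
                raise ValueError(
                    f"static vector of length {s.shape} does not match "
                    f"static_dim={cfg.static_dim}"
                )
            h0 = self.mlp_init_h.forward(s[None, :], train=True)[0]
            c0 = (
                self.mlp_init_c.forward(s[None, :], train=True)[0]
                if self.mlp_init_c is not None
                else None
            )
            for layer in self.layers:
                layer.reset(h0, c0)
            self._init_pending = True
        else:
            for layer in self.layers:
                layer.reset()
            self._init_pending = False
        if cfg.integration != "none":
            if s is None:
                raise ValueError("static vector required for static integration")
            self._static = np.asarray(s, dtype=float)

    # -- forward / backward --------------------------------------------------

    def forward(
        self, window: np.ndarray, s: np.ndarray | None = None, train: bool = False
    ) -> np.ndarray:
        """One stateful pass: (T, 7) standardized features -> (T, n_outputs).

        The output at step ``t`` estimates (standardized) glucose at
        ``t + horizon``. Hidden state persists across consecutive calls
        until :meth:`reset`.
        """
        window = np.asarray(window, dtype=float)
        if window.ndim != 2 or window.shape[1] != self.n_features:
            raise ValueError(
                f"expected (T, {self.n_features}) input, got {window.shape}"
            )
        cfg = self.config
        if cfg.integration != "none":
            if s is None:
                s = self._static
            if s is None:
                raise ValueError("static vector required for static integration")
            s = np.asarray(s, dtype=float)
        h = window
        for layer in self.layers:
            h = layer.forward(h, train=train)
        if cfg.integration in ("cat", "both"):
            e = self.mlp_cat.forward(s[None, :], train=train)  # (1, 2)
            head_in = np.concatenate(
                [h, np.broadcast_to(e, (h.shape[0], 2))], axis=1
            )
            self._head_T = h.shape[0]
            return self.head.forward(head_in, train=train)
        return self.head.forward(h, train=train)

    def backward(self, d_out: np.ndarray) -> None:
        """Accumulate parameter gradients for the last ``train=True`` pass."""
        cfg = self.config
        if cfg.integration in ("cat", "both"):
            d_head_in = self.head.backward(d_out)
            dh = d_head_in[:, : cfg.n_units]
            de = d_head_in[:, cfg.n_units :].sum(axis=0, keepdims=True)
            self.mlp_cat.backward(de)
        else:
            dh = self.head.backward(d_out)
        dh0_total = np.zeros(cfg.n_units)
        dc0_total = np.zeros(cfg.n_units)
        for layer in reversed(self.layers):
            dh, dh_buf = layer.backward(dh)
            if self._init_pending:
                dh0_total += dh_buf.sum(axis=0)
                if cfg.cell == "lstm":
                    dc0_total += layer._last_dc_buf.sum(axis=0)
        if self._init_pending and cfg.integration in ("init", "both"):
            self.mlp_init_h.backward(dh0_total[None, :])
            if self.mlp_init_c is not None:
                self.mlp_init_c.backward(dc0_total[None, :])
        self._init_pending = False

    def predict(
        self, window: np.ndarray, s: np.ndarray | None = None
    ) -> np.ndarray:
        """Inference pass; quantile outputs are monotonised by sorting."""
        out = self.forward(window, s, train=False)
        if self.config.quantile_head:
            out = np.sort(out, axis=1)
        return out

    def point_predictions(self, out: np.ndarray) -> np.ndarray:
        """Point forecast per step: the median quantile, or the single
        output channel."""
        if self.config.quantile_head:
            return out[:, self.config.quantiles.index(0.5)]
        return out[:, 0]

    # -- parameters ----------------------------------------------------------

    def parameters(self) -> list[Param]:
        params: list[Param] = []
        for layer in self.layers:
            params.extend(layer.parameters())
        for mlp in (self.mlp_init_h, self.mlp_init_c, self.mlp_cat):
            if mlp is not None:
                params.extend(mlp.parameters())
        params.extend(
            self.head.parameters()
            if isinstance(self.head, (MLP, Dense))
            else []
        )
        return params


def build_model(
    config: RecurrentConfig, n_features: int = 7, seed: int = 0
) -> ForecastModel:
    """Construct a :class:`ForecastModel`; all weight shapes follow from the
    config alone."""
    return ForecastModel(config, n_features=n_features, seed=seed)


def init_hidden_from_statics(model: ForecastModel, s: np.ndarray) -> np.ndarray:
    """Initialise the model's state from a static vector; returns the shared
    initial hidden state (one row per layer slot is identical by design)."""
    if model.config.integration not in ("init", "both"):
        raise ValueError("init_hidden_from_statics requires integration init/both")
    model.reset(s)
    return model.layers[0].h_buf.copy()


def cat_head(
    model: ForecastModel, o_t: np.ndarray, s: np.ndarray
) -> np.ndarray:
    """Apply the concatenation head to recurrent output(s) ``o_t``."""
    if model.config.integration not in ("cat", "both"):
        raise ValueError("cat_head requires integration cat/both")
    o_t = np.atleast_2d(np.asarray(o_t, dtype=float))
    e = model.mlp_cat.forward(np.asarray(s, dtype=float)[None, :])
    head_in = np.concatenate([o_t, np.broadcast_to(e, (o_t.shape[0], 2))], axis=1)
    return model.head.forward(head_in)


def quantile_loss(
    y: np.ndarray, y_q: np.ndarray, quantiles: tuple[float, ...] = DEFAULT_QUANTILES
) -> float:
    """Pinball loss: mean over samples of the per-quantile losses summed
    over levels, ``QL(y, yhat, q) = q (y - yhat)_+ + (1 - q) (yhat - y)_+``.
    """
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    y_q = np.asarray(y_q, dtype=float)
    if y_q.ndim == 1:
        y_q = y_q.reshape(1, -1) if len(y) == 1 else y_q.reshape(-1, 1)
    if y_q.shape[1] != len(quantiles):
        raise ValueError("one prediction column per quantile level required")
    q = np.asarray(quantiles, dtype=float)[None, :]
    diff = y - y_q
    ql = q * np.maximum(diff, 0.0) + (1.0 - q) * np.maximum(-diff, 0.0)
    return float(ql.sum(axis=1).mean())


def quantile_loss_grad(
    y: np.ndarray, y_q: np.ndarray, quantiles: tuple[float, ...]
) -> np.ndarray:
    """Subgradient of :func:`quantile_loss` with respect to the predictions."""
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    q = np.asarray(quantiles, dtype=float)[None, :]
    grad = np.where(y > y_q, -q, np.where(y < y_q, 1.0 - q, 0.0))
    return grad / y.shape[0]


def count_parameters(model: ForecastModel) -> int:
    """Exact number of trainable scalars."""
    return sum(p.size for p in model.parameters())


def format_parameter_count(n: int) -> str:
    """Round to the nearest 0.1k below 10k, else to the nearest 1k."""
    if n < 10_000:
        return f"{round(n / 100) / 10:g}k"
    return f"{round(n / 1000):d}k"


__all__ = [
    "DEFAULT_QUANTILES",
    "RecurrentConfig",
    "ForecastModel",
    "build_model",
    "init_hidden_from_statics",
    "cat_head",
    "quantile_loss",
    "quantile_loss_grad",
    "count_parameters",
    "format_parameter_count",
]
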
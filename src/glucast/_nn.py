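"""Minimal neural-network primitives in numpy.

Dense layers, single-hidden-layer MLPs and stateful (optionally dilated)
recurrent layers with hand-derived gradients, plus an Adam optimizer with L2
weight decay. Recurrent layers follow the dual-bias convention (separate
input-side and recurrent-side bias vectors per gate); for the GRU the
recurrent-side candidate bias sits inside the reset gate, so the two biases
are genuinely distinct parameters there.

Gradients are accumulated into ``Param.grad`` (call ``zero_grad`` between
steps). Backward passes implement truncated BPTT: gradients do not flow
past the state buffer a chunk started from, but the buffer gradients are
returned so that a statics-driven state initialiser can be trained on the
first chunk after a reset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass
class Param:
    value: np.ndarray
    grad: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


def _uniform(rng: np.random.Generator, shape: tuple[int, ...], bound: float) -> np.ndarray:
    return rng.uniform(-bound, bound, size=shape)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


class Dense:
    """Affine map with fan-in uniform initialisation."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        bound = 1.0 / math.sqrt(max(in_dim, 1))
        self.W = Param(_uniform(rng, (in_dim, out_dim), bound))
        self.b = Param(_uniform(rng, (out_dim,), bound))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._x is not None, "backward before forward(train=True)"
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T

    def parameters(self) -> list[Param]:
        return [self.W, self.b]


class MLP:
    """Feed-forward stack with ReLU after every hidden layer."""

    def __init__(self, widths: list[int], rng: np.random.Generator):
        self.layers = [Dense(a, b, rng) for a, b in zip(widths[:-1], widths[1:])]
        self._relu_masks: list[np.ndarray] = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._relu_masks = []
        h = x
        for i, layer in enumerate(self.layers):
            h = layer.forward(h, train=train)
            if i < len(self.layers) - 1:
                mask = h > 0
                h = h * mask
                if train:
                    self._relu_masks.append(mask)
        return h

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for i in range(len(self.layers) - 1, -1, -1):
            if i < len(self.layers) - 1:
                dy = dy * self._relu_masks[i]
            dy = self.layers[i].backward(dy)
        return dy

    def parameters(self) -> list[Param]:
        return [p for l in self.layers for p in l.parameters()]


_GATES = {"rnn": 1, "gru": 3, "lstm": 4}


class RecurrentLayer:
    """One stateful recurrent layer with lagged (dilated) recurrence.

    The recurrence of a layer with dilation ``d`` reads the layer's own
    state from ``d`` steps back: ``h_t = cell(x_t, h_{t-d})``. State buffers
    persist across forward calls until :meth:`reset`.
    """

    def __init__(
        self,
        cell: str,
        in_dim: int,
        units: int,
        dilation: int,
        rng: np.random.Generator,
    ):
        if cell not in _GATES:
            raise ValueError(f"unknown cell type {cell!r}")
        g = _GATES[cell]
        bound = 1.0 / math.sqrt(units)
        self.cell = cell
        self.in_dim = in_dim
        self.units = units
        self.dilation = int(dilation)
        self.W = Param(_uniform(rng, (in_dim, g * units), bound))
        self.U = Param(_uniform(rng, (units, g * units), bound))
        self.b_ih = Param(_uniform(rng, (g * units,), bound))
        self.b_hh = Param(_uniform(rng, (g * units,), bound))
        self.h_buf = np.zeros((self.dilation, units))
        self.c_buf = np.zeros((self.dilation, units)) if cell == "lstm" else None
        self._cache: dict | None = None

    def parameters(self) -> list[Param]:
        return [self.W, self.U, self.b_ih, self.b_hh]

    def reset(self, h0: np.ndarray | None = None, c0: np.ndarray | None = None) -> None:
        """Reset the state buffers; every dilation slot receives ``h0``
        (zeros when omitted)."""
        self.h_buf = np.tile(
            np.zeros(self.units) if h0 is None else np.asarray(h0, dtype=float),
            (self.dilation, 1),
        )
        if self.cell == "lstm":
            self.c_buf = np.tile(
                np.zeros(self.units) if c0 is None else np.asarray(c0, dtype=float),
                (self.dilation, 1),
            )

    # -- forward ------------------------------------------------------------

    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        T = X.shape[0]
        u, d = self.units, self.dilation
        XW = X @ self.W.value + self.b_ih.value
        H = np.empty((T, u))
        Hprev = np.empty((T, u))
        cache: dict = {"X": X, "Hprev": Hprev}

        if self.cell == "rnn":
            for t in range(T):
                hp = self.h_buf[t] if t < d else H[t - d]
                Hprev[t] = hp
                H[t] = np.tanh(XW[t] + hp @ self.U.value + self.b_hh.value)
            cache["H"] = H
        elif self.cell == "gru":
            R = np.empty((T, u)); Z = np.empty((T, u))
            N = np.empty((T, u)); HN = np.empty((T, u))
            for t in range(T):
                hp = self.h_buf[t] if t < d else H[t - d]
                Hprev[t] = hp
                hU = hp @ self.U.value + self.b_hh.value
                r = _sigmoid(XW[t, :u] + hU[:u])
                z = _sigmoid(XW[t, u : 2 * u] + hU[u : 2 * u])
                hn = hU[2 * u :]
                n = np.tanh(XW[t, 2 * u :] + r * hn)
                H[t] = (1.0 - z) * n + z * hp
                R[t], Z[t], N[t], HN[t] = r, z, n, hn
            cache.update(H=H, R=R, Z=Z, N=N, HN=HN)
        else:  # lstm
            Cprev = np.empty((T, u))
            I = np.empty((T, u)); F = np.empty((T, u))
            G = np.empty((T, u)); O = np.empty((T, u)); C = np.empty((T, u))
            for t in range(T):
                hp = self.h_buf[t] if t < d else H[t - d]
                cp = self.c_buf[t] if t < d else C[t - d]
                Hprev[t], Cprev[t] = hp, cp
                pre = XW[t] + hp @ self.U.value + self.b_hh.value
                i = _sigmoid(pre[:u]); f = _sigmoid(pre[u : 2 * u])
                g = np.tanh(pre[2 * u : 3 * u]); o = _sigmoid(pre[3 * u :])
                c = f * cp + i * g
                H[t] = o * np.tanh(c)
                I[t], F[t], G[t], O[t], C[t] = i, f, g, o, c
            cache.update(H=H, I=I, F=F, G=G, O=O, C=C, Cprev=Cprev)

        # roll the state buffers forward
        if T >= d:
            self.h_buf = H[T - d :].copy()
            if self.cell == "lstm":
                self.c_buf = cache["C"][T - d :].copy()
        else:
            self.h_buf = np.vstack([self.h_buf[T:], H])
            if self.cell == "lstm":
                self.c_buf = np.vstack([self.c_buf[T:], cache["C"]])

        if train:
            self._cache = cache
        return H

    # -- backward -----------------------------------------------------------

    def backward(self, dH_out: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """BPTT within the cached chunk.

        Returns ``(dX, dh_buf)`` where ``dh_buf`` (shape (dilation, units),
        summed with the cell-state gradient for LSTMs) is the gradient with
        respect to the pre-chunk state buffer — used to train a statics
        initialiser on the first chunk after a reset.
        """
        assert self._cache is not None, "backward before forward(train=True)"
        cache = self._cache
        X, Hprev = cache["X"], cache["Hprev"]
        T = X.shape[0]
        u, d = self.units, self.dilation
        Uv = self.U.value
        carry = np.zeros((T, u))  # dh flowing to step t from step t + d
        dh_buf = np.zeros((d, u))

        if self.cell == "rnn":
            H = cache["H"]
            dPre = np.empty((T, u))
            for t in range(T - 1, -1, -1):
                dh = dH_out[t] + carry[t]
                dpre = dh * (1.0 - H[t] ** 2)
                dPre[t] = dpre
                dhp = dpre @ Uv.T
                if t - d >= 0:
                    carry[t - d] += dhp
                else:
                    dh_buf[t] += dhp
            dPreX = dPreH = dPre
        elif self.cell == "gru":
            H, R, Z, N, HN = (cache[k] for k in ("H", "R", "Z", "N", "HN"))
            dPreX = np.empty((T, 3 * u))
            dPreH = np.empty((T, 3 * u))
            for t in range(T - 1, -1, -1):
                dh = dH_out[t] + carry[t]
                hp = Hprev[t]
                dz = dh * (hp - N[t]) * Z[t] * (1.0 - Z[t])
                dn = dh * (1.0 - Z[t]) * (1.0 - N[t] ** 2)
                dr = dn * HN[t] * R[t] * (1.0 - R[t])
                dPreX[t, :u] = dr
                dPreX[t, u : 2 * u] = dz
                dPreX[t, 2 * u :] = dn
                dPreH[t, :u] = dr
                dPreH[t, u : 2 * u] = dz
                dPreH[t, 2 * u :] = dn * R[t]
                dhp = dh * Z[t] + dPreH[t] @ Uv.T
                if t - d >= 0:
                    carry[t - d] += dhp
                else:
                    dh_buf[t] += dhp
        else:  # lstm
            I, F, G, O, C, Cprev = (
                cache[k] for k in ("I", "F", "G", "O", "C", "Cprev")
            )
            dPre = np.empty((T, 4 * u))
            dc_carry = np.zeros((T, u))
            dc_buf = np.zeros((d, u))
            for t in range(T - 1, -1, -1):
                dh = dH_out[t] + carry[t]
                tc = np.tanh(C[t])
                do = dh * tc * O[t] * (1.0 - O[t])
                dc = dh * O[t] * (1.0 - tc**2) + dc_carry[t]
                di = dc * G[t] * I[t] * (1.0 - I[t])
                df = dc * Cprev[t] * F[t] * (1.0 - F[t])
                dg = dc * I[t] * (1.0 - G[t] ** 2)
                dPre[t, :u] = di
                dPre[t, u : 2 * u] = df
                dPre[t, 2 * u : 3 * u] = dg
                dPre[t, 3 * u :] = do
                dhp = dPre[t] @ Uv.T
                dcp = dc * F[t]
                if t - d >= 0:
                    carry[t - d] += dhp
                    dc_carry[t - d] += dcp
                else:
                    dh_buf[t] += dhp
                    dc_buf[t] += dcp
            dPreX = dPreH = dPre
            self._last_dc_buf = dc_buf

        self.W.grad += X.T @ dPreX
        self.b_ih.grad += dPreX.sum(axis=0)
        self.U.grad += Hprev.T @ dPreH
        self.b_hh.grad += dPreH.sum(axis=0)
        dX = dPreX @ self.W.value.T
        self._cache = None
        return dX, dh_buf


class Adam:
    """Adam with L2 weight decay added to the gradient."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        weight_decay: float = 0.0,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad + self.weight_decay * p.value
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


__all__ = ["Param", "Dense", "MLP", "RecurrentLayer", "Adam"]
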
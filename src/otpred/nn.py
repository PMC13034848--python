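"""Minimal NumPy compute engine for the prior-embedding sequence models.

Layers implement explicit ``forward``/``backward`` passes and
expose their parameters as :class:`Param` objects, so a whole network is a
plain composition whose gradients are exact and whose behaviour is
deterministic given a seed.  Downstream weights and activations use
``DTYPE`` (float32 by default; the work is memory-bound, so single
precision roughly halves step time) while the prior embedding parameter
stays float64 so its initialization and updates are exact.  Only what the off-target sub-models need is
provided: a scalar position-by-pair embedding lookup, same-padded 1-D
convolutions, a bidirectional LSTM, dense layers, ReLU, and binary
cross-entropy on a sigmoid output, optimized with Adam.

All sequence tensors are channels-last: ``(batch, L, channels)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

#: dtype of downstream weights and activations
DTYPE = np.float32

__all__ = [
    "Param",
    "EmbeddingLookup",
    "Conv1dSame",
    "ReLU",
    "Inception",
    "LSTM",
    "BiLSTM",
    "Flatten",
    "Dense",
    "Sequential",
    "Adam",
    "sigmoid",
    "bce_loss_and_grad",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function (scipy's C implementation)."""
    return expit(z)


@dataclass
class Param:
    """A named tensor with its gradient accumulator and trainability flag."""

    name: str
    value: np.ndarray
    trainable: bool = True
    dtype: np.dtype | None = None
    grad: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.value = np.asarray(self.value, dtype=self.dtype or DTYPE)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class EmbeddingLookup(Layer):
    """Scalar lookup into an L x 16 matrix, one value per sequence position.

    Input: integer column indices ``(B, L)`` (0-based).  Output:
    ``(B, L, 1)`` — each position contributes exactly its matrix cell, which
    is what makes the learned update per (position, pair-type) directly
    interpretable.
    """

    def __init__(self, matrix: np.ndarray, trainable: bool = True) -> None:
        self.W = Param("embedding", matrix.copy(), trainable=trainable, dtype=np.float64)
        self.L = matrix.shape[0]
        self._cols: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W]

    def forward(self, cols: np.ndarray) -> np.ndarray:
        if cols.ndim != 2 or cols.shape[1] != self.L:
            raise ValueError(f"expected (B, {self.L}) index array, got {cols.shape}")
        self._cols = cols
        rows = np.arange(self.L)
        return self.W.value[rows[None, :], cols][..., None].astype(DTYPE)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols = self._cols
        assert cols is not None
        if self.W.trainable:
            rows = np.broadcast_to(np.arange(self.L), cols.shape)
            np.add.at(self.W.grad, (rows.ravel(), cols.ravel()), dout[..., 0].ravel())
        return np.zeros(cols.shape + (1,), dtype=DTYPE)  # indices carry no gradient


class Conv1dSame(Layer):
    """1-D convolution with odd kernel size and zero same-padding."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator, name: str) -> None:
        if k % 2 != 1:
            raise ValueError("kernel size must be odd for symmetric same-padding")
        bound = 1.0 / np.sqrt(c_in * k)
        self.k, self.c_in, self.c_out = k, c_in, c_out
        self.W = Param(f"{name}.W", rng.uniform(-bound, bound, size=(k * c_in, c_out)))
        self.b = Param(f"{name}.b", np.zeros(c_out))
        self._win: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, L, C = x.shape
        p = self.k // 2
        xp = np.zeros((B, L + 2 * p, C), dtype=x.dtype)
        xp[:, p : p + L] = x
        win = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=1)
        # win: (B, L, C, k) -> (B, L, k*C) matching W's (k*c_in) layout
        win = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(B, L, self.k * C)
        self._win, self._xshape = win, x.shape
        return win @ self.W.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        win, (B, L, C) = self._win, self._xshape
        assert win is not None
        flat_win = win.reshape(B * L, -1)
        flat_d = dout.reshape(B * L, self.c_out)
        if self.W.trainable:
            self.W.grad += flat_win.T @ flat_d
            self.b.grad += flat_d.sum(axis=0)
        dwin = (flat_d @ self.W.value.T).reshape(B, L, self.k, C)
        p = self.k // 2
        dxp = np.zeros((B, L + 2 * p, C), dtype=dout.dtype)
        for j in range(self.k):
            dxp[:, j : j + L] += dwin[:, :, j]
        return dxp[:, p : p + L]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Inception(Layer):
    """Parallel same-padded conv branches plus an identity residual branch.

    Branch outputs (each ReLU-activated) and the untouched input are
    concatenated along channels: with kernel sizes (3, 5), 20 kernels each
    and a scalar input, the output has 20 + 20 + 1 = 41 channels per
    position.
    """

    def __init__(
        self,
        c_in: int,
        kernel_sizes: tuple[int, ...],
        kernels_per_branch: int,
        rng: np.random.Generator,
        residual: bool = True,
    ) -> None:
        self.branches = [
            Conv1dSame(c_in, kernels_per_branch, k, rng, name=f"inception.k{k}")
            for k in kernel_sizes
        ]
        self.acts = [ReLU() for _ in self.branches]
        self.residual = residual
        self.c_in = c_in
        self.c_out = kernels_per_branch * len(kernel_sizes) + (c_in if residual else 0)

    def params(self) -> list[Param]:
        return [p for br in self.branches for p in br.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        outs = [act.forward(br.forward(x)) for br, act in zip(self.branches, self.acts)]
        if self.residual:
            outs.append(x)
        self._splits = np.cumsum([o.shape[-1] for o in outs])[:-1]
        return np.concatenate(outs, axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        parts = np.split(dout, self._splits, axis=-1)
        dx = np.zeros(dout.shape[:2] + (self.c_in,), dtype=dout.dtype)
        for br, act, d in zip(self.branches, self.acts, parts):
            dx += br.backward(act.backward(d))
        if self.residual:
            dx += parts[-1]
        return dx


class LSTM(Layer):
    """Single-direction LSTM returning the full hidden sequence.

    Gate order i, f, o, g (the three sigmoid gates first, so one logistic
    call per step covers them); forget-gate bias initialized to 1 (standard
    remedy for early gradient vanishing); weights uniform(-1/sqrt(H), ...).
    The input projection is batched over all timesteps; only the recurrent
    term is sequential.
    """

    def __init__(self, c_in: int, hidden: int, rng: np.random.Generator, name: str) -> None:
        bound = 1.0 / np.sqrt(hidden)
        self.c_in, self.H = c_in, hidden
        self.Wx = Param(f"{name}.Wx", rng.uniform(-bound, bound, size=(c_in, 4 * hidden)))
        self.Wh = Param(f"{name}.Wh", rng.uniform(-bound, bound, size=(hidden, 4 * hidden)))
        b = np.zeros(4 * hidden)
        b[hidden : 2 * hidden] = 1.0
        self.b = Param(f"{name}.b", b)

    def params(self) -> list[Param]:
        return [self.Wx, self.Wh, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, L, _ = x.shape
        H = self.H
        dt = x.dtype
        h = np.zeros((B, H), dtype=dt)
        c = np.zeros((B, H), dtype=dt)
        self._x = x
        # time-major internal layout so per-step slices are contiguous
        zx = (x.reshape(B * L, -1) @ self.Wx.value + self.b.value).reshape(B, L, 4 * H)
        zx = np.ascontiguousarray(zx.transpose(1, 0, 2))  # (L, B, 4H)
        gates = np.empty((L, B, 4 * H), dtype=dt)  # i, f, o sigmoids then g tanh
        cells = np.empty((L, B, H), dtype=dt)
        hs = np.empty((L, B, H), dtype=dt)
        Wh = self.Wh.value
        for t in range(L):
            z = zx[t]
            z += h @ Wh
            sg = expit(z[:, : 3 * H], out=gates[t, :, : 3 * H])
            g = np.tanh(z[:, 3 * H :], out=gates[t, :, 3 * H :])
            i, f, o = sg[:, :H], sg[:, H : 2 * H], sg[:, 2 * H :]
            c = f * c + i * g
            cells[t] = c
            h = o * np.tanh(c)
            hs[t] = h
        self._gates, self._cells, self._hs = gates, cells, hs
        return np.ascontiguousarray(hs.transpose(1, 0, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        B, L, _ = x.shape
        H = self.H
        gates, cells, hs = self._gates, self._cells, self._hs
        dt = x.dtype
        dout_t = np.ascontiguousarray(dout.transpose(1, 0, 2))  # (L, B, H)
        dz_all = np.empty((L, B, 4 * H), dtype=dt)
        dh_next = np.zeros((B, H), dtype=dt)
        dc_next = np.zeros((B, H), dtype=dt)
        WhT = self.Wh.value.T
        zeros_c = np.zeros((B, H), dtype=dt)
        for t in range(L - 1, -1, -1):
            gt = gates[t]
            i = gt[:, :H]
            f = gt[:, H : 2 * H]
            o = gt[:, 2 * H : 3 * H]
            g = gt[:, 3 * H :]
            c_prev = cells[t - 1] if t > 0 else zeros_c
            tc = np.tanh(cells[t])
            dh = dout_t[t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            dc_next = dc * f
            dz = dz_all[t]
            dz[:, :H] = dc * g * i * (1.0 - i)
            dz[:, H : 2 * H] = dc * c_prev * f * (1.0 - f)
            dz[:, 2 * H : 3 * H] = do * o * (1.0 - o)
            dz[:, 3 * H :] = dc * i * (1.0 - g * g)
            dh_next = dz @ WhT
        # back to batch-major once for the big matmuls
        dz_flat = np.ascontiguousarray(dz_all.transpose(1, 0, 2)).reshape(B * L, 4 * H)
        if self.Wx.trainable:
            self.Wx.grad += x.reshape(B * L, -1).T @ dz_flat
            # h_prev sequence: zeros at t=0, then hs[:L-1]
            h_prev = np.concatenate([zeros_c[None], hs[:-1]], axis=0)
            self.Wh.grad += (
                np.ascontiguousarray(h_prev.transpose(1, 0, 2)).reshape(B * L, H).T
                @ dz_flat
            )
            self.b.grad += dz_flat.sum(axis=0)
        return (dz_flat @ self.Wx.value.T).reshape(x.shape)


class BiLSTM(Layer):
    """Stack of bidirectional LSTM layers; outputs 2*hidden channels."""

    def __init__(self, c_in: int, hidden: int, layers: int, rng: np.random.Generator) -> None:
        self.pairs: list[tuple[LSTM, LSTM]] = []
        for n in range(layers):
            cin = c_in if n == 0 else 2 * hidden
            fwd = LSTM(cin, hidden, rng, name=f"bilstm{n}.fwd")
            bwd = LSTM(cin, hidden, rng, name=f"bilstm{n}.bwd")
            self.pairs.append((fwd, bwd))
        self.c_out = 2 * hidden

    def params(self) -> list[Param]:
        return [p for fwd, bwd in self.pairs for p in (*fwd.params(), *bwd.params())]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for fwd, bwd in self.pairs:
            hf = fwd.forward(x)
            hb = bwd.forward(x[:, ::-1])[:, ::-1]
            x = np.concatenate([hf, hb], axis=-1)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for fwd, bwd in reversed(self.pairs):
            H = fwd.H
            df = dout[..., :H]
            db = dout[..., H:]
            dx = fwd.backward(df) + bwd.backward(np.ascontiguousarray(db[:, ::-1]))[:, ::-1]
            dout = dx
        return dout


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, name: str) -> None:
        bound = 1.0 / np.sqrt(c_in)
        self.W = Param(f"{name}.W", rng.uniform(-bound, bound, size=(c_in, c_out)))
        self.b = Param(f"{name}.b", np.zeros(c_out))

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.W.trainable:
            self.W.grad += self._x.T @ dout
            self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


def bce_loss_and_grad(
    logits: np.ndarray, labels: np.ndarray, pos_weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on sigmoid(logits) and d(loss)/d(logits).

    ``pos_weight`` multiplies the positive-class term (optional imbalance
    correction); gradients are already averaged over the batch.
    """
    z = logits.ravel().astype(np.float64)
    y = labels.ravel().astype(np.float64)
    w = np.where(y == 1.0, pos_weight, 1.0)
    # log(1+exp(-|z|)) + max(z,0) - z*y  is the stable BCE-with-logits form
    loss_terms = np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0.0) - z * y
    loss = float(np.mean(w * loss_terms))
    p = sigmoid(z)
    grad = (w * (p - y) / z.size).reshape(logits.shape).astype(logits.dtype)
    return loss, grad


class Adam:
    """Adam optimizer over a list of :class:`Param`; skips frozen ones."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = [p for p in params if p.trainable]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
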
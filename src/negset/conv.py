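"""A small 1-D convolutional network over one-hot DNA, in pure numpy.

Architecture (all sizes configurable): two conv blocks
(width-7 x 32 filters, width-5 x 64 filters, each ReLU + max-pool 2)
-> dense 64 (ReLU) -> sigmoid output, trained with Adam on binary
cross-entropy. Sized for 81-nt windows; forward and backward passes are
vectorized with ``sliding_window_view`` im2col, which keeps desk-scale
training (a few thousand sequences) in seconds-to-minutes on one CPU.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _im2col(x: np.ndarray, width: int) -> np.ndarray:
    # x: (B, L, C) -> (B, L-width+1, width*C)
    view = sliding_window_view(x, window_shape=width, axis=1)  # (B, P, C, width)
    return view.transpose(0, 1, 3, 2).reshape(x.shape[0], -1, width * x.shape[2])


def _col2im(grad_cols: np.ndarray, length: int, width: int, channels: int) -> np.ndarray:
    # inverse scatter-add of _im2col
    B, P, _ = grad_cols.shape
    g = grad_cols.reshape(B, P, width, channels)
    out = np.zeros((B, length, channels), dtype=grad_cols.dtype)
    for w in range(width):
        out[:, w:w + P, :] += g[:, :, w, :]
    return out


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


class ConvNet:
    """Parameter container + forward/backward for the fixed topology."""

    def __init__(
        self,
        length: int,
        kernel1: int = 7,
        filters1: int = 32,
        kernel2: int = 5,
        filters2: int = 64,
        pool: int = 2,
        hidden: int = 64,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.length = length
        self.kernel1, self.filters1 = kernel1, filters1
        self.kernel2, self.filters2 = kernel2, filters2
        self.pool, self.hidden = pool, hidden

        p1 = length - kernel1 + 1
        q1 = p1 // pool
        p2 = q1 - kernel2 + 1
        q2 = p2 // pool
        if q2 < 1:
            raise ValueError("input too short for this architecture")
        self.flat = q2 * filters2

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        self.W1 = he((kernel1 * 4, filters1), kernel1 * 4)
        self.b1 = np.zeros(filters1)
        self.W2 = he((kernel2 * filters1, filters2), kernel2 * filters1)
        self.b2 = np.zeros(filters2)
        self.W3 = he((self.flat, hidden), self.flat)
        self.b3 = np.zeros(hidden)
        self.W4 = he((hidden, 1), hidden)
        self.b4 = np.zeros(1)

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W1, self.b1, self.W2, self.b2, self.W3, self.b3, self.W4, self.b4]

    # -- forward -----------------------------------------------------------
    def forward(self, x: np.ndarray, cache: bool = False):
        """x: (B, L, 4) float. Returns probabilities (B,) [and a cache]."""
        pool = self.pool

        c1 = _im2col(x, self.kernel1)                # (B, P1, k1*4)
        z1 = c1 @ self.W1 + self.b1                  # (B, P1, f1)
        a1 = np.maximum(z1, 0.0)
        P1 = a1.shape[1]
        t1 = a1[:, : (P1 // pool) * pool].reshape(a1.shape[0], P1 // pool, pool, -1)
        m1 = t1.max(axis=2)                          # (B, Q1, f1)
        am1 = t1.argmax(axis=2)

        c2 = _im2col(m1, self.kernel2)
        z2 = c2 @ self.W2 + self.b2
        a2 = np.maximum(z2, 0.0)
        P2 = a2.shape[1]
        t2 = a2[:, : (P2 // pool) * pool].reshape(a2.shape[0], P2 // pool, pool, -1)
        m2 = t2.max(axis=2)
        am2 = t2.argmax(axis=2)

        flat = m2.reshape(m2.shape[0], -1)
        z3 = flat @ self.W3 + self.b3
        a3 = np.maximum(z3, 0.0)                     # penultimate embedding
        z4 = a3 @ self.W4 + self.b4
        prob = 1.0 / (1.0 + np.exp(-z4[:, 0]))

        if not cache:
            return prob
        return prob, {
            "x": x, "c1": c1, "z1": z1, "am1": am1, "m1": m1,
            "c2": c2, "z2": z2, "am2": am2, "m2": m2,
            "flat": flat, "z3": z3, "a3": a3,
        }

    def embed(self, x: np.ndarray) -> np.ndarray:
        """Penultimate-layer (dense ReLU) activations, shape (B, hidden)."""
        _, cache = self.forward(x, cache=True)
        return cache["a3"]

    # -- backward ----------------------------------------------------------
    def backward(self, prob: np.ndarray, y: np.ndarray, cache: dict) -> list[np.ndarray]:
        """Gradients of mean BCE loss w.r.t. params, same order as .params."""
        B = y.shape[0]
        pool = self.pool
        dz4 = ((prob - y) / B)[:, None]              # (B, 1)
        gW4 = cache["a3"].T @ dz4
        gb4 = dz4.sum(axis=0)
        da3 = dz4 @ self.W4.T
        dz3 = da3 * (cache["z3"] > 0)
        gW3 = cache["flat"].T @ dz3
        gb3 = dz3.sum(axis=0)
        dflat = dz3 @ self.W3.T
        dm2 = dflat.reshape(cache["m2"].shape)

        # unpool 2
        B_, Q2, f2 = dm2.shape
        dt2 = np.zeros((B_, Q2, pool, f2))
        idx = np.indices((B_, Q2, f2))
        dt2[idx[0], idx[1], cache["am2"], idx[2]] = dm2
        da2 = np.zeros_like(cache["z2"])
        da2[:, : Q2 * pool] = dt2.reshape(B_, Q2 * pool, f2)
        dz2 = da2 * (cache["z2"] > 0)
        gW2 = np.einsum("bpk,bpf->kf", cache["c2"], dz2)
        gb2 = dz2.sum(axis=(0, 1))
        dc2 = dz2 @ self.W2.T
        dm1 = _col2im(dc2, cache["m1"].shape[1], self.kernel2, self.filters1)

        # unpool 1
        B_, Q1, f1 = dm1.shape
        dt1 = np.zeros((B_, Q1, pool, f1))
        idx = np.indices((B_, Q1, f1))
        dt1[idx[0], idx[1], cache["am1"], idx[2]] = dm1
        da1 = np.zeros_like(cache["z1"])
        da1[:, : Q1 * pool] = dt1.reshape(B_, Q1 * pool, f1)
        dz1 = da1 * (cache["z1"] > 0)
        gW1 = np.einsum("bpk,bpf->kf", cache["c1"], dz1)
        gb1 = dz1.sum(axis=(0, 1))

        return [gW1, gb1, gW2, gb2, gW3, gb3, gW4, gb4]

    def loss(self, prob: np.ndarray, y: np.ndarray) -> float:
        eps = 1e-12
        return float(-np.mean(y * np.log(prob + eps) + (1 - y) * np.log(1 - prob + eps)))

    # -- training ----------------------------------------------------------
    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int = 20,
        batch_size: int = 64,
        learning_rate: float = 1e-3,
        rng: np.random.Generator | None = None,
    ) -> list[float]:
        rng = rng or np.random.default_rng(0)
        opt = _Adam(self.params, lr=learning_rate)
        history = []
        n = x.shape[0]
        for _ in range(epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                sl = order[start:start + batch_size]
                prob, cache = self.forward(x[sl], cache=True)
                losses.append(self.loss(prob, y[sl]))
                opt.step(self.backward(prob, y[sl], cache))
            history.append(float(np.mean(losses)))
        return history
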
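"""Minimal CPU neural-network engine: layers, losses and Adam.

Everything runs in float32 numpy. Convolutions are implemented as
sliding-window gathers followed by a single matrix product, which is the
fastest approach available for the small kernels (2-10) used here.
Each layer exposes ``forward(x, train)`` and ``backward(dY)``;
``backward`` must be called directly after the corresponding forward
(layers cache activations). Weight layers carry an optional L2 penalty
``l2 * sum(W**2)`` whose gradient is added during backward.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Dense", "Conv1D", "Conv2D", "AvgPool1D", "MaxPool1D", "AvgPool2D",
    "MaxPool2D", "Dropout", "Flatten", "Activation",
    "MSELoss", "RMSELoss", "CategoricalCrossEntropy", "Adam",
]


def glorot_uniform(rng: np.random.Generator, shape, fan_in, fan_out) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Layer:
    trainable = False

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def reg_loss(self) -> float:
        return 0.0


class Dense(Layer):
    trainable = True

    def __init__(self, n_in: int, n_out: int, l2: float = 0.0, *, rng: np.random.Generator):
        self.W = glorot_uniform(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.l2 = l2
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dY):
        self.dW[...] = self._x.T @ dY
        if self.l2:
            self.dW += 2.0 * self.l2 * self.W
        self.db[...] = dY.sum(axis=0)
        return dY @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def reg_loss(self):
        return float(self.l2 * np.sum(self.W.astype(np.float64) ** 2)) if self.l2 else 0.0


class Conv1D(Layer):
    """1D convolution over the site axis; filters span all channels.

    Input (B, W, C) -> output (B, W - k + 1, F), stride 1, no padding.
    """

    trainable = True

    def __init__(self, in_ch: int, filters: int, kernel: int, l2: float = 0.0, *,
                 rng: np.random.Generator, padding: str = "valid"):
        fan_in = kernel * in_ch
        self.W = glorot_uniform(rng, (fan_in, filters), fan_in, filters)
        self.b = np.zeros(filters, dtype=np.float32)
        self.kernel = kernel
        self.in_ch = in_ch
        self.l2 = l2
        self.padding = padding
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False):
        k = self.kernel
        self._W0 = x.shape[1]
        if self.padding == "same" and k > 1:
            left = (k - 1) // 2
            x = np.pad(x, ((0, 0), (left, k - 1 - left), (0, 0)))
        B, W, C = x.shape
        # (B, P, k, C) windows -> (B*P, k*C)
        win = sliding_window_view(x, k, axis=1)  # (B, P, C, k)
        win = win.transpose(0, 1, 3, 2).reshape(B * (W - k + 1), k * C)
        self._win = win
        self._shape = (B, W, C)
        y = win @ self.W + self.b
        return y.reshape(B, W - k + 1, -1)

    def backward(self, dY):
        B, W, C = self._shape
        k = self.kernel
        P = W - k + 1
        dy = dY.reshape(B * P, -1)
        self.dW[...] = self._win.T @ dy
        if self.l2:
            self.dW += 2.0 * self.l2 * self.W
        self.db[...] = dy.sum(axis=0)
        dwin = (dy @ self.W.T).reshape(B, P, k, C)
        dx = np.zeros((B, W, C), dtype=np.float32)
        for i in range(k):
            dx[:, i : i + P, :] += dwin[:, :, i, :]
        if self.padding == "same" and k > 1:
            left = (k - 1) // 2
            dx = dx[:, left : left + self._W0, :]
        return dx

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def reg_loss(self):
        return float(self.l2 * np.sum(self.W.astype(np.float64) ** 2)) if self.l2 else 0.0


class Conv2D(Layer):
    """Square-kernel 2D convolution. Input (B, H, W, C) -> (B, H-k+1, W-k+1, F)."""

    trainable = True

    def __init__(self, in_ch: int, filters: int, kernel: int, l2: float = 0.0, *,
                 rng: np.random.Generator, padding: str = "valid"):
        fan_in = kernel * kernel * in_ch
        self.W = glorot_uniform(rng, (fan_in, filters), fan_in, filters)
        self.b = np.zeros(filters, dtype=np.float32)
        self.kernel = kernel
        self.in_ch = in_ch
        self.l2 = l2
        self.padding = padding
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False):
        k = self.kernel
        self._hw0 = x.shape[1:3]
        if self.padding == "same" and k > 1:
            left = (k - 1) // 2
            pad = ((0, 0), (left, k - 1 - left), (left, k - 1 - left), (0, 0))
            x = np.pad(x, pad)
        B, H, W, C = x.shape
        win = sliding_window_view(x, (k, k), axis=(1, 2))  # (B, Ph, Pw, C, k, k)
        win = win.transpose(0, 1, 2, 4, 5, 3).reshape(B * (H - k + 1) * (W - k + 1), k * k * C)
        self._win = win
        self._shape = (B, H, W, C)
        y = win @ self.W + self.b
        return y.reshape(B, H - k + 1, W - k + 1, -1)

    def backward(self, dY):
        B, H, W, C = self._shape
        k = self.kernel
        Ph, Pw = H - k + 1, W - k + 1
        dy = dY.reshape(B * Ph * Pw, -1)
        self.dW[...] = self._win.T @ dy
        if self.l2:
            self.dW += 2.0 * self.l2 * self.W
        self.db[...] = dy.sum(axis=0)
        dwin = (dy @ self.W.T).reshape(B, Ph, Pw, k, k, C)
        dx = np.zeros((B, H, W, C), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dx[:, i : i + Ph, j : j + Pw, :] += dwin[:, :, :, i, j, :]
        if self.padding == "same" and k > 1:
            left = (k - 1) // 2
            H0, W0 = self._hw0
            dx = dx[:, left : left + H0, left : left + W0, :]
        return dx

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def reg_loss(self):
        return float(self.l2 * np.sum(self.W.astype(np.float64) ** 2)) if self.l2 else 0.0


class AvgPool1D(Layer):
    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x, train=False):
        B, W, C = x.shape
        P = W // self.size
        self._shape = x.shape
        return x[:, : P * self.size, :].reshape(B, P, self.size, C).mean(axis=2)

    def backward(self, dY):
        B, W, C = self._shape
        P = dY.shape[1]
        dx = np.zeros((B, W, C), dtype=np.float32)
        dx[:, : P * self.size, :] = np.repeat(dY / self.size, self.size, axis=1)
        return dx


class MaxPool1D(Layer):
    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x, train=False):
        B, W, C = x.shape
        P = W // self.size
        xr = x[:, : P * self.size, :].reshape(B, P, self.size, C)
        self._arg = xr.argmax(axis=2)
        self._shape = x.shape
        return xr.max(axis=2)

    def backward(self, dY):
        B, W, C = self._shape
        P = dY.shape[1]
        dxr = np.zeros((B, P, self.size, C), dtype=np.float32)
        np.put_along_axis(dxr, self._arg[:, :, None, :], dY[:, :, None, :], axis=2)
        dx = np.zeros((B, W, C), dtype=np.float32)
        dx[:, : P * self.size, :] = dxr.reshape(B, P * self.size, C)
        return dx


class AvgPool2D(Layer):
    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x, train=False):
        B, H, W, C = x.shape
        s = self.size
        Ph, Pw = H // s, W // s
        self._shape = x.shape
        xr = x[:, : Ph * s, : Pw * s, :].reshape(B, Ph, s, Pw, s, C)
        return xr.mean(axis=(2, 4))

    def backward(self, dY):
        B, H, W, C = self._shape
        s = self.size
        Ph, Pw = dY.shape[1], dY.shape[2]
        dx = np.zeros((B, H, W, C), dtype=np.float32)
        up = np.repeat(np.repeat(dY / (s * s), s, axis=1), s, axis=2)
        dx[:, : Ph * s, : Pw * s, :] = up
        return dx


class MaxPool2D(Layer):
    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x, train=False):
        B, H, W, C = x.shape
        s = self.size
        Ph, Pw = H // s, W // s
        self._shape = x.shape
        xr = x[:, : Ph * s, : Pw * s, :].reshape(B, Ph, s, Pw, s, C)
        flat = xr.transpose(0, 1, 3, 2, 4, 5).reshape(B, Ph, Pw, s * s, C)
        self._arg = flat.argmax(axis=3)
        return flat.max(axis=3)

    def backward(self, dY):
        B, H, W, C = self._shape
        s = self.size
        Ph, Pw = dY.shape[1], dY.shape[2]
        dflat = np.zeros((B, Ph, Pw, s * s, C), dtype=np.float32)
        np.put_along_axis(dflat, self._arg[:, :, :, None, :], dY[:, :, :, None, :], axis=3)
        dxr = dflat.reshape(B, Ph, Pw, s, s, C).transpose(0, 1, 3, 2, 4, 5)
        dx = np.zeros((B, H, W, C), dtype=np.float32)
        dx[:, : Ph * s, : Pw * s, :] = dxr.reshape(B, Ph * s, Pw * s, C)
        return dx


class Dropout(Layer):
    """Inverted dropout; active only when ``train`` is set."""

    def __init__(self, rate: float, *, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dY):
        return dY if self._mask is None else dY * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dY):
        return dY.reshape(self._shape)


class Activation(Layer):
    def __init__(self, kind: str):
        if kind not in ("relu", "linear", "sigmoid", "softmax"):
            raise ValueError(f"unknown activation {kind!r}")
        self.kind = kind

    def forward(self, x, train=False):
        if self.kind == "relu":
            self._y = np.maximum(x, 0.0)
        elif self.kind == "linear":
            self._y = x
        elif self.kind == "sigmoid":
            self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))
        else:  # softmax over last axis
            z = x - x.max(axis=-1, keepdims=True)
            e = np.exp(z)
            self._y = e / e.sum(axis=-1, keepdims=True)
        return self._y

    def backward(self, dY):
        if self.kind == "relu":
            return dY * (self._y > 0)
        if self.kind == "linear":
            return dY
        if self.kind == "sigmoid":
            return dY * self._y * (1.0 - self._y)
        p = self._y
        return p * (dY - (dY * p).sum(axis=-1, keepdims=True))


class MSELoss:
    def value(self, pred, truth):
        return float(np.mean((pred.astype(np.float64) - truth) ** 2))

    def grad(self, pred, truth):
        return (2.0 / pred.size) * (pred - truth).astype(np.float32)


class RMSELoss:
    """Root-mean-square error pooled over all output dimensions."""

    def value(self, pred, truth):
        return float(np.sqrt(np.mean((pred.astype(np.float64) - truth) ** 2)))

    def grad(self, pred, truth):
        rmse = max(self.value(pred, truth), 1e-12)
        return ((pred - truth) / (pred.size * rmse)).astype(np.float32)


class CategoricalCrossEntropy:
    """Cross-entropy on one-hot labels.

    Outputs are renormalized to sum to one before taking logs, so the loss
    is equally valid for softmax outputs (where the renormalization is a
    no-op) and for multi-neuron sigmoid outputs.
    """

    eps = 1e-7

    def value(self, pred, truth):
        p = np.clip(pred.astype(np.float64), self.eps, None)
        p = p / p.sum(axis=-1, keepdims=True)
        return float(-np.mean(np.sum(truth * np.log(p), axis=-1)))

    def grad(self, pred, truth):
        B = pred.shape[0]
        p = np.clip(pred.astype(np.float64), self.eps, None)
        s = p.sum(axis=-1, keepdims=True)
        g = (-truth / p + truth.sum(axis=-1, keepdims=True) / s) / B
        g = np.where(pred < self.eps, 0.0, g)  # clipped region is flat
        return g.astype(np.float32)


LOSSES = {"mse": MSELoss, "rmse": RMSELoss, "categorical_crossentropy": CategoricalCrossEntropy}


class Adam:
    """Adam with the customary defaults (lr 1e-3, betas 0.9/0.999)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
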
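"""Minimal 1-D convolutional network engine (numpy, CPU).

Provides exactly the layers the IMF classifier needs — Conv1d with
"same" zero padding and optional stride, BatchNorm1d, ReLU, max / fixed
average / adaptive average pooling, dropout, linear layers — together
with manual backpropagation, binary cross-entropy with logits, and an
Adam optimizer with L2 weight decay. Shapes follow the (batch, channel,
length) convention throughout.

Convolutions are evaluated as batched matrix products over an im2col
expansion, which keeps the arithmetic inside BLAS.
"""
from __future__ import annotations

import numpy as np

DTYPE = np.float32  # training precision (matches mainstream DL defaults)

__all__ = [
    "Conv1d",
    "BatchNorm1d",
    "ReLU",
    "MaxPool1d",
    "AvgPool1d",
    "AdaptiveAvgPool1d",
    "Flatten",
    "Linear",
    "Dropout",
    "Sequential",
    "Adam",
    "bce_with_logits",
    "sigmoid",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray):
    """Numerically stable mean BCE loss and its gradient w.r.t. logits."""
    z = np.asarray(logits, dtype=np.float64)
    y = np.asarray(targets, dtype=np.float64)
    loss = np.mean(np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z))))
    grad = (sigmoid(z) - y) / z.size
    return float(loss), grad


class _Layer:
    train_mode: bool = True

    def params(self):
        return []

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


class Conv1d(_Layer):
    """1-D convolution, "same" zero padding, optional stride."""

    def __init__(self, c_in, c_out, kernel, stride=1, rng=None):
        self.c_in, self.c_out, self.kernel, self.stride = c_in, c_out, kernel, stride
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / (c_in * kernel))
        self.W = (rng.standard_normal((c_out, c_in * kernel)) * std).astype(DTYPE)
        self.b = np.zeros(c_out, DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def _cols(self, xp, l_out):
        B, C, _ = xp.shape
        K, s = self.kernel, self.stride
        cols = np.empty((B, C, K, l_out), DTYPE)
        for k in range(K):
            cols[:, :, k, :] = xp[:, :, k : k + s * l_out : s]
        return cols

    def forward(self, x):
        x = np.ascontiguousarray(x, DTYPE)
        B, C, L = x.shape
        K, s = self.kernel, self.stride
        l_out = (L + s - 1) // s  # "same" output length for stride s
        pad_total = max((l_out - 1) * s + K - L, 0)
        self._pl = pad_total // 2
        pr = pad_total - self._pl
        xp = np.pad(x, ((0, 0), (0, 0), (self._pl, pr)))
        cols = self._cols(xp, l_out)  # (B, C, K, l_out)
        self._cols_mat = cols.reshape(B, C * K, l_out)
        self._in_shape = (B, C, L, xp.shape[2])
        y = np.matmul(self.W, self._cols_mat)
        return y + self.b[None, :, None]

    def backward(self, grad):
        B, C, L, Lp = self._in_shape
        K, s = self.kernel, self.stride
        l_out = grad.shape[2]
        grad = np.ascontiguousarray(grad, DTYPE)
        # one large GEMM for dW: (c_out, B*l_out) @ (B*l_out, C*K)
        g2 = grad.transpose(1, 0, 2).reshape(self.c_out, B * l_out)
        c2 = self._cols_mat.transpose(0, 2, 1).reshape(B * l_out, C * K)
        self.dW += g2 @ c2
        self.db += grad.sum(axis=(0, 2))
        dcols = np.matmul(self.W.T, grad)
        dcols = dcols.reshape(B, C, K, l_out)
        dxp = np.zeros((B, C, Lp), DTYPE)
        for k in range(K):
            dxp[:, :, k : k + s * l_out : s] += dcols[:, :, k, :]
        return dxp[:, :, self._pl : self._pl + L]


class BatchNorm1d(_Layer):
    def __init__(self, channels, momentum=0.1, eps=1e-5):
        self.gamma = np.ones(channels, DTYPE)
        self.beta = np.zeros(channels, DTYPE)
        self.dgamma = np.zeros(channels, DTYPE)
        self.dbeta = np.zeros(channels, DTYPE)
        self.running_mean = np.zeros(channels, DTYPE)
        self.running_var = np.ones(channels, DTYPE)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def forward(self, x):
        if self.train_mode:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None]) * self._istd[None, :, None]
        return self.gamma[None, :, None] * self._xhat + self.beta[None, :, None]

    def backward(self, grad):
        B, C, L = grad.shape
        m = B * L
        self.dgamma += (grad * self._xhat).sum(axis=(0, 2))
        self.dbeta += grad.sum(axis=(0, 2))
        if not self.train_mode:
            return grad * (self.gamma * self._istd)[None, :, None]
        g = grad * self.gamma[None, :, None]
        sum_g = g.sum(axis=(0, 2), keepdims=True)
        sum_gx = (g * self._xhat).sum(axis=(0, 2), keepdims=True)
        return (self._istd[None, :, None] / m) * (m * g - sum_g - self._xhat * sum_gx)


class ReLU(_Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool1d(_Layer):
    def __init__(self, k=2):
        self.k = k

    def forward(self, x):
        B, C, L = x.shape
        lo = L // self.k
        self._L = L
        xr = x[:, :, : lo * self.k].reshape(B, C, lo, self.k)
        self._arg = xr.argmax(axis=3)
        return np.take_along_axis(xr, self._arg[..., None], axis=3)[..., 0]

    def backward(self, grad):
        B, C, lo = grad.shape
        dxr = np.zeros((B, C, lo, self.k), DTYPE)
        np.put_along_axis(dxr, self._arg[..., None], grad[..., None], axis=3)
        dx = np.zeros((B, C, self._L), DTYPE)
        dx[:, :, : lo * self.k] = dxr.reshape(B, C, lo * self.k)
        return dx


class AvgPool1d(_Layer):
    def __init__(self, k=2):
        self.k = k

    def forward(self, x):
        B, C, L = x.shape
        lo = L // self.k
        self._L = L
        return x[:, :, : lo * self.k].reshape(B, C, lo, self.k).mean(axis=3)

    def backward(self, grad):
        B, C, lo = grad.shape
        dx = np.zeros((B, C, self._L), DTYPE)
        dx[:, :, : lo * self.k] = np.repeat(grad / self.k, self.k, axis=2)
        return dx


class AdaptiveAvgPool1d(_Layer):
    """Average pooling to a fixed output length with proportional bins."""

    def __init__(self, out_len):
        self.out_len = out_len

    def forward(self, x):
        B, C, L = x.shape
        self._L = L
        self._bins = [
            (int(np.floor(i * L / self.out_len)), int(np.ceil((i + 1) * L / self.out_len)))
            for i in range(self.out_len)
        ]
        y = np.empty((B, C, self.out_len), DTYPE)
        for i, (lo, hi) in enumerate(self._bins):
            y[:, :, i] = x[:, :, lo:hi].mean(axis=2)
        return y

    def backward(self, grad):
        B, C, _ = grad.shape
        dx = np.zeros((B, C, self._L), DTYPE)
        for i, (lo, hi) in enumerate(self._bins):
            dx[:, :, lo:hi] += grad[:, :, i : i + 1] / (hi - lo)
        return dx


class Flatten(_Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Linear(_Layer):
    def __init__(self, d_in, d_out, rng=None):
        rng = rng or np.random.default_rng()
        self.W = (rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in)).astype(DTYPE)
        self.b = np.zeros(d_out, DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x):
        self._x = np.ascontiguousarray(x, DTYPE)
        return self._x @ self.W + self.b

    def backward(self, grad):
        self.dW += self._x.T @ grad
        self.db += grad.sum(axis=0)
        return grad @ self.W.T


class Dropout(_Layer):
    def __init__(self, p, rng=None):
        self.p = p
        self.rng = rng or np.random.default_rng()

    def forward(self, x):
        if not self.train_mode or self.p <= 0:
            self._mask = None
            return x
        self._mask = ((self.rng.random(x.shape) >= self.p) / (1.0 - self.p)).astype(DTYPE)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def set_mode(self, train: bool):
        for layer in self.layers:
            layer.train_mode = train

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def zero_grad(self):
        for _, g in self.params():
            g[...] = 0.0

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def n_parameters(self) -> int:
        return int(sum(p.size for p, _ in self.params()))


class Adam:
    """Adam with (non-decoupled) L2 weight decay, torch-style defaults."""

    def __init__(self, params, lr=1e-4, weight_decay=0.0, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            grad = g + self.wd * p if self.wd else g
            m += (1.0 - self.b1) * (grad - m)
            v += (1.0 - self.b2) * (grad * grad - v)
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
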
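"""Minimal 1-D convolutional network engine in NumPy.

Implements exactly the layers the spectral CNN needs — same-padded 1-D
convolution, batch normalisation, ReLU, length-2 max pooling, global average
pooling, dense layers — with hand-derived backward passes and an Adam
optimizer.  Everything is deterministic given a ``numpy.random.Generator``:
there are no threads, no nondeterministic kernels, no hidden global state.

Convolutions are evaluated as a single GEMM per layer via an im2col view
(``sliding_window_view``), which is what keeps CPU training of 801-point
spectra tractable.

Shapes: activations are ``(N, C, L)`` until global pooling, ``(N, F)`` after.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "DTYPE", "Layer", "Conv1d", "BatchNorm1d", "ReLU", "MaxPool1d",
    "GlobalAvgPool1d", "Dense", "Sequential", "Adam",
    "softmax", "cross_entropy_grad", "mse_grad",
]

#: Working precision of the engine.  Single precision is the CNN-training
#: standard and roughly halves both memory traffic and GEMM time on CPU.
DTYPE = np.float32


class Layer:
    """Base layer: ``forward`` caches what ``backward`` needs."""

    def params(self) -> List[np.ndarray]:
        return []

    def grads(self) -> List[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params()))


class Conv1d(Layer):
    """Same-padded 1-D convolution, kernel size 3 by default (He init)."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 3,
                 rng: Optional[np.random.Generator] = None):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel
        self.W = (rng.standard_normal((c_out, c_in, kernel))
                  * np.sqrt(2.0 / fan_in)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.kernel = kernel
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train):
        N, C, L = x.shape
        k = self.kernel
        pad = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        # cols: (N, L, C*k); cols[n, l] = xp[n, :, l:l+k] flattened
        cols = sliding_window_view(xp, k, axis=2)          # (N, C, L, k)
        cols = cols.transpose(0, 2, 1, 3).reshape(N, L, C * k)
        Wm = self.W.reshape(self.W.shape[0], C * k)        # (c_out, C*k)
        out = cols @ Wm.T + self.b                         # (N, L, c_out)
        self._cache = (cols, (N, C, L))
        return out.transpose(0, 2, 1)                      # (N, c_out, L)

    def backward(self, dout):
        cols, (N, C, L) = self._cache
        k = self.kernel
        pad = k // 2
        d = dout.transpose(0, 2, 1)                        # (N, L, c_out)
        dflat = d.reshape(N * L, -1)
        self.dW[...] = (dflat.T @ cols.reshape(N * L, C * k)).reshape(self.W.shape)
        self.db[...] = dflat.sum(axis=0)
        Wm = self.W.reshape(self.W.shape[0], C * k)
        dcols = (d @ Wm).reshape(N, L, C, k)               # (N, L, C, k)
        dxp = np.zeros((N, C, L + 2 * pad), dtype=DTYPE)
        for j in range(k):
            dxp[:, :, j:j + L] += dcols[:, :, :, j].transpose(0, 2, 1)
        return dxp[:, :, pad:pad + L]


class BatchNorm1d(Layer):
    """Per-channel batch normalisation over the (sample, position) axes."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=DTYPE)
        self.beta = np.zeros(c, dtype=DTYPE)
        self.dgamma = np.zeros(c, dtype=DTYPE)
        self.dbeta = np.zeros(c, dtype=DTYPE)
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2))
            xc = x - mean[None, :, None]
            var = np.mean(xc * xc, axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
            xc = x - mean[None, :, None]
        inv = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        xhat = xc * inv[None, :, None]
        self._cache = (xhat, inv)
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, dout):
        xhat, inv = self._cache
        m = dout.shape[0] * dout.shape[2]
        self.dgamma[...] = (dout * xhat).sum(axis=(0, 2))
        self.dbeta[...] = dout.sum(axis=(0, 2))
        g = self.gamma[None, :, None] * inv[None, :, None]
        return g * (dout
                    - self.dbeta[None, :, None] / m
                    - xhat * self.dgamma[None, :, None] / m)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool1d(Layer):
    """Length-2 max downsampling (odd trailing point dropped)."""

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x, train):
        N, C, L = x.shape
        s = self.size
        Lo = L // s
        xr = x[:, :, :Lo * s].reshape(N, C, Lo, s)
        self._arg = xr.argmax(axis=3)
        self._shape = (N, C, L)
        return xr.max(axis=3)

    def backward(self, dout):
        N, C, L = self._shape
        s = self.size
        Lo = L // s
        dx = np.zeros((N, C, Lo, s), dtype=DTYPE)
        np.put_along_axis(dx, self._arg[..., None], dout[..., None], axis=3)
        out = np.zeros((N, C, L), dtype=DTYPE)
        out[:, :, :Lo * s] = dx.reshape(N, C, Lo * s)
        return out


class GlobalAvgPool1d(Layer):
    """(N, C, L) -> (N, C) mean over positions."""

    def forward(self, x, train):
        self._L = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dout):
        return np.repeat(dout[:, :, None], self._L, axis=2) / self._L


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int,
                 rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng(0)
        self.W = (rng.standard_normal((n_in, n_out))
                  * np.sqrt(2.0 / n_in)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W.T


class Sequential:
    """Ordered layer stack with full and partial forward/backward passes."""

    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def forward_collect(self, x: np.ndarray, train: bool = False):
        """Forward pass returning the activation after every layer."""
        acts = []
        for layer in self.layers:
            x = layer.forward(x, train)
            acts.append(x)
        return acts

    def backward_from(self, index: int, dout: np.ndarray) -> np.ndarray:
        """Backpropagate ``dout`` from the output of layer ``index`` only
        through the layers after it (gradient w.r.t. that activation)."""
        for layer in reversed(self.layers[index + 1:]):
            dout = layer.backward(dout)
        return dout

    def params(self) -> List[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> List[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params()))

    def shape_trace(self, input_length: int) -> List[Tuple[str, tuple]]:
        """Layer-by-layer output shapes for a single-sample input."""
        x = np.zeros((1, 1, input_length), dtype=DTYPE)
        trace = []
        for layer in self.layers:
            x = layer.forward(x, train=False)
            trace.append((type(layer).__name__, x.shape[1:]))
        return trace


class Adam:
    """Adam with an externally supplied per-step learning rate."""

    def __init__(self, params: List[np.ndarray], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, grads: List[np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1.0 - b1) * (g - m)
            v += (1.0 - b2) * (g * g - v)
            p -= lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


# ---------------------------------------------------------------------------
# Losses

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy over the batch and its gradient w.r.t. logits.

    ``y`` holds integer class indices.
    """
    n = logits.shape[0]
    p = softmax(logits)
    loss = float(-np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean())
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


def mse_grad(pred: np.ndarray, y: np.ndarray):
    """Mean squared error over the batch and its gradient w.r.t. pred."""
    diff = pred - y.reshape(pred.shape)
    loss = float(np.mean(diff**2))
    return loss, 2.0 * diff / diff.size
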
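"""Minimal convolutional-network building blocks with explicit backpropagation.

All tensors are NHWC ``float32`` by default (``float64`` is supported for
gradient checking).  Each layer caches what its backward pass needs during
``forward`` and releases it on ``backward``; a layer instance therefore belongs
to exactly one position in a network graph.

Convolutions are evaluated tap-by-tap: a same-padded k x k convolution is the
sum of k*k shifted (N*H*W, C_in) @ (C_in, C_out) matmuls.  This keeps every
BLAS call on nearly contiguous blocks and caches only the padded input (not a
k*k-fold im2col buffer), which measures faster than classic im2col here for
the small channel counts this architecture uses.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape: tuple, dtype=np.float32) -> np.ndarray:
    """Fan-based uniform initialization on [-limit, limit], limit = sqrt(6/(fan_in+fan_out))."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def uniform_pm1(rng: np.random.Generator, fan_in: int, fan_out: int,
                shape: tuple, dtype=np.float32) -> np.ndarray:
    """Fixed-limit uniform initialization on [-1, 1] (no fan scaling)."""
    return rng.uniform(-1.0, 1.0, size=shape).astype(dtype)


INITIALIZERS = {"glorot_uniform": glorot_uniform, "uniform_pm1": uniform_pm1}


class Conv2D:
    """Same-padded stride-1 square convolution with ReLU/sigmoid/linear activation."""

    def __init__(self, c_in: int, c_out: int, kernel_size: int,
                 activation: str = "relu", *, rng: np.random.Generator,
                 init: str = "glorot_uniform", dtype=np.float32):
        if activation not in ("relu", "sigmoid", "linear"):
            raise ConfigurationError(f"unknown activation {activation!r}")
        if init not in INITIALIZERS:
            raise ConfigurationError(f"unknown init_scheme {init!r}")
        k = kernel_size
        fan_in = k * k * c_in
        fan_out = k * k * c_out
        self.k = k
        self.c_in = c_in
        self.c_out = c_out
        self.activation = activation
        # Stored flattened (k*k*c_in, c_out); viewed as (k, k, c_in, c_out) per tap.
        self.W = INITIALIZERS[init](rng, fan_in, fan_out, (fan_in, c_out), dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dW = None
        self.db = None
        self._cache = None

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def _taps(self) -> np.ndarray:
        return self.W.reshape(self.k, self.k, self.c_in, self.c_out)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, h, w, _ = x.shape
        k = self.k
        pad = k // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0))) if pad else x
        Wk = self._taps()
        z = np.empty((n * h * w, self.c_out), dtype=x.dtype)
        z[:] = self.b
        for i in range(k):
            for j in range(k):
                z += xp[:, i:i + h, j:j + w, :].reshape(-1, self.c_in) @ Wk[i, j]
        if self.activation == "relu":
            a = np.maximum(z, 0.0)
        elif self.activation == "sigmoid":
            a = 1.0 / (1.0 + np.exp(-np.clip(z, -80.0, 80.0)))
        else:
            a = z
        self._cache = (xp, a, (n, h, w))
        return a.reshape(n, h, w, self.c_out)

    def backward(self, d_out: np.ndarray, *, from_logits: bool = False) -> np.ndarray:
        """Propagate gradient; ``from_logits`` means ``d_out`` is already dL/dz."""
        xp, a, (n, h, w) = self._cache
        self._cache = None
        k = self.k
        pad = k // 2
        dz = d_out.reshape(n * h * w, self.c_out)
        if not from_logits:
            if self.activation == "relu":
                dz = dz * (a > 0)
            elif self.activation == "sigmoid":
                dz = dz * (a * (1.0 - a))
        Wk = self._taps()
        self.dW = np.empty_like(self.W)
        dWk = self.dW.reshape(k, k, self.c_in, self.c_out)
        self.db = dz.sum(axis=0)
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                blk = xp[:, i:i + h, j:j + w, :].reshape(-1, self.c_in)
                dWk[i, j] = blk.T @ dz
                dxp[:, i:i + h, j:j + w, :] += (dz @ Wk[i, j].T).reshape(n, h, w, self.c_in)
        if pad:
            return dxp[:, pad:pad + h, pad:pad + w, :]
        return dxp


class MaxPool2:
    """2 x 2 max pooling with stride 2; gradient follows the argmax (first tie wins)."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        xr = (x.reshape(n, h // 2, 2, w // 2, 2, c)
                .transpose(0, 1, 3, 5, 2, 4)
                .reshape(n, h // 2, w // 2, c, 4))
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, (n, h, w, c))
        return out

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        idx, (n, h, w, c) = self._cache
        self._cache = None
        dxr = np.zeros((n, h // 2, w // 2, c, 4), dtype=d_out.dtype)
        np.put_along_axis(dxr, idx[..., None], d_out[..., None], axis=-1)
        return (dxr.reshape(n, h // 2, w // 2, c, 2, 2)
                   .transpose(0, 1, 4, 2, 5, 3)
                   .reshape(n, h, w, c))


class UpsampleNearest2:
    """Nearest-neighbour x2 upsampling; gradient sums each 2 x 2 block."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        n, h2, w2, c = d_out.shape
        return d_out.reshape(n, h2 // 2, 2, w2 // 2, 2, c).sum(axis=(2, 4))


class Dropout:
    """Inverted dropout; identity outside training or at rate 0."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ConfigurationError(f"dropout_rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return d_out
        m, self._mask = self._mask, None
        return d_out * m


class Adam:
    """Adam optimizer over a flat list of (param, grad-attr) pairs.

    Only the learning rate is tuned externally; beta1/beta2/epsilon use the
    conventional defaults (0.9, 0.999, 1e-8).
    """

    def __init__(self, layers, learning_rate: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if learning_rate < 0:
            raise ConfigurationError("learning_rate must be >= 0")
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.layers = [l for l in layers if isinstance(l, Conv2D)]
        self.m = [(np.zeros_like(l.W), np.zeros_like(l.b)) for l in self.layers]
        self.v = [(np.zeros_like(l.W), np.zeros_like(l.b)) for l in self.layers]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for layer, (mW, mb), (vW, vb) in zip(self.layers, self.m, self.v):
            for p, g, m, v in ((layer.W, layer.dW, mW, vW),
                               (layer.b, layer.db, mb, vb)):
                m *= self.beta1
                m += (1.0 - self.beta1) * g
                v *= self.beta2
                v += (1.0 - self.beta2) * (g * g)
                p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
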
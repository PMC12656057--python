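"""Layers with explicit forward/backward passes.

Data layout is channels-last: feature maps are (batch, length, channels).
Trainable arrays live in ``layer.params`` and their gradients, filled by
``backward``, in ``layer.grads`` under the same keys.  Batch-norm moving
statistics are kept in ``layer.stats`` (not optimized, but counted in
parameter audits, where a batch-norm layer contributes 4C values).
"""

from __future__ import annotations

import numpy as np


def glorot_uniform(rng: np.random.Generator, shape: tuple, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base: stateless unless parameters are declared."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.stats: dict[str, np.ndarray] = {}

    def param_count(self) -> int:
        """Trainable parameters plus persistent statistics (audit convention)."""
        return sum(p.size for p in self.params.values()) + sum(
            s.size for s in self.stats.values()
        )

    def zero_grads(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}


class Conv1D(Layer):
    """1-D convolution with 'same' zero padding, stride 1, odd kernel."""

    def __init__(self, c_in: int, c_out: int, kernel: int, *, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for 'same' padding")
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.params["W"] = glorot_uniform(
            rng, (kernel, c_in, c_out), kernel * c_in, kernel * c_out
        )
        if bias:
            self.params["b"] = np.zeros(c_out)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, T, _ = x.shape
        k, p = self.kernel, (self.kernel - 1) // 2
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        # cols[b, t, j*c_in:(j+1)*c_in] = xp[b, t+j, :]
        cols = np.concatenate([xp[:, j : j + T, :] for j in range(k)], axis=2)
        self._cols, self._T = cols, T
        W = self.params["W"].reshape(k * self.c_in, self.c_out)
        y = cols @ W
        if "b" in self.params:
            y = y + self.params["b"]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, T, _ = dy.shape
        k, p = self.kernel, (self.kernel - 1) // 2
        W = self.params["W"].reshape(k * self.c_in, self.c_out)
        flat_cols = self._cols.reshape(-1, k * self.c_in)
        flat_dy = dy.reshape(-1, self.c_out)
        self.grads["W"] = (flat_cols.T @ flat_dy).reshape(self.params["W"].shape)
        if "b" in self.params:
            self.grads["b"] = flat_dy.sum(axis=0)
        dcols = (flat_dy @ W.T).reshape(B, T, k * self.c_in)
        dxp = np.zeros((B, T + 2 * p, self.c_in))
        for j in range(k):
            dxp[:, j : j + T, :] += dcols[:, :, j * self.c_in : (j + 1) * self.c_in]
        return dxp[:, p : p + T, :]


class BatchNorm(Layer):
    """Batch normalization over all axes but the last (channel) axis.

    Uses batch statistics in training and exponential moving statistics
    at inference (eps 1e-3, momentum 0.99, matching common DL-framework
    defaults).  Works on (B, C) and (B, T, C) inputs.
    """

    def __init__(self, c: int, eps: float = 1e-3, momentum: float = 0.99):
        super().__init__()
        self.c, self.eps, self.momentum = c, eps, momentum
        self.params["gamma"] = np.ones(c)
        self.params["beta"] = np.zeros(c)
        self.stats["moving_mean"] = np.zeros(c)
        self.stats["moving_var"] = np.ones(c)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.stats["moving_mean"] = m * self.stats["moving_mean"] + (1 - m) * mean
            self.stats["moving_var"] = m * self.stats["moving_var"] + (1 - m) * var
        else:
            mean, var = self.stats["moving_mean"], self.stats["moving_var"]
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._xhat, self._inv, self._axes = xhat, inv, axes
        self._n = int(np.prod([x.shape[a] for a in axes]))
        self._training = training
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        axes, xhat, inv, n = self._axes, self._xhat, self._inv, self._n
        self.grads["gamma"] = (dy * xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        g = self.params["gamma"] * inv
        if self._training:
            mean_dy = dy.mean(axis=axes)
            mean_dy_xhat = (dy * xhat).mean(axis=axes)
            return g * (dy - mean_dy - xhat * mean_dy_xhat)
        return g * dy


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class ChannelAttention(Layer):
    """Squeeze-and-excitation style channel gating with dual pooling.

    Global average- and max-pooled channel descriptors pass through a
    shared bottleneck MLP (C -> C/r, ReLU, C/r -> C; bias only on the
    expansion layer).  With ``double_sigmoid`` each path is squashed
    before the paths are summed and squashed again — the literal form of
    the model this package reproduces; ``double_sigmoid=False`` gives
    the conventional single-squash variant.
    """

    def __init__(self, c: int, reduction_ratio: int = 8, *, double_sigmoid: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if reduction_ratio < 1 or c % reduction_ratio != 0:
            from ..errors import ConfigurationError

            raise ConfigurationError(
                f"channels ({c}) must be divisible by reduction ratio ({reduction_ratio})"
            )
        rng = rng or np.random.default_rng(0)
        self.c, self.r = c, reduction_ratio
        self.double_sigmoid = double_sigmoid
        h = c // reduction_ratio
        self.params["W1"] = glorot_uniform(rng, (c, h), c, h)  # no bias
        self.params["W2"] = glorot_uniform(rng, (h, c), h, c)
        self.params["b2"] = np.zeros(c)
        self.last_weights: np.ndarray | None = None  # attention tap, (B, C)

    def _mlp(self, p: np.ndarray):
        h = p @ self.params["W1"]
        hr = np.maximum(h, 0.0)
        s = hr @ self.params["W2"] + self.params["b2"]
        return h, hr, s

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, T, C = x.shape
        avg = x.mean(axis=1)
        arg = x.argmax(axis=1)  # (B, C)
        mx = np.take_along_axis(x, arg[:, None, :], axis=1)[:, 0, :]
        h_a, hr_a, s_a = self._mlp(avg)
        h_m, hr_m, s_m = self._mlp(mx)
        if self.double_sigmoid:
            pa, pm = _sigmoid(s_a), _sigmoid(s_m)
            a = _sigmoid(pa + pm)
            self._pa, self._pm = pa, pm
        else:
            a = _sigmoid(s_a + s_m)
        self._cache = (x, avg, mx, arg, h_a, hr_a, h_m, hr_m, a)
        self.last_weights = a
        return x * a[:, None, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, avg, mx, arg, h_a, hr_a, h_m, hr_m, a = self._cache
        B, T, C = x.shape
        W1, W2 = self.params["W1"], self.params["W2"]

        dx = dy * a[:, None, :]
        da = (dy * x).sum(axis=1)
        if self.double_sigmoid:
            du = da * a * (1 - a)
            ds_a = du * self._pa * (1 - self._pa)
            ds_m = du * self._pm * (1 - self._pm)
        else:
            ds = da * a * (1 - a)
            ds_a = ds_m = ds

        # shared MLP: accumulate over both paths
        self.grads["W2"] = hr_a.T @ ds_a + hr_m.T @ ds_m
        self.grads["b2"] = (ds_a + ds_m).sum(axis=0)
        dhr_a = ds_a @ W2.T
        dhr_m = ds_m @ W2.T
        dh_a = dhr_a * (h_a > 0)
        dh_m = dhr_m * (h_m > 0)
        self.grads["W1"] = avg.T @ dh_a + mx.T @ dh_m
        davg = dh_a @ W1.T
        dmx = dh_m @ W1.T

        dx += davg[:, None, :] / T
        # route max-pool gradient to the argmax sample of each channel
        dmax_full = np.zeros_like(x)
        np.put_along_axis(dmax_full, arg[:, None, :], dmx[:, None, :], axis=1)
        dx += dmax_full
        return dx


class MaxPool1D(Layer):
    """Non-overlapping max pooling (size=stride=2, valid)."""

    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, T, C = x.shape
        s = self.size
        t_out = T // s
        xr = x[:, : t_out * s, :].reshape(B, t_out, s, C)
        arg = xr.argmax(axis=2)
        y = np.take_along_axis(xr, arg[:, :, None, :], axis=2)[:, :, 0, :]
        self._arg, self._in_shape = arg, x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, T, C = self._in_shape
        s = self.size
        t_out = T // s
        dxr = np.zeros((B, t_out, s, C))
        np.put_along_axis(dxr, self._arg[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros((B, T, C))
        dx[:, : t_out * s, :] = dxr.reshape(B, t_out * s, C)
        return dx


class GlobalPoolConcat(Layer):
    """Concatenated global average and max pooling over the length axis."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, T, C = x.shape
        arg = x.argmax(axis=1)
        mx = np.take_along_axis(x, arg[:, None, :], axis=1)[:, 0, :]
        self._arg, self._in_shape = arg, x.shape
        return np.concatenate([x.mean(axis=1), mx], axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, T, C = self._in_shape
        davg, dmax = dy[:, :C], dy[:, C:]
        dx = np.repeat(davg[:, None, :], T, axis=1) / T
        dmax_full = np.zeros((B, T, C))
        np.put_along_axis(dmax_full, self._arg[:, None, :], dmax[:, None, :], axis=1)
        return dx + dmax_full


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.n_in, self.n_out = n_in, n_out
        self.params["W"] = glorot_uniform(rng, (n_in, n_out), n_in, n_out)
        self.params["b"] = np.zeros(n_out)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float = 0.5):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = np.random.default_rng(0)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask
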
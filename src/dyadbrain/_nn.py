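"""Minimal NumPy neural-network engine used by the embedder and classifiers.

Only the handful of layers the shallow-ConvNet architecture needs are
implemented, each with an explicit backward pass.  Gradients are exact
analytic expressions and are verified against central finite differences in
the test suite.  All stochastic elements (initialization, dropout masks) draw
from an explicit ``numpy.random.Generator`` so training is a pure function of
the seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Module",
    "TemporalConv",
    "SpatialConv",
    "BatchNorm",
    "Square",
    "AvgPool",
    "LogEps",
    "Dropout",
    "Flatten",
    "Linear",
    "ReLU",
    "Network",
    "Adam",
]


class Module:
    """Base layer: parameter dict, gradient dict, forward/backward pair."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class TemporalConv(Module):
    """Per-channel temporal convolution: (B, C, T) -> (B, F, C, T-k+1).

    The same bank of ``n_filters`` length-``k`` kernels is applied to every
    channel independently (valid convolution, implemented as correlation).
    """

    def __init__(self, n_filters: int, k: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.k = k
        self.params["W"] = _glorot(rng, (n_filters, k), k, n_filters)
        self.params["b"] = np.zeros(n_filters)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, c, t = x.shape
        tc = t - self.k + 1
        self._shape = (b, c, t)
        # contiguous im2col so both passes are plain BLAS matmuls
        self._cols = np.ascontiguousarray(
            sliding_window_view(x, self.k, axis=-1)
        ).reshape(b * c * tc, self.k)
        y = self._cols @ self.params["W"].T  # (B*C*Tc, F)
        y = np.moveaxis(y.reshape(b, c, tc, -1), 3, 1)
        return y + self.params["b"][None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, t = self._shape
        tc = t - self.k + 1
        w = self.params["W"]
        dyf = np.ascontiguousarray(np.moveaxis(dy, 1, 3)).reshape(-1, w.shape[0])
        self.grads["W"] = dyf.T @ self._cols
        self.grads["b"] = dyf.sum(axis=0)
        dcols = (dyf @ w).reshape(b, c, tc, self.k)
        dx = np.zeros((b, c, t))
        for k in range(self.k):  # scatter the k-th column back to its lag
            dx[:, :, k : k + tc] += dcols[:, :, :, k]
        return dx


class SpatialConv(Module):
    """Spatial aggregation across electrodes: (B, G, C, T) -> (B, F, T).

    Each output feature map is a learned linear combination over all channels
    and all temporal-filter outputs (kernel spanning the full electrode axis,
    no bias — the following batch norm owns the offset).
    """

    def __init__(self, n_out: int, n_in: int, n_channels: int, rng: np.random.Generator) -> None:
        super().__init__()
        fan_in = n_in * n_channels
        self.params["W"] = _glorot(rng, (n_out, n_in, n_channels), fan_in, n_out)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        b, g, c, t = x.shape
        w = self.params["W"]
        y = np.tensordot(x.reshape(b, g * c, t), w.reshape(w.shape[0], g * c), axes=([1], [1]))
        return np.moveaxis(y, 1, 2)  # (B, F, T)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        self.grads["W"] = np.tensordot(dy, x, axes=([0, 2], [0, 3]))
        dx = np.tensordot(dy, self.params["W"], axes=([1], [0]))  # (B, T, G, C)
        return np.ascontiguousarray(np.moveaxis(dx, 1, 3))


class BatchNorm(Module):
    """Per-feature-map batch normalization over (batch, time) for (B, F, T).

    Batch statistics during training; exponentially averaged running
    statistics at inference.
    """

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(n_features)
        self.params["beta"] = np.zeros(n_features)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None]) * self._inv[None, :, None]
        self._train = train
        return self.params["gamma"][None, :, None] * self._xhat + self.params["beta"][None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat = self._xhat
        self.grads["gamma"] = (dy * xhat).sum(axis=(0, 2))
        self.grads["beta"] = dy.sum(axis=(0, 2))
        dxhat = dy * self.params["gamma"][None, :, None]
        if not self._train:
            return dxhat * self._inv[None, :, None]
        m1 = dxhat.mean(axis=(0, 2), keepdims=True)
        m2 = (dxhat * xhat).mean(axis=(0, 2), keepdims=True)
        return self._inv[None, :, None] * (dxhat - m1 - xhat * m2)


class Square(Module):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x * x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return 2.0 * self._x * dy


class AvgPool(Module):
    """Temporal average pooling on (B, F, T) -> (B, F, P)."""

    def __init__(self, length: int, stride: int) -> None:
        super().__init__()
        self.length = length
        self.stride = stride

    @staticmethod
    def out_len(t: int, length: int, stride: int) -> int:
        if t < length:
            raise ValueError(f"pool length {length} exceeds input length {t}")
        return (t - length) // stride + 1

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._t = x.shape[-1]
        win = sliding_window_view(x, self.length, axis=-1)[..., :: self.stride, :]
        return win.mean(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.zeros(dy.shape[:-1] + (self._t,))
        for p in range(dy.shape[-1]):
            s = p * self.stride
            dx[..., s : s + self.length] += dy[..., p, None] / self.length
        return dx


class LogEps(Module):
    """Elementwise log with a floor: log(max(x, eps)); keeps outputs finite."""

    def __init__(self, eps: float = 1e-6) -> None:
        super().__init__()
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return np.log(np.maximum(x, self.eps))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * (self._x > self.eps) / np.maximum(self._x, self.eps)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class Flatten(Module):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["W"] = _glorot(rng, (n_in, n_out), n_in, n_out)
        self.params["b"] = np.zeros(n_out)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class ReLU(Module):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * (self._x > 0)


class Network:
    """A plain sequential stack of modules with flat-vector (de)serialization."""

    def __init__(self, modules: list[Module]) -> None:
        self.modules = modules

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for m in self.modules:
            x = m.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for m in reversed(self.modules):
            dy = m.backward(dy)
        return dy

    def parameters(self) -> list[tuple[Module, str]]:
        return [(m, name) for m in self.modules for name in m.params]

    def n_params(self) -> int:
        return sum(m.n_params() for m in self.modules)

    def get_flat(self) -> np.ndarray:
        chunks = [m.params[name].ravel() for m, name in self.parameters()]
        return np.concatenate(chunks) if chunks else np.empty(0)

    def set_flat(self, vec: np.ndarray) -> None:
        i = 0
        for m, name in self.parameters():
            p = m.params[name]
            m.params[name] = vec[i : i + p.size].reshape(p.shape).copy()
            i += p.size
        if i != vec.size:
            raise ValueError(f"flat vector has {vec.size} entries, expected {i}")

    def get_grad_flat(self) -> np.ndarray:
        chunks = [m.grads[name].ravel() for m, name in self.parameters()]
        return np.concatenate(chunks) if chunks else np.empty(0)


class Adam:
    """Adam optimizer over one or more networks' parameters."""

    def __init__(
        self,
        networks: list[Network],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.slots = [(m, name) for net in networks for (m, name) in net.parameters()]
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(m.params[name]) for m, name in self.slots]
        self.v = [np.zeros_like(m.params[name]) for m, name in self.slots]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (mod, name) in enumerate(self.slots):
            g = mod.grads.get(name)
            if g is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            mod.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for mod, name in self.slots:
            mod.grads.pop(name, None)
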
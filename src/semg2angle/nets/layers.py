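"""Minimal NumPy neural-net layers with explicit backward passes.

Feature maps are ``(N, C, T)`` — batch, channels, time. Every layer caches
what its backward pass needs during ``forward`` and accumulates parameter
gradients in ``Parameter.grad`` during ``backward``. The models here are
small (tens of thousands of parameters, windows of ten samples), so plain
vectorized NumPy is fast enough; no autograd framework is required.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "CausalConv1d",
    "BatchNorm1d",
    "ReLU",
    "Dropout",
    "Linear",
    "TakeLast",
    "Transpose",
    "sigmoid",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Parameter:
    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = np.asarray(data, dtype=float)
        self.grad = np.zeros_like(self.data)
        self.name = name

    def __repr__(self) -> str:  # pragma: no cover
        return f"Parameter({self.name}, shape={self.data.shape})"


class Module:
    """Base class: parameter bookkeeping + forward/backward contract."""

    name: str = ""

    def parameters(self) -> list[Parameter]:
        return []

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.forward(x, training=training)


class Sequential(Module):
    def __init__(self, *modules: Module, name: str = ""):
        self.modules = list(modules)
        self.name = name

    def parameters(self) -> list[Parameter]:
        return [p for m in self.modules for p in m.parameters()]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for m in self.modules:
            x = m.forward(x, training=training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for m in reversed(self.modules):
            dy = m.backward(dy)
        return dy


def _fan_in_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in) if fan_in > 0 else 0.0
    return rng.uniform(-bound, bound, size=shape)


class CausalConv1d(Module):
    """Dilated convolution with left-only zero padding of (K-1)*d samples.

    Output y[:, :, t] therefore depends only on inputs at times <= t, the
    current sample included; output length equals input length.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 dilation: int = 1, rng: np.random.Generator | None = None,
                 name: str = "conv"):
        if kernel < 1 or dilation < 1:
            raise ValueError("kernel and dilation must be >= 1")
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.dilation = dilation
        self.name = name
        fan_in = in_channels * kernel
        self.W = Parameter(
            _fan_in_uniform(rng, (out_channels, in_channels, kernel), fan_in),
            f"{name}.W",
        )
        self.b = Parameter(_fan_in_uniform(rng, (out_channels,), fan_in), f"{name}.b")
        self._cache = None

    @property
    def pad(self) -> int:
        return (self.kernel - 1) * self.dilation

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]

    def _gather(self, xpad: np.ndarray, N: int, T: int) -> np.ndarray:
        """Stack dilated taps into a (K*C_in, N*T) matrix for one BLAS gemm.

        Tap k is the input at time t - (K-1-k)*d, so the last tap block is
        the current sample; the flattened weight order below matches.
        """
        slices = [xpad[:, :, k * self.dilation: k * self.dilation + T]
                  for k in range(self.kernel)]
        return np.concatenate(slices, axis=1).transpose(1, 0, 2).reshape(-1, N * T)

    def _flat_weight(self) -> np.ndarray:
        # (out, C_in, K) -> (out, K, C_in) -> (out, K*C_in), matching _gather
        return self.W.data.transpose(0, 2, 1).reshape(self.out_channels, -1)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim != 3 or x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected (N, {self.in_channels}, T) input, got {x.shape}"
            )
        N, _, T = x.shape
        xpad = np.pad(x, ((0, 0), (0, 0), (self.pad, 0)))
        taps = self._gather(xpad, N, T)  # (K*C_in, N*T)
        y = (self._flat_weight() @ taps).reshape(self.out_channels, N, T)
        self._cache = (taps, x.shape)
        return y.transpose(1, 0, 2) + self.b.data[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        taps, xshape = self._cache
        N, _, T = xshape
        dy2 = np.ascontiguousarray(dy.transpose(1, 0, 2)).reshape(self.out_channels, -1)
        dWf = dy2 @ taps.T
        self.W.grad += dWf.reshape(
            self.out_channels, self.kernel, self.in_channels
        ).transpose(0, 2, 1)
        self.b.grad += dy2.sum(axis=1)
        dtaps = (self._flat_weight().T @ dy2).reshape(
            self.kernel, self.in_channels, N, T
        )
        dxpad = np.zeros((N, self.in_channels, T + self.pad))
        for k in range(self.kernel):
            dxpad[:, :, k * self.dilation: k * self.dilation + T] += dtaps[k].transpose(1, 0, 2)
        return dxpad[:, :, self.pad:]


class BatchNorm1d(Module):
    """Per-channel normalization over batch and time axes."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 name: str = "bn"):
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.name = name
        self.gamma = Parameter(np.ones(channels), f"{name}.gamma")
        self.beta = Parameter(np.zeros(channels), f"{name}.beta")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        ivstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None]) * ivstd[None, :, None]
        self._cache = (xhat, ivstd, training, x.shape)
        return self.gamma.data[None, :, None] * xhat + self.beta.data[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, ivstd, training, shape = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2))
        self.beta.grad += dy.sum(axis=(0, 2))
        dxhat = dy * self.gamma.data[None, :, None]
        if not training:
            return dxhat * ivstd[None, :, None]
        m = shape[0] * shape[2]
        s1 = dxhat.sum(axis=(0, 2), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        return (ivstd[None, :, None] / m) * (m * dxhat - s1 - xhat * s2)


class ReLU(Module):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class Dropout(Module):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng(0)
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None, name: str = "linear"):
        rng = rng or np.random.default_rng(0)
        self.name = name
        self.W = Parameter(
            _fan_in_uniform(rng, (out_features, in_features), in_features), f"{name}.W"
        )
        self.b = Parameter(_fan_in_uniform(rng, (out_features,), in_features), f"{name}.b")
        self._x = None

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W.data.T + self.b.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.data


class TakeLast(Module):
    """(N, C, T) -> (N, C): features at the window's final time step."""

    def __init__(self):
        self._shape = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x[:, :, -1]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._shape)
        dx[:, :, -1] = dy
        return dx


class Transpose(Module):
    """(N, T, C) <-> (N, C, T) adapter between window layout and conv layout."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return np.ascontiguousarray(x.transpose(0, 2, 1))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.ascontiguousarray(dy.transpose(0, 2, 1))
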
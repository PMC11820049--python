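"""Channel and temporal (spatial) attention for 1-D feature maps.

Channel attention pools each channel over time (average and max), feeds
both descriptors through one shared two-layer MLP, sums, and squashes with
a sigmoid to per-channel weights in (0, 1). Spatial attention pools over
channels, concatenates the two pooled rows, runs a width-3 single-output
convolution (symmetric zero padding) and a sigmoid to per-time-step
weights. The block applies channel attention first, then spatial, each as
an elementwise rescaling of the map, so attenuated maps never exceed the
input in magnitude.

A ``bypass`` flag turns the whole block into the identity, which is the
ablation that reduces the cascaded attention model to its plain
encoder-decoder counterpart.
"""

from __future__ import annotations

import numpy as np

from .layers import Module, Parameter, _fan_in_uniform, sigmoid

__all__ = ["ChannelAttention", "SpatialAttention", "CBAM"]


class ChannelAttention(Module):
    def __init__(self, channels: int, k: int | None = None,
                 rng: np.random.Generator | None = None, name: str = "ca"):
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.k = k if k is not None else max(channels // 8, 1)
        self.name = name
        self.W0 = Parameter(_fan_in_uniform(rng, (self.k, channels), channels), f"{name}.W0")
        self.b0 = Parameter(_fan_in_uniform(rng, (self.k,), channels), f"{name}.b0")
        self.W1 = Parameter(_fan_in_uniform(rng, (channels, self.k), self.k), f"{name}.W1")
        self.b1 = Parameter(_fan_in_uniform(rng, (channels,), self.k), f"{name}.b1")
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.W0, self.b0, self.W1, self.b1]

    def _mlp(self, v: np.ndarray):
        a = v @ self.W0.data.T + self.b0.data  # (N, k)
        h = np.maximum(a, 0.0)
        o = h @ self.W1.data.T + self.b1.data  # (N, C)
        return a, h, o

    def weights(self, x: np.ndarray) -> np.ndarray:
        """Attention weights only (no rescaling); used by tests/oracles."""
        avg = x.mean(axis=2)
        mx = x.max(axis=2)
        _, _, o_avg = self._mlp(avg)
        _, _, o_max = self._mlp(mx)
        return sigmoid(o_avg + o_max)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        N, C, T = x.shape
        avg = x.mean(axis=2)
        mx = x.max(axis=2)
        argmax = x.argmax(axis=2)
        a_avg, h_avg, o_avg = self._mlp(avg)
        a_max, h_max, o_max = self._mlp(mx)
        m = sigmoid(o_avg + o_max)  # (N, C)
        self._cache = (x, avg, mx, argmax, a_avg, h_avg, a_max, h_max, m, T)
        return x * m[:, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, avg, mx, argmax, a_avg, h_avg, a_max, h_max, m, T = self._cache
        dx = dy * m[:, :, None]
        dm = (dy * x).sum(axis=2)
        do = dm * m * (1.0 - m)  # through sigmoid; shared by both branches

        dpooled = []
        for a, h, v in ((a_avg, h_avg, avg), (a_max, h_max, mx)):
            self.W1.grad += do.T @ h
            self.b1.grad += do.sum(axis=0)
            dh = do @ self.W1.data
            da = dh * (a > 0)
            self.W0.grad += da.T @ v
            self.b0.grad += da.sum(axis=0)
            dpooled.append(da @ self.W0.data)  # (N, C)
        davg, dmax = dpooled
        dx += davg[:, :, None] / T
        np.put_along_axis(
            dx, argmax[:, :, None],
            np.take_along_axis(dx, argmax[:, :, None], axis=2) + dmax[:, :, None],
            axis=2,
        )
        return dx


class SpatialAttention(Module):
    def __init__(self, kernel: int = 3, rng: np.random.Generator | None = None,
                 name: str = "sa"):
        if kernel % 2 != 1:
            raise ValueError("spatial kernel must be odd for symmetric padding")
        rng = rng or np.random.default_rng(0)
        self.kernel = kernel
        self.name = name
        fan_in = 2 * kernel
        self.W = Parameter(_fan_in_uniform(rng, (2, kernel), fan_in), f"{name}.W")
        self.b = Parameter(_fan_in_uniform(rng, (1,), fan_in), f"{name}.b")
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]

    def _conv(self, cat: np.ndarray, T: int):
        pad = self.kernel // 2
        catpad = np.pad(cat, ((0, 0), (0, 0), (pad, pad)))
        s = np.full((cat.shape[0], T), self.b.data[0])
        for k in range(self.kernel):
            s += np.einsum("c,nct->nt", self.W.data[:, k], catpad[:, :, k: k + T])
        return s, catpad

    def weights(self, x: np.ndarray) -> np.ndarray:
        avg = x.mean(axis=1, keepdims=True)
        mx = x.max(axis=1, keepdims=True)
        s, _ = self._conv(np.concatenate([avg, mx], axis=1), x.shape[2])
        return sigmoid(s)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        N, C, T = x.shape
        avg = x.mean(axis=1, keepdims=True)
        mx = x.max(axis=1, keepdims=True)
        argmax = x.argmax(axis=1)
        cat = np.concatenate([avg, mx], axis=1)  # (N, 2, T)
        s, catpad = self._conv(cat, T)
        m = sigmoid(s)  # (N, T)
        self._cache = (x, cat, catpad, argmax, m, C, T)
        return x * m[:, None, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, cat, catpad, argmax, m, C, T = self._cache
        dx = dy * m[:, None, :]
        dm = (dy * x).sum(axis=1)
        ds = dm * m * (1.0 - m)  # (N, T)

        pad = self.kernel // 2
        dcatpad = np.zeros_like(catpad)
        for k in range(self.kernel):
            self.W.grad[:, k] += np.einsum("nt,nct->c", ds, catpad[:, :, k: k + T])
            dcatpad[:, :, k: k + T] += ds[:, None, :] * self.W.data[:, k][None, :, None]
        self.b.grad += ds.sum()
        dcat = dcatpad[:, :, pad: pad + T]
        dx += dcat[:, 0:1, :] / C
        np.put_along_axis(
            dx, argmax[:, None, :],
            np.take_along_axis(dx, argmax[:, None, :], axis=1) + dcat[:, 1:2, :],
            axis=1,
        )
        return dx


class CBAM(Module):
    """Channel attention followed by spatial attention, or identity when bypassed."""

    def __init__(self, channels: int, k: int | None = None, spatial_kernel: int = 3,
                 rng: np.random.Generator | None = None, name: str = "cbam",
                 bypass: bool = False):
        self.channel = ChannelAttention(channels, k, rng=rng, name=f"{name}.channel")
        self.spatial = SpatialAttention(spatial_kernel, rng=rng, name=f"{name}.spatial")
        self.bypass = bypass
        self.name = name

    def parameters(self) -> list[Parameter]:
        return self.channel.parameters() + self.spatial.parameters()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if self.bypass:
            return x
        return self.spatial.forward(self.channel.forward(x, training), training)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.bypass:
            return dy
        return self.channel.backward(self.spatial.backward(dy))
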
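"""Stacked LSTM with hand-written backpropagation through time.

Input layout is (N, T, C). Gate order in the packed weight matrices is
input, forget, cell, output. Windows here are ten steps long, so the
explicit Python loop over time is cheap.
"""

from __future__ import annotations

import numpy as np

from .layers import Module, Parameter, _fan_in_uniform, sigmoid

__all__ = ["LSTMLayer", "LSTMStack"]


class LSTMLayer(Module):
    def __init__(self, input_size: int, hidden_size: int,
                 rng: np.random.Generator | None = None, name: str = "lstm"):
        rng = rng or np.random.default_rng(0)
        self.input_size = input_size
        self.hidden_size = hidden_size
        self.name = name
        H = hidden_size
        self.Wx = Parameter(_fan_in_uniform(rng, (4 * H, input_size), H), f"{name}.Wx")
        self.Wh = Parameter(_fan_in_uniform(rng, (4 * H, H), H), f"{name}.Wh")
        self.b = Parameter(_fan_in_uniform(rng, (4 * H,), H), f"{name}.b")
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.Wx, self.Wh, self.b]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        N, T, _ = x.shape
        H = self.hidden_size
        h = np.zeros((N, H))
        c = np.zeros((N, H))
        hs = np.empty((N, T, H))
        steps = []
        for t in range(T):
            gates = x[:, t] @ self.Wx.data.T + h @ self.Wh.data.T + self.b.data
            i = sigmoid(gates[:, :H])
            f = sigmoid(gates[:, H:2 * H])
            g = np.tanh(gates[:, 2 * H:3 * H])
            o = sigmoid(gates[:, 3 * H:])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            hs[:, t] = h
            steps.append((x[:, t], h_prev, c_prev, i, f, g, o, tc))
        self._cache = (steps, x.shape)
        return hs

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        steps, xshape = self._cache
        N, T, _ = xshape
        H = self.hidden_size
        dx = np.empty(xshape)
        dh_next = np.zeros((N, H))
        dc_next = np.zeros((N, H))
        for t in reversed(range(T)):
            xt, h_prev, c_prev, i, f, g, o, tc = steps[t]
            dh = dhs[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dgates = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            self.Wx.grad += dgates.T @ xt
            self.Wh.grad += dgates.T @ h_prev
            self.b.grad += dgates.sum(axis=0)
            dx[:, t] = dgates @ self.Wx.data
            dh_next = dgates @ self.Wh.data
            dc_next = dc * f
        return dx


class LSTMStack(Module):
    """Stacked LSTM layers returning the full hidden sequence of the top layer."""

    def __init__(self, input_size: int, hidden_size: int, n_layers: int,
                 rng: np.random.Generator | None = None, name: str = "lstm"):
        sizes = [input_size] + [hidden_size] * n_layers
        self.layers = [
            LSTMLayer(sizes[i], hidden_size, rng=rng, name=f"{name}.layer{i}")
            for i in range(n_layers)
        ]
        self.name = name

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class TakeLastStep(Module):
    """(N, T, H) -> (N, H) at the final time step."""

    def __init__(self):
        self._shape = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x[:, -1, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._shape)
        dx[:, -1, :] = dy
        return dx
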
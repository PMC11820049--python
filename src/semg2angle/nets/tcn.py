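"""Temporal-convolutional residual blocks and stacks.

Each block runs two (causal dilated conv -> batch norm -> ReLU -> dropout)
stages and adds the input back through an identity shortcut, or a 1x1
convolution when the channel counts differ, with a final ReLU after the
addition. A stack of blocks with dilation schedule (d_1, ..., d_B) and
kernel K has receptive field 1 + 2*(K-1)*sum(d_b) — two convs per block.
"""

from __future__ import annotations

import numpy as np

from .layers import BatchNorm1d, CausalConv1d, Dropout, Module, Parameter, ReLU, Sequential

__all__ = ["ResidualBlock", "TCNStage", "receptive_field"]


def receptive_field(kernel: int, dilations: tuple[int, ...], convs_per_block: int = 2) -> int:
    """Span of past samples that can influence one output sample."""
    return 1 + convs_per_block * (kernel - 1) * int(sum(dilations))


class ResidualBlock(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 dilation: int, dropout: float,
                 rng: np.random.Generator | None = None,
                 dropout_rng: np.random.Generator | None = None,
                 name: str = "block"):
        rng = rng or np.random.default_rng(0)
        self.name = name
        self.path = Sequential(
            CausalConv1d(in_channels, out_channels, kernel, dilation, rng, f"{name}.conv1"),
            BatchNorm1d(out_channels, name=f"{name}.bn1"),
            ReLU(),
            Dropout(dropout, dropout_rng),
            CausalConv1d(out_channels, out_channels, kernel, dilation, rng, f"{name}.conv2"),
            BatchNorm1d(out_channels, name=f"{name}.bn2"),
            ReLU(),
            Dropout(dropout, dropout_rng),
        )
        if in_channels != out_channels:
            self.shortcut: Module | None = CausalConv1d(
                in_channels, out_channels, 1, 1, rng, f"{name}.proj"
            )
        else:
            self.shortcut = None
        self._relu_mask = None

    def parameters(self) -> list[Parameter]:
        params = self.path.parameters()
        if self.shortcut is not None:
            params += self.shortcut.parameters()
        return params

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        h = self.path.forward(x, training=training)
        s = x if self.shortcut is None else self.shortcut.forward(x, training=training)
        out = h + s
        self._relu_mask = out > 0
        return np.where(self._relu_mask, out, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dout = np.where(self._relu_mask, dy, 0.0)
        dx = self.path.backward(dout)
        if self.shortcut is None:
            dx = dx + dout
        else:
            dx = dx + self.shortcut.backward(dout)
        return dx


class TCNStage(Sequential):
    """Residual blocks with a per-block dilation schedule."""

    def __init__(self, in_channels: int, channels: int, kernel: int,
                 dilations: tuple[int, ...], dropout: float,
                 rng: np.random.Generator | None = None,
                 dropout_rng: np.random.Generator | None = None,
                 name: str = "tcn"):
        blocks = []
        c_in = in_channels
        for i, d in enumerate(dilations):
            blocks.append(
                ResidualBlock(c_in, channels, kernel, d, dropout,
                              rng=rng, dropout_rng=dropout_rng, name=f"{name}.block{i}")
            )
            c_in = channels
        super().__init__(*blocks, name=name)
        self.kernel = kernel
        self.dilations = tuple(dilations)

    @property
    def receptive_field(self) -> int:
        return receptive_field(self.kernel, self.dilations)
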
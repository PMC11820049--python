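"""Model zoo: the cascaded attention network and its comparison baselines.

``cb_tcn``   encoder TCN -> CBAM (channel then temporal attention) -> decoder
             TCN -> linear head on the final time step.
``ed_tcn``   the same cascade without the attention block.
``tcn``      a single TCN stage plus head.
``lstm``     stacked LSTM, head on the last hidden state.
``wiener``   FIR least squares over the window's lags (see ``wiener.py``).

All architectures share kernel size, channel width, depth and dropout
where applicable, so differences in fit quality reflect the architecture
rather than capacity knobs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cbam import CBAM
from .layers import Linear, Module, Sequential, TakeLast, Transpose
from .lstm import LSTMStack, TakeLastStep
from .tcn import TCNStage
from .wiener import WienerModel

__all__ = ["ModelSpec", "NeuralModel", "build_model", "ARCHITECTURES"]

ARCHITECTURES = ("cb_tcn", "ed_tcn", "tcn", "lstm", "wiener")


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameter description of one estimator (fully reproducible)."""

    architecture: str = "cb_tcn"
    in_channels: int = 7
    n_joints: int = 3
    channels: int = 64
    kernel: int = 3
    dilations: tuple[int, ...] = (1, 2)
    dropout: float = 0.05
    cbam_k: int | None = None  # None -> max(channels // 8, 1)
    cbam_spatial_kernel: int = 3
    lstm_hidden: int = 64
    lstm_layers: int = 2
    wiener_ridge: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; choose from {ARCHITECTURES}"
            )
        if self.kernel < 1 or self.channels < 1 or self.n_joints < 1:
            raise ValueError("kernel, channels and n_joints must be positive")

    def to_yaml(self, path: str | Path | None = None) -> str:
        doc = asdict(self)
        doc["dilations"] = list(doc["dilations"])
        text = yaml.safe_dump(doc)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "ModelSpec":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = yaml.safe_load(text)
        doc["dilations"] = tuple(doc.get("dilations", (1, 2)))
        return cls(**doc)


class NeuralModel:
    """A trainable network with the (windows -> joint angles) contract.

    ``forward`` consumes (N, W, in_channels) windows and returns
    (N, n_joints); ``backward`` accepts the loss gradient of the output.
    All initialization and dropout randomness derives from ``spec.seed``.
    """

    def __init__(self, spec: ModelSpec, net: Module, cbam: CBAM | None = None):
        self.spec = spec
        self.net = net
        self.cbam = cbam

    def parameters(self):
        return self.net.parameters()

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        self.net.zero_grad()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.net.forward(np.asarray(x, dtype=float), training=training)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.net.backward(dy)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, training=False)

    # -- checkpointing ----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name or f"param{i}": p.data for i, p in enumerate(self.parameters())}
        for i, m in enumerate(_iter_modules(self.net)):
            if hasattr(m, "running_mean"):
                state[f"{m.name or i}.running_mean"] = m.running_mean
                state[f"{m.name or i}.running_var"] = m.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.data[...] = state[p.name or f"param{i}"]
        for i, m in enumerate(_iter_modules(self.net)):
            if hasattr(m, "running_mean"):
                m.running_mean = np.asarray(state[f"{m.name or i}.running_mean"])
                m.running_var = np.asarray(state[f"{m.name or i}.running_var"])

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path, __spec__=self.spec.to_yaml(), **self.state_dict())
        return path

    @classmethod
    def load(cls, path: str | Path) -> "NeuralModel":
        with np.load(path, allow_pickle=False) as data:
            spec = ModelSpec.from_yaml(str(data["__spec__"]))
            model = build_model(spec)
            model.load_state_dict({k: data[k] for k in data.files if k != "__spec__"})
        return model


def _iter_modules(m: Module):
    yield m
    for attr in ("modules", "layers"):
        for child in getattr(m, attr, []):
            yield from _iter_modules(child)
    for attr in ("path", "shortcut", "channel", "spatial"):
        child = getattr(m, attr, None)
        if isinstance(child, Module):
            yield from _iter_modules(child)


def build_model(spec: ModelSpec):
    """Instantiate the estimator described by ``spec``.

    Returns a :class:`NeuralModel` for the network architectures and a
    :class:`WienerModel` for the linear baseline.
    """
    if spec.architecture == "wiener":
        return WienerModel(n_joints=spec.n_joints, ridge=spec.wiener_ridge)

    rng = np.random.default_rng(spec.seed)
    drop_rng = np.random.default_rng((spec.seed, 0xD0))

    if spec.architecture == "lstm":
        net = Sequential(
            LSTMStack(spec.in_channels, spec.lstm_hidden, spec.lstm_layers, rng=rng),
            TakeLastStep(),
            Linear(spec.lstm_hidden, spec.n_joints, rng=rng, name="head"),
            name="lstm",
        )
        return NeuralModel(spec, net)

    stage1 = TCNStage(spec.in_channels, spec.channels, spec.kernel, spec.dilations,
                      spec.dropout, rng=rng, dropout_rng=drop_rng, name="stage1")
    head = [TakeLast(), Linear(spec.channels, spec.n_joints, rng=rng, name="head")]

    if spec.architecture == "tcn":
        net = Sequential(Transpose(), stage1, *head, name="tcn")
        return NeuralModel(spec, net)

    cbam = None
    middle: list[Module] = []
    if spec.architecture == "cb_tcn":
        cbam = CBAM(spec.channels, spec.cbam_k, spec.cbam_spatial_kernel,
                    rng=np.random.default_rng((spec.seed, 0xCB)), name="cbam")
        middle = [cbam]
    stage2 = TCNStage(spec.channels, spec.channels, spec.kernel, spec.dilations,
                      spec.dropout, rng=rng, dropout_rng=drop_rng, name="stage2")
    net = Sequential(Transpose(), stage1, *middle, stage2, *head, name=spec.architecture)
    return NeuralModel(spec, net, cbam=cbam)
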
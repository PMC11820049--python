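"""Sliding-window expansion of processed trials into supervised samples.

A trial of length T yields ``floor((T - W) / S) + 1`` overlapping windows;
with the default W=10, S=1 that is T - W + 1 windows, each a verbatim
slice of the envelope matrix paired with the joint angles at the window's
last (or center) sample.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .session import ProcessedTrial

__all__ = ["WindowSpec", "WindowSet", "make_windows", "concat_trials", "Normalizer"]


@dataclass(frozen=True)
class WindowSpec:
    """Window length W, hop S (in samples) and target alignment policy."""

    W: int = 10
    S: int = 1
    target_policy: str = "last_sample"

    def __post_init__(self) -> None:
        if self.W < 1:
            raise ValueError("W must be >= 1")
        if self.S < 1:
            raise ValueError("S must be >= 1")
        if self.target_policy not in ("last_sample", "center_sample"):
            raise ValueError(f"unknown target_policy {self.target_policy!r}")

    def n_windows(self, T: int) -> int:
        """Window count for a length-T series (0 when T < W)."""
        if T < self.W:
            return 0
        return (T - self.W) // self.S + 1


@dataclass
class WindowSet:
    """Row-aligned supervised samples from one or more trials.

    ``inputs`` is (n_windows, W, n_channels); ``targets`` is
    (n_windows, n_joints) in degrees; ``trial_ids`` gives each row's
    source trial for leakage-free splitting.
    """

    inputs: np.ndarray
    targets: np.ndarray
    trial_ids: np.ndarray
    channel_names: list[str] = field(default_factory=list)
    joint_names: list[str] = field(default_factory=list)
    spec: WindowSpec = field(default_factory=WindowSpec)

    def __post_init__(self) -> None:
        if len(self.inputs) != len(self.targets) or len(self.inputs) != len(self.trial_ids):
            raise ValueError("inputs, targets and trial_ids must be row-aligned")

    def __len__(self) -> int:
        return len(self.inputs)

    @property
    def n_channels(self) -> int:
        return self.inputs.shape[2] if self.inputs.ndim == 3 else 0

    @property
    def n_joints(self) -> int:
        return self.targets.shape[1] if self.targets.ndim == 2 else 0

    def subset(self, mask: np.ndarray) -> "WindowSet":
        return WindowSet(
            inputs=self.inputs[mask],
            targets=self.targets[mask],
            trial_ids=self.trial_ids[mask],
            channel_names=self.channel_names,
            joint_names=self.joint_names,
            spec=self.spec,
        )

    def save(self, path: str | Path) -> Path:
        """Write inputs/targets as flat CSV-like text with a JSON sidecar."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savetxt(path / "inputs.csv", self.inputs.reshape(len(self), -1), delimiter=",")
        np.savetxt(path / "targets.csv", np.atleast_2d(self.targets), delimiter=",")
        np.savetxt(path / "trial_ids.csv", self.trial_ids, fmt="%d")
        sidecar = {
            "shape": list(self.inputs.shape),
            "channels": self.channel_names,
            "joints": self.joint_names,
            "spec": {"W": self.spec.W, "S": self.spec.S,
                     "target_policy": self.spec.target_policy},
        }
        (path / "windows.json").write_text(json.dumps(sidecar, indent=2))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "WindowSet":
        path = Path(path)
        sidecar = json.loads((path / "windows.json").read_text())
        shape = tuple(sidecar["shape"])
        inputs = np.loadtxt(path / "inputs.csv", delimiter=",", ndmin=2).reshape(shape)
        targets = np.loadtxt(path / "targets.csv", delimiter=",", ndmin=2)
        trial_ids = np.loadtxt(path / "trial_ids.csv", dtype=int, ndmin=1)
        return cls(
            inputs=inputs,
            targets=targets,
            trial_ids=trial_ids,
            channel_names=sidecar["channels"],
            joint_names=sidecar["joints"],
            spec=WindowSpec(**sidecar["spec"]),
        )


def make_windows(
    trial: ProcessedTrial, spec: WindowSpec | None = None, trial_id: int = 0
) -> WindowSet:
    """Expand one processed trial into overlapping windows.

    Degenerate trials shorter than W produce an empty set with a warning
    rather than an error.
    """
    spec = spec or WindowSpec()
    env = trial.envelopes.T  # (T, C)
    ang = trial.angle_matrix()  # (T, J)
    T = env.shape[0]
    n = spec.n_windows(T)
    if n == 0:
        warnings.warn(
            f"trial of length {T} shorter than window {spec.W}: empty window set",
            stacklevel=2,
        )
        return WindowSet(
            inputs=np.empty((0, spec.W, env.shape[1])),
            targets=np.empty((0, ang.shape[1])),
            trial_ids=np.empty((0,), dtype=int),
            channel_names=list(trial.channel_names),
            joint_names=trial.joint_names,
            spec=spec,
        )
    view = np.lib.stride_tricks.sliding_window_view(env, spec.W, axis=0)
    # view: (T-W+1, C, W) -> stride by S, put time back in the middle
    inputs = np.ascontiguousarray(view[:: spec.S][:n].transpose(0, 2, 1))
    starts = np.arange(n) * spec.S
    if spec.target_policy == "last_sample":
        tidx = starts + spec.W - 1
    else:
        tidx = starts + (spec.W - 1) // 2
    return WindowSet(
        inputs=inputs,
        targets=ang[tidx],
        trial_ids=np.full(n, trial_id, dtype=int),
        channel_names=list(trial.channel_names),
        joint_names=trial.joint_names,
        spec=spec,
    )


def concat_trials(sets: list[WindowSet]) -> WindowSet:
    """Row-stack window sets, preserving per-window trial provenance."""
    if not sets:
        return WindowSet(
            inputs=np.empty((0, 0, 0)),
            targets=np.empty((0, 0)),
            trial_ids=np.empty((0,), dtype=int),
        )
    first = sets[0]
    for s in sets[1:]:
        if s.channel_names != first.channel_names or s.joint_names != first.joint_names:
            raise ValueError("window sets disagree on channels or joints")
        if s.inputs.shape[1:] != first.inputs.shape[1:]:
            raise ValueError("window sets disagree on window shape")
    return WindowSet(
        inputs=np.concatenate([s.inputs for s in sets]),
        targets=np.concatenate([s.targets for s in sets]),
        trial_ids=np.concatenate([s.trial_ids for s in sets]),
        channel_names=first.channel_names,
        joint_names=first.joint_names,
        spec=first.spec,
    )


@dataclass
class Normalizer:
    """Per-channel z-scoring of inputs and targets, fit on training data only."""

    x_mean: np.ndarray | None = None
    x_std: np.ndarray | None = None
    y_mean: np.ndarray | None = None
    y_std: np.ndarray | None = None

    def fit(self, ws: WindowSet) -> "Normalizer":
        x = ws.inputs.reshape(-1, ws.n_channels)
        self.x_mean = x.mean(axis=0)
        self.x_std = np.where(x.std(axis=0) > 1e-12, x.std(axis=0), 1.0)
        self.y_mean = ws.targets.mean(axis=0)
        ystd = ws.targets.std(axis=0)
        self.y_std = np.where(ystd > 1e-12, ystd, 1.0)
        return self

    def transform_x(self, inputs: np.ndarray) -> np.ndarray:
        return (inputs - self.x_mean) / self.x_std

    def transform_y(self, targets: np.ndarray) -> np.ndarray:
        return (targets - self.y_mean) / self.y_std

    def inverse_y(self, targets_z: np.ndarray) -> np.ndarray:
        return targets_z * self.y_std + self.y_mean

    def to_dict(self) -> dict:
        return {
            k: (v.tolist() if v is not None else None)
            for k, v in (
                ("x_mean", self.x_mean), ("x_std", self.x_std),
                ("y_mean", self.y_mean), ("y_std", self.y_std),
            )
        }
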
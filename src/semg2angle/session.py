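"""Data containers for recorded / simulated sessions and their disk layout.

A session directory holds plain delimited tables plus a YAML manifest::

    session/
      manifest.yaml   pattern, rates, seed, channel names, joint names
      emg.csv         time + one column per EMG channel (mV)
      markers.csv     time + x/y/z per marker per joint (mm)
      angles.csv      (ground truth only) time + one column per joint (deg)
      activations.csv (ground truth only) time + one column per muscle
      processed.csv   (ProcessedTrial) time + envelopes + angles at 20 Hz
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["RawSession", "GroundTruth", "ProcessedTrial"]

MUSCLES = ("RF", "TA", "SOL", "GAS", "VM", "VL", "BF")
JOINTS = ("hip", "knee", "ankle")


@dataclass
class RawSession:
    """Synchronized multi-rate recording before any filtering.

    ``emg`` is (n_channels, n_emg_samples) in mV at ``fs_emg``; ``markers``
    maps joint name -> (n_mocap_samples, 3 points, 3 coords) in mm at
    ``fs_mocap``.
    """

    emg: np.ndarray
    markers: dict[str, np.ndarray]
    fs_emg: float
    fs_mocap: float
    pattern: str
    channel_names: tuple[str, ...] = MUSCLES
    seed: int | None = None

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        t_e = np.arange(self.emg.shape[1]) / self.fs_emg
        emg_df = pd.DataFrame({"time": t_e})
        for name, ch in zip(self.channel_names, self.emg):
            emg_df[name] = ch
        emg_df.to_csv(path / "emg.csv", index=False)

        n_m = next(iter(self.markers.values())).shape[0]
        mk_df = pd.DataFrame({"time": np.arange(n_m) / self.fs_mocap})
        for joint, m in self.markers.items():
            for p, pname in enumerate(("a", "b", "c")):
                for c, cname in enumerate("xyz"):
                    mk_df[f"{joint}_{pname}_{cname}"] = m[:, p, c]
        mk_df.to_csv(path / "markers.csv", index=False)

        manifest = {
            "pattern": self.pattern,
            "fs_emg": float(self.fs_emg),
            "fs_mocap": float(self.fs_mocap),
            "channels": list(self.channel_names),
            "joints": list(self.markers),
            "seed": self.seed,
        }
        (path / "manifest.yaml").write_text(yaml.safe_dump(manifest))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RawSession":
        path = Path(path)
        manifest = yaml.safe_load((path / "manifest.yaml").read_text())
        emg_df = pd.read_csv(path / "emg.csv")
        emg = emg_df[manifest["channels"]].to_numpy().T
        mk_df = pd.read_csv(path / "markers.csv")
        markers = {}
        for joint in manifest["joints"]:
            cols = [f"{joint}_{p}_{c}" for p in ("a", "b", "c") for c in "xyz"]
            markers[joint] = mk_df[cols].to_numpy().reshape(-1, 3, 3)
        return cls(
            emg=emg,
            markers=markers,
            fs_emg=manifest["fs_emg"],
            fs_mocap=manifest["fs_mocap"],
            pattern=manifest["pattern"],
            channel_names=tuple(manifest["channels"]),
            seed=manifest.get("seed"),
        )


@dataclass
class GroundTruth:
    """Latent state of a simulated session, kept for testing only.

    ``activations`` is (n_muscles, n_emg_samples) in [0, 1] at ``fs_emg``;
    ``angles`` maps joint -> degree series at ``fs_mocap``;
    ``mapping_params`` records the angle->activation forward-model
    parameters so tests can invert it.
    """

    activations: np.ndarray
    angles: dict[str, np.ndarray]
    fs_emg: float
    fs_mocap: float
    muscle_names: tuple[str, ...] = MUSCLES
    mapping_params: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        ang_df = pd.DataFrame(
            {"time": np.arange(len(next(iter(self.angles.values())))) / self.fs_mocap}
        )
        for joint, a in self.angles.items():
            ang_df[joint] = a
        ang_df.to_csv(path / "angles.csv", index=False)
        act_df = pd.DataFrame({"time": np.arange(self.activations.shape[1]) / self.fs_emg})
        for name, a in zip(self.muscle_names, self.activations):
            act_df[name] = a
        act_df.to_csv(path / "activations.csv", index=False)
        return path


@dataclass
class ProcessedTrial:
    """Envelopes and joint angles on the common analysis time base.

    ``envelopes`` is (n_channels, T) non-negative mV; ``angles`` maps
    joint -> length-T degree series; both at ``fs`` (20 Hz by default).
    """

    envelopes: np.ndarray
    angles: dict[str, np.ndarray]
    fs: float
    pattern: str
    channel_names: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.envelopes < 0):
            raise ValueError("envelopes must be non-negative")
        n = self.envelopes.shape[1]
        for joint, a in self.angles.items():
            if len(a) != n:
                raise ValueError(
                    f"angle series for {joint!r} has length {len(a)}, envelopes {n}"
                )

    @property
    def n_samples(self) -> int:
        return self.envelopes.shape[1]

    @property
    def joint_names(self) -> list[str]:
        return list(self.angles)

    def angle_matrix(self) -> np.ndarray:
        """Angles stacked to (T, n_joints) in manifest joint order."""
        return np.stack([self.angles[j] for j in self.angles], axis=1)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        df = pd.DataFrame({"time": np.arange(self.n_samples) / self.fs})
        for name, env in zip(self.channel_names, self.envelopes):
            df[f"env_{name}"] = env
        for joint, a in self.angles.items():
            df[f"angle_{joint}"] = a
        df.to_csv(path / "processed.csv", index=False)
        manifest = {
            "pattern": self.pattern,
            "fs": float(self.fs),
            "channels": list(self.channel_names),
            "joints": list(self.angles),
            "provenance": self.provenance,
        }
        (path / "processed_manifest.yaml").write_text(yaml.safe_dump(manifest))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ProcessedTrial":
        path = Path(path)
        manifest = yaml.safe_load((path / "processed_manifest.yaml").read_text())
        df = pd.read_csv(path / "processed.csv")
        env = df[[f"env_{c}" for c in manifest["channels"]]].to_numpy().T
        angles = {j: df[f"angle_{j}"].to_numpy() for j in manifest["joints"]}
        return cls(
            envelopes=env,
            angles=angles,
            fs=manifest["fs"],
            pattern=manifest["pattern"],
            channel_names=list(manifest["channels"]),
            provenance=manifest.get("provenance", {}),
        )
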
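"""Synthetic session generator: kinematics -> muscle activation -> raw sEMG.

The forward model stands in for human recordings. It is deliberately
simple — periodic joint trajectories, a monotone saturating map from
joint state to muscle activation with a known electromechanical lead, and
activation-modulated band-limited noise as the EMG carrier — so that every
downstream stage can be checked against the latent ground truth.

Angle convention: included vertex angle in degrees, strictly inside
(0, 180), which is what the three-marker geometry can represent. The
per-pattern periods and amplitude ranges are configuration, chosen to be
physiologically plausible; they are not measured values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .session import JOINTS, MUSCLES, GroundTruth, RawSession

__all__ = [
    "SimConfig",
    "PATTERNS",
    "simulate_angles",
    "angles_to_activations",
    "activations_to_semg",
    "angles_to_markers",
    "simulate_session",
    "simulate_trials",
]

# Per-pattern waveform bank: cycle period and, per joint, the mean included
# angle plus (fundamental, second-harmonic) cosine amplitudes and phases.
# Second harmonics stay below a quarter of the fundamental so every cycle
# contributes exactly one local maximum (no secondary peaks).
PATTERNS: dict[str, dict] = {
    "gait": {
        "period_s": 1.1,
        "default_duration_s": 5.5,
        "joints": {
            "hip": {"mean": 120.0, "amps": (12.0, 4.0), "phases": (0.0, 0.9)},
            # pronounced second harmonic: stance and swing flexion bumps
            "knee": {"mean": 135.0, "amps": (20.0, 9.0), "phases": (2.1, 5.4)},
            "ankle": {"mean": 95.0, "amps": (10.0, 4.0), "phases": (4.0, 1.5)},
        },
    },
    "obstacle": {
        "period_s": 2.5,
        "default_duration_s": 5.0,
        "joints": {
            "hip": {"mean": 115.0, "amps": (18.0, 4.0), "phases": (0.0, 0.5)},
            "knee": {"mean": 125.0, "amps": (26.0, 6.0), "phases": (1.6, 0.2)},
            "ankle": {"mean": 95.0, "amps": (12.0, 2.8), "phases": (3.1, 1.0)},
        },
    },
    "squat": {
        "period_s": 2.5,
        "default_duration_s": 25.0,
        "joints": {
            "hip": {"mean": 120.0, "amps": (20.0, 2.5), "phases": (math.pi, 0.0)},
            "knee": {"mean": 120.0, "amps": (30.0, 4.0), "phases": (math.pi, 0.0)},
            "ankle": {"mean": 100.0, "amps": (10.0, 1.5), "phases": (math.pi, 0.0)},
        },
    },
    "knee_flexion": {
        "period_s": 2.0,
        "default_duration_s": 20.0,
        "joints": {
            "hip": {"mean": 120.0, "amps": (0.5, 0.0), "phases": (0.0, 0.0)},
            "knee": {"mean": 125.0, "amps": (28.0, 4.0), "phases": (math.pi, 0.0)},
            "ankle": {"mean": 95.0, "amps": (10.0, 2.0), "phases": (1.2, 0.4)},
        },
    },
}

# Which joints drive which muscle, with agonist/antagonist signs, plus a
# velocity sensitivity. Rows follow MUSCLES = RF TA SOL GAS VM VL BF;
# columns follow JOINTS = hip knee ankle.
_ANGLE_WEIGHTS = np.array(
    [
        [0.7, -0.9, 0.0],   # RF: hip flexor / knee extensor
        [0.0, 0.3, -1.1],   # TA: dorsiflexor
        [0.0, 0.0, 1.0],    # SOL: plantarflexor
        [0.0, -0.5, 0.9],   # GAS: biarticular plantarflexor
        [0.0, -1.0, 0.0],   # VM: knee extensor
        [0.2, -1.0, 0.0],   # VL: knee extensor
        [-0.8, 0.8, 0.0],   # BF: hip extensor / knee flexor
    ]
)
_VELOCITY_WEIGHTS = np.array(
    [
        [0.3, -0.4, 0.0],
        [0.0, 0.1, -0.5],
        [0.0, 0.0, 0.5],
        [0.0, -0.2, 0.4],
        [0.0, -0.5, 0.0],
        [0.1, -0.5, 0.0],
        [-0.4, 0.3, 0.0],
    ]
)
# strong gains push the sigmoid well into both tails over a movement cycle,
# clipping waveform peaks: together with the within-trial amplitude drift
# this makes the envelope -> angle inverse distinctly nonlinear, so a
# linear FIR readout cannot fully invert it
_GAINS = np.array([4.5, 4.5, 4.5, 4.5, 4.5, 4.5, 4.5])
_BIASES = np.array([-0.9, -0.6, -1.1, -0.8, -0.6, -1.2, -0.9])


@dataclass(frozen=True)
class SimConfig:
    """Full description of one synthetic recording session."""

    pattern: str = "gait"
    duration_s: float = 5.5
    fs_emg: float = 2000.0
    fs_mocap: float = 100.0
    n_emg_channels: int = 7
    joints: tuple[str, ...] = JOINTS
    emd_s: float = 0.05
    line_hz: float = 50.0
    line_amp_rel: float = 0.5
    snr_db: float = 20.0
    emg_scale_mv: float = 1.0
    drift_depth: float = 0.3
    drift_hz: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(
                f"unknown pattern {self.pattern!r}; choose from {sorted(PATTERNS)}"
            )
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fs_emg <= 2 * 450:
            raise ValueError("fs_emg must exceed twice the 450 Hz EMG bandwidth")
        if self.fs_mocap <= 0:
            raise ValueError("fs_mocap must be positive")
        if self.emd_s < 0:
            raise ValueError("emd_s must be non-negative")
        if self.n_emg_channels < 1 or self.n_emg_channels > len(MUSCLES):
            raise ValueError(f"n_emg_channels must be in [1, {len(MUSCLES)}]")
        unknown = set(self.joints) - set(JOINTS)
        if unknown:
            raise ValueError(f"unknown joints {sorted(unknown)}")

    @classmethod
    def for_pattern(cls, pattern: str, **kwargs) -> "SimConfig":
        """Config with the pattern's default trial duration."""
        kwargs.setdefault("duration_s", PATTERNS[pattern]["default_duration_s"])
        return cls(pattern=pattern, **kwargs)

    @property
    def n_mocap(self) -> int:
        return int(round(self.duration_s * self.fs_mocap))

    @property
    def n_emg(self) -> int:
        return int(round(self.duration_s * self.fs_emg))


def _trial_rng(cfg: SimConfig) -> np.random.Generator:
    return np.random.default_rng(cfg.seed)


def simulate_angles(cfg: SimConfig, rng: np.random.Generator | None = None) -> dict[str, np.ndarray]:
    """Pattern-specific periodic joint trajectories at ``fs_mocap``.

    Each joint is a mean plus two harmonics of the cycle frequency (hence
    band-limited well below 5 Hz), with a seeded per-trial global time
    shift and +/-5 % amplitude scale so repeated trials differ slightly.
    """
    rng = rng or _trial_rng(cfg)
    bank = PATTERNS[cfg.pattern]
    period = bank["period_s"]
    t = np.arange(cfg.n_mocap) / cfg.fs_mocap
    t0 = rng.uniform(0.0, period)
    amp_scale = rng.uniform(0.95, 1.05)
    omega = 2.0 * math.pi / period
    # slow within-trial amplitude drift (cycle-to-cycle motor variability):
    # a few random cosines well below the cycle frequency, scaled to
    # +/- drift_depth; shared by all joints like a common effort level
    if cfg.drift_depth > 0:
        drift = np.zeros_like(t)
        for _ in range(3):
            f = rng.uniform(0.3, 1.0) * cfg.drift_hz
            drift += rng.uniform(0.5, 1.0) * np.cos(
                2.0 * math.pi * f * t + rng.uniform(0, 2 * math.pi)
            )
        peak = np.max(np.abs(drift))
        drift = 1.0 + cfg.drift_depth * drift / (peak if peak > 0 else 1.0)
    else:
        drift = np.ones_like(t)
    out: dict[str, np.ndarray] = {}
    for joint in cfg.joints:
        p = bank["joints"][joint]
        wave = np.zeros_like(t)
        for h, (amp, phase) in enumerate(zip(p["amps"], p["phases"]), start=1):
            wave += amp_scale * amp * np.cos(h * omega * (t - t0) + phase)
        out[joint] = p["mean"] + drift * wave
    return out


@dataclass
class ActivationMapping:
    """Stored parameters of the angle -> activation forward map.

    activation_m(t) = sigmoid(gain_m * u_m(t + emd) + bias_m) with
    u_m = sum_j W_ang[m,j] * z_j + W_vel[m,j] * v_j, where z_j / v_j are
    the standardized joint angle and angular velocity. Monotone and
    saturating, hence invertible given these parameters.
    """

    angle_weights: np.ndarray
    velocity_weights: np.ndarray
    gains: np.ndarray
    biases: np.ndarray
    angle_means: np.ndarray
    angle_scales: np.ndarray
    velocity_scales: np.ndarray
    emd_samples: int
    joints: tuple[str, ...]
    muscles: tuple[str, ...]

    def drive(self, angles_upsampled: np.ndarray) -> np.ndarray:
        """Unshifted drive u_m from (n_joints, T) angles at fs_emg."""
        z = (angles_upsampled - self.angle_means[:, None]) / self.angle_scales[:, None]
        v = np.gradient(z, axis=1) / self.velocity_scales[:, None]
        return self.angle_weights @ z + self.velocity_weights @ v


def _upsample_angles(angles: dict[str, np.ndarray], cfg: SimConfig) -> np.ndarray:
    ratio = cfg.fs_emg / cfg.fs_mocap
    frac_num = int(round(ratio))
    if abs(ratio - frac_num) > 1e-9:
        raise ValueError("fs_emg must be an integer multiple of fs_mocap")
    stacked = np.stack([angles[j] for j in cfg.joints])
    if frac_num == 1:
        return stacked
    means = stacked.mean(axis=1, keepdims=True)
    up = signal.resample_poly(stacked - means, frac_num, 1, axis=1, padtype="line")
    return up + means


def angles_to_activations(
    angles: dict[str, np.ndarray], cfg: SimConfig
) -> tuple[np.ndarray, ActivationMapping]:
    """Muscle activations in [0, 1] at ``fs_emg``, leading the angles by ``emd_s``.

    The lead is realized by evaluating the drive at ``t + emd_s`` (edge
    padded), i.e. the activation at time t anticipates the kinematic state
    the electromechanical delay later.
    """
    n_ch = cfg.n_emg_channels
    up = _upsample_angles(angles, cfg)
    means = up.mean(axis=1)
    scales = up.std(axis=1)
    scales = np.where(scales > 1e-9, scales, 1.0)
    zs = (up - means[:, None]) / scales[:, None]
    vel = np.gradient(zs, axis=1)
    vscales = vel.std(axis=1)
    vscales = np.where(vscales > 1e-12, vscales, 1.0)

    mapping = ActivationMapping(
        angle_weights=_ANGLE_WEIGHTS[:n_ch, : len(cfg.joints)].copy(),
        velocity_weights=_VELOCITY_WEIGHTS[:n_ch, : len(cfg.joints)].copy(),
        gains=_GAINS[:n_ch].copy(),
        biases=_BIASES[:n_ch].copy(),
        angle_means=means,
        angle_scales=scales,
        velocity_scales=vscales,
        emd_samples=int(round(cfg.emd_s * cfg.fs_emg)),
        joints=tuple(cfg.joints),
        muscles=MUSCLES[:n_ch],
    )
    u = mapping.drive(up)
    if mapping.emd_samples > 0:
        k = mapping.emd_samples
        u = np.concatenate([u[:, k:], np.repeat(u[:, -1:], k, axis=1)], axis=1)
    act = 1.0 / (1.0 + np.exp(-(mapping.gains[:, None] * u + mapping.biases[:, None])))
    return act, mapping


def activations_to_semg(
    activations: np.ndarray, cfg: SimConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Raw multi-channel sEMG (mV) at ``fs_emg``.

    Each channel is a unit-RMS 20-450 Hz Gaussian carrier multiplied by
    the activation (linear gain), plus a line-frequency sinusoid scaled
    relative to the modulated-signal RMS and broadband Gaussian noise at
    ``snr_db`` below the modulated-signal power.
    """
    rng = rng or _trial_rng(cfg)
    act = np.asarray(activations, dtype=float)
    if act.ndim != 2:
        raise ValueError("activations must be (n_channels, n_samples)")
    if np.any(act < 0) or np.any(act > 1):
        raise ValueError("activations must lie in [0, 1]")
    n_ch, n = act.shape
    t = np.arange(n) / cfg.fs_emg

    sos = signal.butter(4, (20.0, 450.0), btype="bandpass", fs=cfg.fs_emg, output="sos")
    carrier = signal.sosfiltfilt(sos, rng.standard_normal((n_ch, n)), axis=1)
    crms = np.sqrt(np.mean(carrier**2, axis=1, keepdims=True))
    carrier = carrier / np.where(crms > 0, crms, 1.0)

    emg = cfg.emg_scale_mv * act * carrier
    mod_rms = np.sqrt(np.mean(emg**2, axis=1, keepdims=True))

    if cfg.line_amp_rel > 0:
        phases = rng.uniform(0, 2 * math.pi, size=(n_ch, 1))
        line = np.sin(2 * math.pi * cfg.line_hz * t[None, :] + phases)
        emg = emg + cfg.line_amp_rel * mod_rms * math.sqrt(2.0) * line
    if np.isfinite(cfg.snr_db):
        noise_rms = mod_rms / (10.0 ** (cfg.snr_db / 20.0))
        emg = emg + noise_rms * rng.standard_normal((n_ch, n))
    return emg


# planar marker geometry: vertex at a per-joint origin, two 400 mm segments
# opening symmetrically about the +y axis
_SEGMENT_MM = 400.0
_JOINT_SPACING_MM = 500.0


def angles_to_markers(angles: dict[str, np.ndarray], cfg: SimConfig) -> dict[str, np.ndarray]:
    """Three planar markers per joint whose vertex angle equals the input.

    Returns joint -> (T, 3 points, 3 coords) in mm. The vertex marker is
    static; the two limb markers swing symmetrically so the included angle
    reproduces the angle series exactly. Angles must lie strictly inside
    (0, 180) degrees — a collinear or folded vertex is degenerate.
    """
    out: dict[str, np.ndarray] = {}
    for idx, joint in enumerate(cfg.joints):
        theta = np.asarray(angles[joint], dtype=float)
        if np.any(theta <= 0.0) or np.any(theta >= 180.0):
            raise ValueError(
                f"{joint}: angles must lie strictly inside (0, 180) degrees"
            )
        half = np.radians(theta) / 2.0
        base = np.array([idx * _JOINT_SPACING_MM, 0.0, 0.0])
        n = len(theta)
        m = np.empty((n, 3, 3))
        m[:, 1] = base
        # limbs at 90deg +/- half-angle from +x axis
        ang_a = np.pi / 2.0 + half
        ang_c = np.pi / 2.0 - half
        m[:, 0, 0] = base[0] + _SEGMENT_MM * np.cos(ang_a)
        m[:, 0, 1] = base[1] + _SEGMENT_MM * np.sin(ang_a)
        m[:, 0, 2] = base[2]
        m[:, 2, 0] = base[0] + _SEGMENT_MM * np.cos(ang_c)
        m[:, 2, 1] = base[1] + _SEGMENT_MM * np.sin(ang_c)
        m[:, 2, 2] = base[2]
        out[joint] = m
    return out


def simulate_session(cfg: SimConfig) -> tuple[RawSession, GroundTruth]:
    """One synthetic trial: raw streams plus the latent ground truth."""
    rng = _trial_rng(cfg)
    angles = simulate_angles(cfg, rng)
    activations, mapping = angles_to_activations(angles, cfg)
    emg = activations_to_semg(activations, cfg, rng)
    markers = angles_to_markers(angles, cfg)
    raw = RawSession(
        emg=emg,
        markers=markers,
        fs_emg=cfg.fs_emg,
        fs_mocap=cfg.fs_mocap,
        pattern=cfg.pattern,
        channel_names=MUSCLES[: cfg.n_emg_channels],
        seed=cfg.seed,
    )
    truth = GroundTruth(
        activations=activations,
        angles=angles,
        fs_emg=cfg.fs_emg,
        fs_mocap=cfg.fs_mocap,
        muscle_names=MUSCLES[: cfg.n_emg_channels],
        mapping_params={"mapping": mapping, "emd_s": cfg.emd_s},
    )
    return raw, truth


def simulate_trials(cfg: SimConfig, n_trials: int) -> list[tuple[RawSession, GroundTruth]]:
    """Independent repeats of the same movement: seeds ``seed .. seed+n-1``.

    Pattern parameters are shared; noise, phase and amplitude jitter differ
    per trial.
    """
    return [simulate_session(replace(cfg, seed=cfg.seed + i)) for i in range(n_trials)]
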
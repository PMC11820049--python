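"""Signal conditioning: filtering, envelope extraction, joint angles, resampling.

The analysis chain brings every stream onto a common 20 Hz time base:

* EMG channels: 20-450 Hz band-pass -> 50 Hz notch (Q=35) -> full-wave
  rectification -> 10 Hz low-pass envelope -> resample to 20 Hz.
* Marker trajectories: 15 Hz zero-phase low-pass -> three-point vertex
  angle per frame -> resample to 20 Hz.

All IIR filters are Butterworth (or a single second-order notch) designed
with :mod:`scipy.signal`. "Fourth order, zero phase" means a 4th-order
design applied forward-backward, i.e. an 8th-order magnitude response.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

from .session import ProcessedTrial, RawSession

__all__ = [
    "FilterSpec",
    "apply_filter",
    "extract_envelope",
    "joint_angle",
    "joint_angle_series",
    "resample",
    "preprocess_session",
    "EMG_BANDPASS_HZ",
    "NOTCH_HZ",
    "NOTCH_Q",
    "ENVELOPE_LOWPASS_HZ",
    "KINEMATIC_LOWPASS_HZ",
    "ANALYSIS_RATE_HZ",
]

EMG_BANDPASS_HZ = (20.0, 450.0)
NOTCH_HZ = 50.0
NOTCH_Q = 35.0
ENVELOPE_LOWPASS_HZ = 10.0
KINEMATIC_LOWPASS_HZ = 15.0
ANALYSIS_RATE_HZ = 20.0


@dataclass(frozen=True)
class FilterSpec:
    """Description of one linear filter in the conditioning chain.

    Parameters
    ----------
    kind:
        One of ``butter_bandpass``, ``butter_lowpass``, ``notch``.
    cutoff_hz:
        Single corner frequency, or a ``(low, high)`` pair for the band-pass.
        For the notch this is the center frequency.
    fs:
        Sampling rate of the series the filter will be applied to.
    order:
        Butterworth design order (ignored for the notch, which is the
        standard second-order design).
    q_factor:
        Quality factor of the notch.
    zero_phase:
        Apply forward-backward (``filtfilt``) for zero group delay. When
        false the filter runs causally in one pass.
    """

    kind: str
    cutoff_hz: float | tuple[float, float]
    fs: float
    order: int = 4
    q_factor: float = NOTCH_Q
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("butter_bandpass", "butter_lowpass", "notch"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        nyq = self.fs / 2.0
        cut = np.atleast_1d(np.asarray(self.cutoff_hz, dtype=float))
        if np.any(cut <= 0) or np.any(cut >= nyq):
            raise ValueError(
                f"cutoff {self.cutoff_hz} must lie strictly inside (0, {nyq}) Hz"
            )
        if self.kind == "butter_bandpass":
            if cut.size != 2 or cut[0] >= cut[1]:
                raise ValueError("band-pass needs an increasing (low, high) pair")
        elif cut.size != 1:
            raise ValueError(f"{self.kind} takes a single cutoff")
        if self.kind == "notch" and self.q_factor <= 0:
            raise ValueError("q_factor must be positive")

    def design_sos(self) -> np.ndarray:
        """Return the filter as second-order sections."""
        if self.kind == "butter_bandpass":
            return signal.butter(
                self.order, self.cutoff_hz, btype="bandpass", fs=self.fs, output="sos"
            )
        if self.kind == "butter_lowpass":
            return signal.butter(
                self.order, self.cutoff_hz, btype="lowpass", fs=self.fs, output="sos"
            )
        b, a = signal.iirnotch(float(np.atleast_1d(self.cutoff_hz)[0]), self.q_factor, fs=self.fs)
        return signal.tf2sos(b, a)


def apply_filter(x: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Filter a uniform series (last axis = time), preserving length.

    Zero-phase specs run forward-backward and therefore introduce no lag;
    causal specs run a single forward pass.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] == 0:
        raise ValueError("empty series")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite samples")
    sos = spec.design_sos()
    if spec.zero_phase:
        # filtfilt needs padlen < n; fall back to a shorter pad for short series
        ntaps = 2 * sos.shape[0] + 1
        padlen = min(3 * ntaps, x.shape[-1] - 1)
        return signal.sosfiltfilt(sos, x, axis=-1, padlen=padlen)
    return signal.sosfilt(sos, x, axis=-1)


def extract_envelope(emg: np.ndarray, fs: float, *, zero_phase: bool = True) -> np.ndarray:
    """Full-wave rectification followed by a 10 Hz low-pass.

    Expects an already band-passed / notch-filtered channel. The output is
    clipped at zero: the low-pass can slightly undershoot near sharp
    transitions and the envelope is non-negative by definition.
    """
    spec = FilterSpec("butter_lowpass", ENVELOPE_LOWPASS_HZ, fs, order=4, zero_phase=zero_phase)
    env = apply_filter(np.abs(np.asarray(emg, dtype=float)), spec)
    return np.clip(env, 0.0, None)


def joint_angle(a, b, c) -> float:
    """Included angle (degrees) at vertex ``b`` of the triple ``a-b-c``.

    Computed from the cosine of the angle between the limb vectors
    ``a - b`` and ``c - b``; the cosine is clamped to [-1, 1] before the
    arccos so collinear triples are exact. Range [0, 180].
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    u = a - b
    v = c - b
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    if np.any(nu == 0) or np.any(nv == 0):
        raise ValueError("degenerate geometry: zero-length limb vector")
    cosang = np.sum(u * v, axis=-1) / (nu * nv)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def joint_angle_series(markers: np.ndarray) -> np.ndarray:
    """Vertex angle per frame for a ``(T, 3, 3)`` marker-triple trajectory."""
    m = np.asarray(markers, dtype=float)
    if m.ndim != 3 or m.shape[1:] != (3, 3):
        raise ValueError("expected markers of shape (T, 3 points, 3 coords)")
    return joint_angle(m[:, 0], m[:, 1], m[:, 2])


def resample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Anti-aliased rational-factor resampling along the last axis.

    Output length is ``round(n * fs_out / fs_in)`` for exact rational
    ratios. The content is assumed band-limited below ``fs_out / 2``
    (true for 10 Hz envelopes and 15 Hz-filtered kinematics going to 20 Hz).
    """
    x = np.asarray(x, dtype=float)
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be positive")
    if x.shape[-1] == 0:
        raise ValueError("empty series")
    if fs_out > fs_in:
        import warnings

        warnings.warn("upsampling requested (fs_out > fs_in)", stacklevel=2)
    frac = Fraction(fs_out / fs_in).limit_denominator(10**6)
    up, down = frac.numerator, frac.denominator
    if up == down:
        return x.copy()
    return signal.resample_poly(x, up, down, axis=-1, padtype="line")


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs of the full conditioning chain (defaults follow the study design)."""

    emg_band_hz: tuple[float, float] = EMG_BANDPASS_HZ
    notch_hz: float = NOTCH_HZ
    notch_q: float = NOTCH_Q
    envelope_lp_hz: float = ENVELOPE_LOWPASS_HZ
    kinematic_lp_hz: float = KINEMATIC_LOWPASS_HZ
    out_rate_hz: float = ANALYSIS_RATE_HZ
    order: int = 4
    emg_zero_phase: bool = True


def preprocess_session(raw: RawSession, cfg: PreprocessConfig | None = None) -> ProcessedTrial:
    """Run the full conditioning chain on one recorded session.

    EMG channels and marker streams are processed independently, brought to
    the common output rate and truncated to the overlapping duration. The
    two streams must describe the same recording: a duration mismatch of
    more than one output-rate sample raises an alignment error.
    """
    cfg = cfg or PreprocessConfig()
    fs_e, fs_m = raw.fs_emg, raw.fs_mocap

    dur_e = raw.emg.shape[1] / fs_e
    dur_m = next(iter(raw.markers.values())).shape[0] / fs_m
    if abs(dur_e - dur_m) > 1.0 / cfg.out_rate_hz:
        raise ValueError(
            f"stream durations differ by {abs(dur_e - dur_m):.3f} s "
            f"(> 1 sample at {cfg.out_rate_hz} Hz)"
        )

    bp = FilterSpec("butter_bandpass", cfg.emg_band_hz, fs_e, order=cfg.order,
                    zero_phase=cfg.emg_zero_phase)
    notch = FilterSpec("notch", cfg.notch_hz, fs_e, q_factor=cfg.notch_q,
                       zero_phase=cfg.emg_zero_phase)
    envelopes = []
    for ch in raw.emg:
        y = apply_filter(ch, bp)
        y = apply_filter(y, notch)
        env = extract_envelope(y, fs_e, zero_phase=cfg.emg_zero_phase)
        envelopes.append(resample(env, fs_e, cfg.out_rate_hz))
    env20 = np.clip(np.stack(envelopes), 0.0, None)

    lp = FilterSpec("butter_lowpass", cfg.kinematic_lp_hz, fs_m, order=cfg.order,
                    zero_phase=True)
    angles = {}
    for joint, markers in raw.markers.items():
        smoothed = np.stack(
            [apply_filter(markers[:, p, :].T, lp).T for p in range(3)], axis=1
        )
        theta = joint_angle_series(smoothed)
        angles[joint] = resample(theta, fs_m, cfg.out_rate_hz)

    n = min([env20.shape[1]] + [a.shape[0] for a in angles.values()])
    env20 = env20[:, :n]
    angles = {j: a[:n] for j, a in angles.items()}

    provenance = {
        "emg_chain": [
            f"butter_bandpass{cfg.emg_band_hz}@order{cfg.order}",
            f"notch{cfg.notch_hz}Hz@Q{cfg.notch_q}",
            "rectify",
            f"butter_lowpass{cfg.envelope_lp_hz}Hz",
            f"resample->{cfg.out_rate_hz}Hz",
        ],
        "kinematic_chain": [
            f"butter_lowpass{cfg.kinematic_lp_hz}Hz zero-phase",
            "three-point vertex angle",
            f"resample->{cfg.out_rate_hz}Hz",
        ],
        "emg_zero_phase": cfg.emg_zero_phase,
    }
    return ProcessedTrial(
        envelopes=env20,
        angles=angles,
        fs=cfg.out_rate_hz,
        pattern=raw.pattern,
        channel_names=list(raw.channel_names),
        provenance=provenance,
    )
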
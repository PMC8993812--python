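"""Accelerometer feature variants: Raw-30 Hz spectrograms, TBVM, FFT-1Hz, Uniform-1Hz.

Four feature families are derived from tri-axial limb accelerometry:

* ``Raw 30 Hz``: the 30 Hz vector-magnitude stream, cut into non-overlapping
  75 s frames and decomposed into 19x129 linear spectrogram patches for the
  CNN.
* ``TBVM``: Total Body Vector Magnitude — a single scalar summarizing all
  four limbs.  Each limb's mean 1 Hz VM is divided by 717.9 (the largest
  healthy-volunteer limb average, which belonged to the left wrist) and
  multiplied by the limb's normalization coefficient; the four normalized
  values are summed.
* ``FFT 1 Hz``: two scalar features per limb (mean movement level and the
  dominant non-DC spectral magnitude) from the DFT of the 1 Hz VM series —
  8 features in total.
* ``Uniform 1 Hz``: the 1 Hz VM series truncated or zero-padded to exactly
  70 samples per limb (280 values), optionally z-scored with statistics
  estimated on the training split only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alsfrs import LIMBS
from .io import AccelRecording

ACCEL_RATE = 30
FRAME_SECONDS = 75
FRAME_SAMPLES = FRAME_SECONDS * ACCEL_RATE  # 2250
STFT_WINDOW = 7 * ACCEL_RATE                # 210 samples = 7 s
STFT_HOP = 4 * ACCEL_RATE                   # 120 samples = 4 s
N_FFT = 256                                 # 30 Hz * 7 s = 210 -> next pow2
N_TIME_STEPS = 19                           # 75 / (7 - 3)
N_FREQ_BINS = N_FFT // 2 + 1                # 129
UNIFORM_LENGTH = 70

__all__ = [
    "TbvmCoefficients",
    "TBVM_COEFFICIENTS",
    "vector_magnitude",
    "tbvm",
    "fft1hz_features",
    "Uniform1HzScaler",
    "uniform1hz",
    "accel_frames",
    "accel_spectrogram",
    "block_average_1hz",
    "recording_vm_1hz",
]


@dataclass(frozen=True)
class TbvmCoefficients:
    """Healthy-volunteer normalization constants for the TBVM summary.

    The divisor is the largest limb-average VM observed in an 18-volunteer
    control cohort (left wrist, 717.9); each limb's coefficient is the ratio
    of that maximum to the limb's own control average, so the left wrist's
    coefficient is exactly 1.  The both-wrists coefficient belongs to a fifth
    exercise that the four-limb TBVM does not use.
    """

    divisor: float = 717.9
    per_limb: dict[str, float] = field(
        default_factory=lambda: {
            "LA": 2.497844,
            "RA": 2.492674,
            "LW": 1.0,
            "RW": 1.01044,
        }
    )
    both_wrists: float = 3.123886


TBVM_COEFFICIENTS = TbvmCoefficients()


def vector_magnitude(x, y, z) -> np.ndarray:
    """Per-sample Euclidean norm of the tri-axial reading."""
    x, y, z = (np.asarray(a, dtype=np.float64) for a in (x, y, z))
    if not (x.shape == y.shape == z.shape):
        raise ValueError("x, y, z must have the same length")
    return np.sqrt(x**2 + y**2 + z**2)


def tbvm(
    limb_mean_vm: dict[str, float],
    coeffs: TbvmCoefficients = TBVM_COEFFICIENTS,
) -> float:
    """Total Body Vector Magnitude from per-limb mean 1 Hz VM values.

    ``sum over limbs of coeff_limb * (vm_limb / divisor)``.  All four limbs
    must be present.
    """
    missing = [l for l in coeffs.per_limb if l not in limb_mean_vm]
    if missing:
        raise ValueError(f"missing limb(s) for TBVM: {missing}")
    return float(
        sum(
            coeffs.per_limb[limb] * (float(limb_mean_vm[limb]) / coeffs.divisor)
            for limb in coeffs.per_limb
        )
    )


def fft1hz_features(limb_series_1hz: dict[str, np.ndarray]) -> np.ndarray:
    """Two DFT features per limb from the 1 Hz VM series — 8 values total.

    Per limb, in LA, LW, RA, RW order: (1) the DC magnitude divided by the
    series length, i.e. the mean movement level, and (2) the largest non-DC
    magnitude divided by the series length, i.e. the dominant periodic
    component (half the amplitude of a pure sinusoid spanning an integer
    number of periods).
    """
    missing = [l for l in LIMBS if l not in limb_series_1hz]
    if missing:
        raise ValueError(f"missing limb(s): {missing}")
    feats = []
    for limb in LIMBS:
        series = np.asarray(limb_series_1hz[limb], dtype=np.float64)
        if series.size == 0:
            raise ValueError(f"limb {limb!r}: empty series")
        spectrum = np.abs(np.fft.rfft(series)) / len(series)
        feats.append(spectrum[0])
        feats.append(spectrum[1:].max() if len(spectrum) > 1 else 0.0)
    return np.asarray(feats)


class Uniform1HzScaler:
    """Per-position standardization for Uniform-1Hz vectors.

    Statistics are estimated on the training split only and reused for the
    validation and test splits.  Positions with zero variance are centered
    but not scaled (their sd is treated as 1).
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "Uniform1HzScaler":
        X = np.asarray(X, dtype=np.float64)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("scaler is not fitted")
        return (np.asarray(X, dtype=np.float64) - self.mean_) / self.scale_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def uniform1hz(
    limb_series_1hz: dict[str, np.ndarray],
    scaler: Uniform1HzScaler | None = None,
) -> np.ndarray:
    """Fixed-length (280,) vector: 70 x 1 Hz VM samples per limb.

    Shorter limb series are zero-padded to 70 samples, longer ones truncated.
    If a fitted scaler is given the vector is z-scored with its (training)
    statistics.
    """
    missing = [l for l in LIMBS if l not in limb_series_1hz]
    if missing:
        raise ValueError(f"missing limb(s): {missing}")
    parts = []
    for limb in LIMBS:
        series = np.asarray(limb_series_1hz[limb], dtype=np.float64)[:UNIFORM_LENGTH]
        parts.append(np.pad(series, (0, UNIFORM_LENGTH - len(series))))
    vec = np.concatenate(parts)
    if scaler is not None:
        vec = scaler.transform(vec[None, :])[0]
    return vec


def accel_frames(recording: AccelRecording) -> dict[str, list[np.ndarray]]:
    """Cut each limb's 30 Hz VM stream into non-overlapping 75 s frames.

    Returns limb -> list of 2250-sample VM frames; the trailing partial frame
    is dropped, so sessions shorter than 75 s yield empty lists.
    """
    if recording.sample_rate_hz != ACCEL_RATE:
        raise ValueError("framing requires the 30 Hz stream")
    out: dict[str, list[np.ndarray]] = {}
    for limb, xyz in recording.limb_series.items():
        vm = vector_magnitude(xyz[0], xyz[1], xyz[2])
        n = len(vm) // FRAME_SAMPLES
        out[limb] = [vm[i * FRAME_SAMPLES : (i + 1) * FRAME_SAMPLES] for i in range(n)]
    return out


def accel_spectrogram(frame_vm: np.ndarray) -> np.ndarray:
    """Linear spectrogram of one 75 s VM frame, shape (19, 129).

    Rectangular 7 s (210-sample) windows hopped every 4 s — 19 windows, the
    final ones zero-padded where they overrun the frame — each zero-padded to
    a 256-point FFT giving 129 one-sided bins of linear magnitude (no log).
    """
    frame_vm = np.asarray(frame_vm, dtype=np.float64)
    if frame_vm.shape != (FRAME_SAMPLES,):
        raise ValueError(
            f"frame must have exactly {FRAME_SAMPLES} samples, got {frame_vm.shape}"
        )
    padded = np.pad(frame_vm, (0, STFT_WINDOW))
    starts = np.arange(N_TIME_STEPS) * STFT_HOP
    idx = starts[:, None] + np.arange(STFT_WINDOW)[None, :]
    return np.abs(np.fft.rfft(padded[idx], n=N_FFT, axis=1))


def block_average_1hz(series_30hz: np.ndarray) -> np.ndarray:
    """Derive a 1 Hz stream by averaging consecutive 30-sample blocks.

    Used when no native 1 Hz vendor export accompanies the 30 Hz stream; the
    trailing partial second is dropped.
    """
    series_30hz = np.asarray(series_30hz, dtype=np.float64)
    n = len(series_30hz) // ACCEL_RATE
    return series_30hz[: n * ACCEL_RATE].reshape(n, ACCEL_RATE).mean(axis=1)


def recording_vm_1hz(recording: AccelRecording) -> dict[str, np.ndarray]:
    """Per-limb 1 Hz VM series for a recording (native 1 Hz or derived)."""
    out: dict[str, np.ndarray] = {}
    for limb, xyz in recording.limb_series.items():
        vm = vector_magnitude(xyz[0], xyz[1], xyz[2])
        out[limb] = vm if recording.sample_rate_hz == 1 else block_average_1hz(vm)
    return out
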
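"""Voice featurization: 96x64 log-mel spectrogram context windows.

A recording is resampled to an 8 kHz mono stream and cut into non-overlapping
960 ms frames (7680 samples).  Each frame is decomposed with a short-time
Fourier transform over 25 ms windows hopped every 10 ms (the windows that
overrun the frame are zero-padded), integrated into 64 mel-spaced frequency
bins, and log-transformed after adding an offset of 0.001.  The result is one
96x64 log-mel "context window" per frame — the unit the voice classifier
consumes.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy.signal import resample_poly

from .io import VoiceRecording

TARGET_RATE = 8000
FRAME_SAMPLES = 7680          # 960 ms at 8 kHz
STFT_WINDOW = 200             # 25 ms
STFT_HOP = 80                 # 10 ms
N_FFT = 256                   # next power of two >= 200
N_TIME_STEPS = 96             # hops at 0, 80, ..., 7600
N_MELS = 64
MEL_FMIN = 125.0
MEL_FMAX = 3800.0
LOG_OFFSET = 1e-3

__all__ = [
    "resample_mono",
    "frame_audio",
    "mel_filterbank",
    "logmel_window",
    "logmel_windows",
]


def resample_mono(
    waveform: np.ndarray,
    in_rate: float,
    participant_id: str = "",
    date: int = 0,
) -> VoiceRecording:
    """Downmix to mono and uniformly resample to 8 kHz.

    Accepts shape (n,) mono or (2, n) stereo input; stereo channels are
    averaged.  Duration is preserved to within one sample.
    """
    x = np.asarray(waveform, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty waveform")
    if in_rate <= 0:
        raise ValueError("in_rate must be positive")
    if x.ndim == 2:
        if x.shape[0] > 2:
            raise ValueError("at most 2 channels supported")
        x = x.mean(axis=0)
    elif x.ndim != 1:
        raise ValueError("waveform must be 1-D or 2-D")

    if in_rate != TARGET_RATE:
        ratio = Fraction(TARGET_RATE, int(round(in_rate))).limit_denominator(10**6)
        n_in = np.asarray(waveform, dtype=np.float64).shape[-1]
        x = resample_poly(x, ratio.numerator, ratio.denominator)
        # resample_poly yields ceil(n*up/down); trim/pad to the exact duration
        n_target = int(round(n_in * TARGET_RATE / in_rate))
        if len(x) > n_target:
            x = x[:n_target]
        elif len(x) < n_target:
            x = np.pad(x, (0, n_target - len(x)))
    return VoiceRecording(participant_id, date, x, TARGET_RATE)


def frame_audio(recording: VoiceRecording) -> list[np.ndarray]:
    """Cut an 8 kHz recording into non-overlapping 960 ms frames.

    The trailing partial frame is dropped; recordings shorter than 960 ms
    yield an empty list.
    """
    if recording.sample_rate_hz != TARGET_RATE:
        raise ValueError("recording must be resampled to 8000 Hz first")
    x = recording.waveform
    n_frames = len(x) // FRAME_SAMPLES
    return [
        x[i * FRAME_SAMPLES : (i + 1) * FRAME_SAMPLES] for i in range(n_frames)
    ]


def _hz_to_mel(hz):
    """HTK mel scale."""
    return 2595.0 * np.log10(1.0 + np.asarray(hz, dtype=np.float64) / 700.0)


def _mel_to_hz(mel):
    return 700.0 * (10.0 ** (np.asarray(mel, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(
    n_mels: int = N_MELS,
    n_fft: int = N_FFT,
    sample_rate: float = TARGET_RATE,
    fmin: float = MEL_FMIN,
    fmax: float = MEL_FMAX,
) -> np.ndarray:
    """Triangular mel filterbank, shape (n_mels, n_fft//2 + 1).

    Filters are triangles between mel-equally-spaced edge frequencies
    (HTK formula), normalized to unit area so overall energy level is
    comparable across bins.
    """
    edges_mel = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mels + 2)
    edges_hz = _mel_to_hz(edges_mel)
    fft_freqs = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate)
    fb = np.zeros((n_mels, len(fft_freqs)))
    for m in range(n_mels):
        lo, center, hi = edges_hz[m], edges_hz[m + 1], edges_hz[m + 2]
        rising = (fft_freqs - lo) / (center - lo)
        falling = (hi - fft_freqs) / (hi - center)
        fb[m] = np.maximum(0.0, np.minimum(rising, falling))
        area = fb[m].sum()
        if area > 0:
            fb[m] /= area
    return fb


def mel_filter_centers(
    n_mels: int = N_MELS, fmin: float = MEL_FMIN, fmax: float = MEL_FMAX
) -> np.ndarray:
    """Center frequency (Hz) of each mel filter."""
    edges_mel = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mels + 2)
    return _mel_to_hz(edges_mel)[1:-1]


_FILTERBANK_CACHE: dict[tuple, np.ndarray] = {}


def _cached_filterbank() -> np.ndarray:
    key = (N_MELS, N_FFT, TARGET_RATE, MEL_FMIN, MEL_FMAX)
    if key not in _FILTERBANK_CACHE:
        _FILTERBANK_CACHE[key] = mel_filterbank()
    return _FILTERBANK_CACHE[key]


def logmel_window(frame: np.ndarray, power: bool = False) -> np.ndarray:
    """Log-mel spectrogram of one 960 ms frame, shape (96, 64).

    STFT with a 25 ms periodic Hann window hopped every 10 ms (96 hops at
    sample offsets 0, 80, ..., 7600; windows overrunning the frame are
    zero-padded), magnitude (or power, if ``power=True``) integrated through
    the 64-bin mel filterbank, then ``ln(mel + 0.001)``.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.shape != (FRAME_SAMPLES,):
        raise ValueError(
            f"frame must have exactly {FRAME_SAMPLES} samples, got {frame.shape}"
        )
    # pad so the last hops have a full 200-sample window
    padded = np.pad(frame, (0, STFT_WINDOW))
    starts = np.arange(N_TIME_STEPS) * STFT_HOP
    idx = starts[:, None] + np.arange(STFT_WINDOW)[None, :]
    segments = padded[idx]
    window = np.hanning(STFT_WINDOW + 1)[:-1]  # periodic Hann
    spec = np.abs(np.fft.rfft(segments * window, n=N_FFT, axis=1))
    if power:
        spec = spec**2
    mel = spec @ _cached_filterbank().T
    return np.log(mel + LOG_OFFSET)


def logmel_windows(recording: VoiceRecording, power: bool = False) -> np.ndarray:
    """All context windows of a recording, shape (n_frames, 96, 64)."""
    frames = frame_audio(recording)
    if not frames:
        return np.empty((0, N_TIME_STEPS, N_MELS))
    return np.stack([logmel_window(f, power=power) for f in frames])
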
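"""Streaming, windowless log-Mel feature extraction with int8 quantization.

The edge node receives audio as 512-sample microphone buffers. To stay
real-time on a microcontroller it skips the usual analysis window entirely:
each new buffer is concatenated with the previous one into a 1024-sample
rectangular frame (hop 512 = 50% overlap) and transformed with a 1024-point
DFT. One second of audio (16000 samples = 31.25 buffers) therefore yields
exactly 32 frames — the stream starts from 512 zero samples of prehistory
and the final partial buffer is zero-padded — giving a 512x32 power
spectrogram. A 48-band HTK-mel triangular filterbank and a decibel
transform (referenced to the matrix maximum, floored at -80 dB) reduce this
to the 48x32 model input. Features can be affine-quantized to int8, cutting
per-second storage from 6144 to 1536 bytes.

Feature matrices are plain ``np.ndarray``: float32 ``(48, 32)`` for log-Mel,
``(512, 32)`` for power spectrograms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

N_FFT = 1024
HOP = 512
N_BINS = 512  # one-sided bins k = 0..511 (Nyquist bin dropped)
N_MELS = 48
N_FRAMES = 32
DB_FLOOR = 80.0  # dynamic range kept below the per-matrix maximum
_AMIN = 1e-10


def hop_spectrogram(samples: np.ndarray, pad: bool = True) -> np.ndarray:
    """Power spectrogram (512 bins x 32 frames) of one second of audio.

    Frames are rectangular (no window function): consecutive pairs of
    512-sample buffers. Frame 0 uses zeros as prehistory; the last hop is
    zero-padded. Shorter inputs are zero-padded at the tail when ``pad``.
    """
    x = np.asarray(samples, dtype=np.float64).ravel()
    if x.size > 16000:
        raise ValueError(f"expected at most 16000 samples, got {x.size}")
    if x.size < 16000 and not pad:
        raise ValueError(f"expected exactly 16000 samples, got {x.size} (padding disabled)")
    buf = np.zeros(HOP + N_FRAMES * HOP)  # 512 zeros of prehistory + 32 buffers
    buf[HOP : HOP + x.size] = x
    frames = np.lib.stride_tricks.sliding_window_view(buf, N_FFT)[::HOP][:N_FRAMES]
    spec = np.abs(np.fft.rfft(frames, n=N_FFT, axis=1)[:, :N_BINS]) ** 2
    return spec.T.astype(np.float32)  # (512, 32)


def hz_to_mel(f):
    """HTK mel scale: m = 2595 * log10(1 + f / 700)."""
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("frequency must be >= 0")
    return 2595.0 * np.log10(1.0 + f / 700.0)


def mel_to_hz(m):
    m = np.asarray(m, dtype=np.float64)
    return 700.0 * (10.0 ** (m / 2595.0) - 1.0)


def mel_filterbank(n_mels: int = N_MELS, sr: int = 16000, n_bins: int = N_BINS, n_fft: int = N_FFT) -> np.ndarray:
    """Triangular mel filterbank mapped onto the spectrogram bins.

    Centers are equally spaced on the HTK mel scale between 0 and sr/2;
    filters are area-normalized (each triangle weighted by 2 / bandwidth in
    Hz) so wide high-frequency filters do not dominate.
    """
    if n_mels < 1:
        raise ValueError("n_mels must be >= 1")
    mel_pts = np.linspace(hz_to_mel(0.0), hz_to_mel(sr / 2.0), n_mels + 2)
    f_pts = mel_to_hz(mel_pts)
    fft_freqs = np.arange(n_bins) * sr / n_fft
    fdiff = np.diff(f_pts)
    ramps = f_pts[:, None] - fft_freqs[None, :]
    lower = -ramps[:-2] / fdiff[:-1][:, None]
    upper = ramps[2:] / fdiff[1:][:, None]
    weights = np.maximum(0.0, np.minimum(lower, upper))
    weights *= (2.0 / (f_pts[2:] - f_pts[:-2]))[:, None]
    if np.any(weights.sum(axis=1) <= 0):
        raise ValueError(f"n_mels={n_mels} too large: some filters cover no spectrogram bin")
    return weights


def log_mel(spec: np.ndarray, filterbank: np.ndarray | None = None) -> np.ndarray:
    """dB-scaled mel spectrogram: 10*log10(filterbank @ spec), referenced to
    the matrix maximum and floored ``DB_FLOOR`` dB below it."""
    if filterbank is None:
        filterbank = mel_filterbank()
    m = filterbank @ np.asarray(spec, dtype=np.float64)
    ref = max(m.max(), _AMIN)
    db = 10.0 * np.log10(np.maximum(m, _AMIN)) - 10.0 * np.log10(ref)
    return np.maximum(db, db.max() - DB_FLOOR).astype(np.float32)


def extract(samples: np.ndarray, filterbank: np.ndarray | None = None) -> np.ndarray:
    """One-second waveform -> 48x32 log-Mel feature."""
    return log_mel(hop_spectrogram(samples), filterbank)


# ---------------------------------------------------------------------------
# int8 affine quantization: q = clamp(round(x / scale) + zero_point, -128, 127)
# ---------------------------------------------------------------------------


@dataclass
class QuantizedFeature:
    values: np.ndarray  # int8
    scale: float
    zero_point: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if not -128 <= self.zero_point <= 127:
            raise ValueError("zero_point must be in [-128, 127]")


def calibrate_quantization(features: Iterable[np.ndarray], epsilon: float = 1e-8) -> tuple[float, int]:
    """Pick (scale, zero_point) mapping the observed [min, max] onto [-128, 127].

    Calibration is global (over the whole collection), mirroring a fixed-scale
    deployment. The range is nudged to include zero — the usual deployment
    convention, which also guarantees the zero point is representable in
    int8. A degenerate collection (min == max) falls back to ``epsilon``.
    """
    lo, hi = np.inf, -np.inf
    n = 0
    for f in features:
        f = np.asarray(f)
        lo, hi = min(lo, float(f.min())), max(hi, float(f.max()))
        n += 1
    if n == 0:
        raise ValueError("calibration collection must be nonempty")
    lo, hi = min(lo, 0.0), max(hi, 0.0)
    scale = (hi - lo) / 255.0
    if scale <= 0:
        scale = epsilon
    zero_point = int(np.clip(round(-128 - lo / scale), -128, 127))
    return scale, zero_point


def quantize(feature: np.ndarray, scale: float, zero_point: int) -> QuantizedFeature:
    q = np.clip(np.round(np.asarray(feature, dtype=np.float64) / scale) + zero_point, -128, 127)
    return QuantizedFeature(q.astype(np.int8), scale, zero_point)


def dequantize(q: QuantizedFeature) -> np.ndarray:
    return (q.scale * (q.values.astype(np.float64) - q.zero_point)).astype(np.float32)
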
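"""Parametric synthesis of household activity sounds.

The recorded corpus this system is designed around cannot be shared, so this
module generates audio with the same *structure*: eleven activity sound
classes plus a background class, each with a distinct, stable spectral
fingerprint, and scripted multi-event sessions with exact ground truth.
Continuous textures (running water, brushing, appliance hum, speech) are
steady or slowly-modulated noise/harmonic mixtures; transient events
(hitting, flushing) are short bursts with characteristic envelopes.

All generation is driven by ``numpy.random.default_rng`` seeded from
``(seed, stream)`` pairs, so clips are bit-reproducible and adding an entry
to a session never perturbs the noise of other entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile
from scipy.signal import butter, sosfilt

SAMPLE_RATE = 16000

#: Canonical class list: the 11 activity labels plus "background".
LABELS = (
    "airutils",
    "background",
    "brushing",
    "cooking",
    "flushing",
    "hitting",
    "microwave",
    "peeing",
    "speech",
    "tv",
    "watering1",
    "watering2",
)

#: Transient event classes; everything else is a continuous texture.
INSTANT_LABELS = frozenset({"hitting", "flushing"})


@dataclass
class AudioClip:
    """Mono 16 kHz audio held as float32 amplitudes in [-1, 1]."""

    samples: np.ndarray
    rate: int = SAMPLE_RATE

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float32)
        if self.rate != SAMPLE_RATE:
            raise ValueError(f"rate must be {SAMPLE_RATE} Hz, got {self.rate}")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if np.max(np.abs(self.samples)) > 1.0 + 1e-6:
            raise ValueError("samples must lie in [-1, 1]")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


@dataclass
class ScriptEntry:
    label: str
    onset: float
    duration: float
    level_db: float = 0.0


@dataclass
class SessionScript:
    """Timed list of sound events over a background bed.

    ``noise_floor_db`` is the RMS level of the pink-noise bed in dB relative
    to full scale (``-np.inf`` disables the bed).
    """

    entries: list[ScriptEntry] = field(default_factory=list)
    noise_floor_db: float = -50.0
    total_duration: float = 10.0

    def validate(self, labels: tuple[str, ...] = LABELS) -> None:
        for e in self.entries:
            if e.label not in labels:
                raise ValueError(f"unknown label {e.label!r}; valid: {sorted(labels)}")
            if e.duration <= 0:
                raise ValueError(f"entry duration must be > 0 (got {e.duration})")
            if e.onset < 0 or e.onset + e.duration > self.total_duration + 1e-9:
                raise ValueError(
                    f"entry {e.label!r} [{e.onset}, {e.onset + e.duration}] "
                    f"exceeds total_duration {self.total_duration}"
                )


@dataclass
class GroundTruth:
    """Labelled (label, start, end) intervals mirroring a session script."""

    intervals: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for label, start, end in self.intervals:
            if not start < end:
                raise ValueError(f"interval for {label!r} must have start < end")


# ---------------------------------------------------------------------------
# signal building blocks
# ---------------------------------------------------------------------------


def _band_noise(rng: np.random.Generator, n: int, lo: float, hi: float) -> np.ndarray:
    sos = butter(4, [lo, hi], btype="bandpass", fs=SAMPLE_RATE, output="sos")
    return sosfilt(sos, rng.standard_normal(n)).astype(np.float64)


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    # 1/f spectral shaping of white noise in the frequency domain
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / SAMPLE_RATE)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    return np.fft.irfft(spec, n)


def _harmonics(n: int, f0: float, weights: list[float]) -> np.ndarray:
    t = np.arange(n) / SAMPLE_RATE
    out = np.zeros(n)
    for k, w in enumerate(weights, start=1):
        out += w * np.sin(2 * np.pi * f0 * k * t)
    return out


def _syllabic_envelope(rng: np.random.Generator, n: int, rate_hz: float = 4.0) -> np.ndarray:
    """Smoothed random on/off gating that mimics syllable rhythm."""
    seg = max(1, int(SAMPLE_RATE / rate_hz))
    n_seg = n // seg + 2
    gates = rng.uniform(0.05, 1.0, n_seg) * (rng.random(n_seg) > 0.25)
    env = np.repeat(gates, seg)[:n]
    # ~30 ms smoothing window removes the hard edges
    k = int(0.03 * SAMPLE_RATE)
    return np.convolve(env, np.ones(k) / k, mode="same")


def _voice(rng: np.random.Generator, n: int, f0: float) -> np.ndarray:
    """Formant-like tonal stack with slow pitch wobble, syllabically gated."""
    t = np.arange(n) / SAMPLE_RATE
    wobble = 1.0 + 0.03 * np.sin(2 * np.pi * rng.uniform(0.5, 2.0) * t + rng.uniform(0, 2 * np.pi))
    sig = np.zeros(n)
    for fc, w in [(f0, 1.0), (3.5 * f0, 0.6), (8.0 * f0, 0.35), (13.0 * f0, 0.2)]:
        phase = rng.uniform(0, 2 * np.pi)
        sig += w * np.sin(2 * np.pi * fc * np.cumsum(wobble) / SAMPLE_RATE + phase)
    return sig * _syllabic_envelope(rng, n)


def _edge_fade(x: np.ndarray, fade_s: float = 0.15) -> np.ndarray:
    """Raised-cosine onset/offset ramps: sounds do not start or stop in one
    sample, and a step edge would read as an impact transient."""
    k = min(int(fade_s * SAMPLE_RATE), x.size // 2)
    if k == 0:
        return x
    ramp = 0.5 - 0.5 * np.cos(np.pi * np.arange(k) / k)
    x = x.copy()
    x[:k] *= ramp
    x[-k:] *= ramp[::-1]
    return x


def _rms_normalize(x: np.ndarray, target: float) -> np.ndarray:
    rms = np.sqrt(np.mean(x**2))
    if rms < 1e-12:
        return x
    return x * (target / rms)


# ---------------------------------------------------------------------------
# per-label recipes
# ---------------------------------------------------------------------------


def _recipe(label: str, rng: np.random.Generator, n: int) -> np.ndarray:
    t = np.arange(n) / SAMPLE_RATE
    if label == "watering1":  # strong shower-like broadband rush
        return _rms_normalize(_band_noise(rng, n, 800, 6500), 0.10)
    if label == "watering2":  # gentler low-band flow
        return _rms_normalize(_band_noise(rng, n, 150, 1800), 0.10)
    if label == "brushing":
        mod = 0.55 + 0.45 * np.sin(2 * np.pi * 4.0 * t + rng.uniform(0, 2 * np.pi))
        return _rms_normalize(_band_noise(rng, n, 1000, 4200) * mod, 0.09)
    if label == "cooking":  # oil crackle over a hiss bed
        hiss = 0.6 * _band_noise(rng, n, 2000, 7200)
        spikes = np.zeros(n)
        idx = np.flatnonzero(rng.random(n) < 25.0 / SAMPLE_RATE)
        spikes[idx] = rng.uniform(2.0, 6.0, idx.size) * rng.choice([-1, 1], idx.size)
        decay = np.exp(-np.arange(int(0.004 * SAMPLE_RATE)) / (0.001 * SAMPLE_RATE))
        crackle = np.convolve(spikes, decay)[:n]
        return _rms_normalize(hiss + crackle, 0.09)
    if label == "microwave":
        hum = _harmonics(n, 60.0, [1.0, 0.6, 0.3, 0.15])
        fan = 0.45 * _rms_normalize(_band_noise(rng, n, 200, 900), 1.0)
        return _rms_normalize(hum + fan, 0.09)
    if label == "airutils":  # ventilation fan / vacuum family
        hum = _harmonics(n, 50.0, [0.5, 0.35, 0.25])
        fan = 1.1 * _rms_normalize(_band_noise(rng, n, 300, 2600), 1.0)
        return _rms_normalize(hum + fan, 0.09)
    if label == "speech":
        return _rms_normalize(_voice(rng, n, 180.0), 0.09)
    if label == "tv":  # voice plus steady music-band chord and wide bed
        chord = sum(np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi)) for f in (262.0, 330.0, 392.0, 523.0))
        bed = 0.25 * _rms_normalize(_band_noise(rng, n, 100, 5000), 1.0)
        return _rms_normalize(0.8 * _voice(rng, n, 140.0) + 0.5 * chord + bed, 0.09)
    if label == "peeing":  # narrow trickle band, slight slow modulation
        mod = 0.8 + 0.2 * np.sin(2 * np.pi * 1.7 * t + rng.uniform(0, 2 * np.pi))
        return _rms_normalize(_band_noise(rng, n, 1800, 3200) * mod, 0.08)
    if label == "hitting":  # single impact: decaying broadband burst, zero elsewhere
        n_t = min(int(0.3 * SAMPLE_RATE), n)
        burst = rng.standard_normal(n_t) * np.exp(-np.arange(n_t) / (0.04 * SAMPLE_RATE))
        burst = _rms_normalize(burst, 0.22)
        out = np.zeros(n)
        offset = int(rng.integers(0, n - n_t + 1))
        out[offset : offset + n_t] = burst
        return out
    if label == "flushing":  # rise-sustain-fall low gurgling rush
        n_e = min(n, int(3.0 * SAMPLE_RATE))
        env = np.ones(n_e)
        n_rise, n_fall = int(0.15 * n_e), int(0.25 * n_e)
        if n_rise:
            env[:n_rise] = np.linspace(0, 1, n_rise)
        if n_fall:
            env[-n_fall:] = np.linspace(1, 0, n_fall)
        te = np.arange(n_e) / SAMPLE_RATE
        gurgle = 0.55 + 0.45 * np.sin(2 * np.pi * rng.uniform(9.0, 13.0) * te + rng.uniform(0, 2 * np.pi))
        rush = _band_noise(rng, n_e, 250, 1400) * gurgle + 0.8 * _band_noise(rng, n_e, 60, 300)
        out = np.zeros(n)
        out[:n_e] = _rms_normalize(rush, 0.10) * env
        return out
    if label == "background":
        return _rms_normalize(_pink_noise(rng, n), 0.01)
    raise ValueError(f"unknown label {label!r}; valid: {sorted(LABELS)}")


def synth_clip(label: str, duration_s: float, seed: int, level_db: float = 0.0) -> AudioClip:
    """Render one seeded clip of ``label``.

    ``level_db`` is a relative gain applied after the recipe's nominal level.
    Output is deterministic given ``(label, duration_s, seed, level_db)``.
    """
    if label not in LABELS:
        raise ValueError(f"unknown label {label!r}; valid: {sorted(LABELS)}")
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    n = int(round(duration_s * SAMPLE_RATE))
    rng = np.random.default_rng([seed, LABELS.index(label)])
    x = _recipe(label, rng, n) * 10.0 ** (level_db / 20.0)
    if label not in ("hitting", "background"):
        x = _edge_fade(x)
    peak = np.max(np.abs(x))
    if peak > 1.0:
        x = x / peak
    return AudioClip(x.astype(np.float32))


def synth_session(script: SessionScript, seed: int) -> tuple[AudioClip, GroundTruth]:
    """Render a scripted session: entries summed over a pink-noise bed.

    Overlapping entries add sample-wise; the mix is peak-normalized only if
    it exceeds full scale (preserving transient crest factors otherwise).
    Ground truth mirrors the script intervals exactly.
    """
    script.validate()
    n = int(round(script.total_duration * SAMPLE_RATE))
    mix = np.zeros(n)
    if np.isfinite(script.noise_floor_db):
        bed_rng = np.random.default_rng([seed, 0x7FFFFFFF])
        mix += _rms_normalize(_pink_noise(bed_rng, n), 10.0 ** (script.noise_floor_db / 20.0))
    for i, e in enumerate(script.entries):
        clip = synth_clip(e.label, e.duration, _entry_seed(seed, i), e.level_db)
        a = int(round(e.onset * SAMPLE_RATE))
        seg = clip.samples[: n - a]
        mix[a : a + seg.size] += seg
    peak = np.max(np.abs(mix)) if n else 0.0
    if peak > 1.0:
        mix /= peak
    truth = GroundTruth([(e.label, e.onset, e.onset + e.duration) for e in script.entries])
    return AudioClip(mix.astype(np.float32)), truth


def _entry_seed(master: int, index: int) -> int:
    # independent per-entry streams: adding entry k never changes entries < k
    return int(np.random.default_rng([master, index]).integers(0, 2**31 - 1))


def generate_pool(
    labels: tuple[str, ...] = LABELS,
    n_per_label: int = 100,
    seed: int = 0,
    duration_s: float = 1.0,
    snr_db: tuple[float, float] = (15.0, 25.0),
) -> dict[str, list[AudioClip]]:
    """Labelled clip pool for training/evaluation.

    Each clip carries a low pink-noise bed at an SNR drawn uniformly from
    ``snr_db``, emulating the residual room noise of real recordings
    ("background" clips are the bed alone). For continuous textures, 20% of
    clips carry the sound over only part of the window (0.4-0.9 s at a
    random offset): one-second segmentation of real recordings inevitably
    produces such boundary clips where the activity starts or stops
    mid-window, and they still carry that activity's label.
    """
    rng = np.random.default_rng([seed, 0x5EED])
    pool: dict[str, list[AudioClip]] = {}
    for label in labels:
        clips = []
        for i in range(n_per_label):
            clip_seed = int(rng.integers(0, 2**31 - 1))
            if label not in ("background", "hitting") and rng.random() < 0.2:
                dur = rng.uniform(0.4, 0.9)
                part = synth_clip(label, dur, clip_seed)
                x0 = np.zeros(int(round(duration_s * SAMPLE_RATE)), dtype=np.float32)
                off = int(rng.integers(0, x0.size - part.samples.size + 1))
                x0[off : off + part.samples.size] = part.samples
                clip = AudioClip(x0)
            else:
                clip = synth_clip(label, duration_s, clip_seed)
            x = clip.samples.astype(np.float64)
            if label != "background":
                snr = rng.uniform(*snr_db)
                bed = _pink_noise(np.random.default_rng([clip_seed, 0xBED]), x.size)
                sig_rms = max(np.sqrt(np.mean(x**2)), 1e-12)
                x = x + _rms_normalize(bed, sig_rms * 10.0 ** (-snr / 20.0))
                peak = np.max(np.abs(x))
                if peak > 1.0:
                    x /= peak
            clips.append(AudioClip(x.astype(np.float32)))
        pool[label] = clips
    return pool


# ---------------------------------------------------------------------------
# WAV I/O (RIFF PCM16 mono 16 kHz only — no silent conversion)
# ---------------------------------------------------------------------------


def write_wav(clip: AudioClip, path) -> None:
    """Write 16-bit PCM mono WAV; full-scale 1.0 maps to 32767 (no overflow)."""
    pcm = np.clip(np.round(clip.samples.astype(np.float64) * 32767.0), -32768, 32767)
    wavfile.write(path, SAMPLE_RATE, pcm.astype(np.int16))


def read_wav(path) -> AudioClip:
    """Read a 16 kHz mono PCM16 WAV; anything else is rejected, not resampled."""
    rate, data = wavfile.read(path)
    if rate != SAMPLE_RATE:
        raise ValueError(f"expected {SAMPLE_RATE} Hz WAV, got {rate} Hz: {path}")
    if data.ndim != 1:
        raise ValueError(f"expected mono WAV, got {data.ndim} channels: {path}")
    if data.dtype != np.int16:
        raise ValueError(f"expected 16-bit PCM WAV, got {data.dtype}: {path}")
    return AudioClip(np.clip(data / 32767.0, -1.0, 1.0).astype(np.float32))
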
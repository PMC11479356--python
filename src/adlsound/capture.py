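"""Software twin of the edge node's event-driven wake/sleep capture.

The hardware node sleeps until the microphone's 512-sample buffer carries
enough energy, then records until the signal stays quiet for a few seconds.
Here the same automaton runs over in-memory clips: mean-absolute frame
energy, a wake threshold, and a consecutive-silence stop condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth import SAMPLE_RATE, AudioClip

FRAME_LEN = 512  # microphone buffer granularity (samples)


@dataclass
class Segment:
    """Contiguous active run of a source clip, at frame granularity."""

    start_sample: int
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.start_sample < 0 or self.samples.size == 0:
            raise ValueError("segment must have start_sample >= 0 and length > 0")

    @property
    def start_time(self) -> float:
        return self.start_sample / SAMPLE_RATE


def frame_energy(frame: np.ndarray) -> float:
    """Mean absolute amplitude of one 512-sample frame: (sum |x_n|) / N."""
    frame = np.asarray(frame)
    if frame.shape != (FRAME_LEN,):
        raise ValueError(f"frame must have exactly {FRAME_LEN} samples, got {frame.shape}")
    return float(np.mean(np.abs(frame)))


def gate_stream(
    clip: AudioClip,
    wake_threshold: float = 0.01,
    stop_silence_s: float = 5.0,
) -> list[Segment]:
    """Segment a clip into active runs, emulating wake/sleep gating.

    Scans 512-sample frames in order. A segment opens at the first frame with
    energy >= ``wake_threshold`` and closes once ``stop_silence_s`` worth of
    consecutive sub-threshold frames accumulate; that trailing silence is
    trimmed from the emitted segment. A partial final frame is dropped
    (hardware only ever delivers whole buffers). Silent clips yield [].
    """
    if wake_threshold <= 0:
        raise ValueError("wake_threshold must be > 0")
    x = clip.samples
    n_frames = x.size // FRAME_LEN
    silence_frames_limit = int(np.ceil(stop_silence_s * SAMPLE_RATE / FRAME_LEN))

    segments: list[Segment] = []
    open_start = -1  # frame index where the current segment opened
    last_active = -1  # last supra-threshold frame of the current segment
    quiet = 0
    for i in range(n_frames):
        e = frame_energy(x[i * FRAME_LEN : (i + 1) * FRAME_LEN])
        if e >= wake_threshold:
            if open_start < 0:
                open_start = i
            last_active = i
            quiet = 0
        elif open_start >= 0:
            quiet += 1
            if quiet >= silence_frames_limit:
                segments.append(_emit(x, open_start, last_active))
                open_start, last_active, quiet = -1, -1, 0
    if open_start >= 0:
        segments.append(_emit(x, open_start, last_active))
    return segments


def _emit(x: np.ndarray, first_frame: int, last_frame: int) -> Segment:
    a = first_frame * FRAME_LEN
    b = (last_frame + 1) * FRAME_LEN
    return Segment(start_sample=a, samples=x[a:b])
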
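"""Vote-based temporal smoothing and activity-log assembly.

A 1-second classifier run every 0.5 s produces a noisy stream of per-frame
probability vectors: single misclassified frames fragment long activities
and transient sounds appear only once. Smoothing works on a sliding buffer
of 7 frames (3.5 s), sliding by one frame:

* per label, frames with probability above a threshold are counted;
* a *continuous* label "occurs" in a window when the count exceeds half the
  buffer (strict majority), with confidence = mean probability over the
  whole buffer;
* an *instant* label occurs on any single supra-threshold frame, with
  confidence = mean of only the supra-threshold probabilities. Each frame
  can trigger an instant label once — it is credited to the first window
  containing it and suppressed in the 6 later windows that overlap it.

Labels are judged independently, so overlapping sounds (water running while
dishes clang) each produce their own event stream. Per-label event streams
are then folded into activities: an activity opens at the first occurred
window, a per-label *tolerance* counter absorbs short dropouts (decremented
on every non-occurred window, reset on occurrence), and the activity closes
— with exact duration and mean confidence — once the counter goes negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synth import INSTANT_LABELS, LABELS


@dataclass
class PredictionFrame:
    """Class-probability vector for one 1 s frame; ``time`` is the frame center."""

    time: float
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if abs(self.probs.sum() - 1.0) > 1e-6:
            raise ValueError("probabilities must sum to 1")


@dataclass
class PostConfig:
    labels: tuple[str, ...] = LABELS
    threshold: float = 0.5
    window_size: int = 7
    frame_hop_s: float = 0.5
    tolerance_continuous: int = 10  # windows; 10 * 0.5 s = 5 s
    tolerance_instant: int = 4
    min_duration: float = 0.5
    min_confidence: float = 0.0
    instant_labels: frozenset[str] = frozenset(INSTANT_LABELS)
    per_label_threshold: dict = field(default_factory=dict)
    per_label_tolerance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.window_size < 3 or self.window_size % 2 == 0:
            raise ValueError("window_size must be odd and >= 3")
        if self.tolerance_continuous < 0 or self.tolerance_instant < 0:
            raise ValueError("tolerances must be >= 0")

    def kind(self, label: str) -> str:
        return "instant" if label in self.instant_labels else "continuous"

    def label_threshold(self, label: str) -> float:
        return self.per_label_threshold.get(label, self.threshold)

    def label_tolerance(self, label: str) -> int:
        if label in self.per_label_tolerance:
            return self.per_label_tolerance[label]
        return self.tolerance_instant if label in self.instant_labels else self.tolerance_continuous


@dataclass
class VoteWindow:
    frames: list[PredictionFrame]
    start_index: int  # stream index of the oldest frame

    @property
    def time(self) -> float:
        return self.frames[-1].time


@dataclass
class EventRecord:
    label: str
    occurred: bool
    confidence: float
    window_time: float
    kind: str


@dataclass
class ActivityRecord:
    label: str
    start_time: float
    end_time: float
    duration: float
    location: str
    confidence: float


def stream_windows(predictions: list[PredictionFrame], window_size: int = 7, hop_s: float = 0.5) -> list[VoteWindow]:
    """Sliding windows over a time-ordered prediction stream.

    The first window is emitted once ``window_size`` frames have arrived,
    then one per frame: n frames yield max(0, n - window_size + 1) windows.
    """
    for a, b in zip(predictions, predictions[1:]):
        if b.time <= a.time:
            raise ValueError(f"prediction frames out of order at t={b.time}")
        if abs((b.time - a.time) - hop_s) > 1e-6:
            raise ValueError(f"expected {hop_s} s frame spacing, got {b.time - a.time:.6f}")
    return [
        VoteWindow(predictions[i : i + window_size], i)
        for i in range(len(predictions) - window_size + 1)
    ]


def vote(window: VoteWindow, config: PostConfig) -> list[EventRecord]:
    """Per-label occurrence decisions for one full window (labels independent)."""
    out = []
    for li, label in enumerate(config.labels):
        p = np.array([f.probs[li] for f in window.frames])
        thr = config.label_threshold(label)
        supra = p > thr
        count = int(supra.sum())
        if config.kind(label) == "continuous":
            occurred = count > config.window_size / 2  # strict majority
            confidence = float(p.mean())
        else:
            occurred = count >= 1
            confidence = float(p[supra].mean()) if count else 0.0
        out.append(EventRecord(label, occurred, confidence, window.time, config.kind(label)))
    return out


def smooth_stream(predictions: list[PredictionFrame], config: PostConfig) -> list[EventRecord]:
    """Vote over all windows of a stream, with instant-event frame dedup.

    A supra-threshold frame appears in up to ``window_size`` overlapping
    windows; an instant occurrence is attributed once, at the first window
    containing that frame, and suppressed afterwards.
    """
    events: list[EventRecord] = []
    credited: dict[str, set[int]] = {l: set() for l in config.labels}
    for window in stream_windows(predictions, config.window_size, config.frame_hop_s):
        for li, ev in enumerate(vote(window, config)):
            if ev.kind == "instant" and ev.occurred:
                thr = config.label_threshold(ev.label)
                supra_idx = [
                    (window.start_index + j, f.probs[li])
                    for j, f in enumerate(window.frames)
                    if f.probs[li] > thr
                ]
                fresh = [(i, p) for i, p in supra_idx if i not in credited[ev.label]]
                if fresh:
                    credited[ev.label].update(i for i, _ in fresh)
                    ev = EventRecord(
                        ev.label, True, float(np.mean([p for _, p in fresh])), ev.window_time, ev.kind
                    )
                else:
                    ev = EventRecord(ev.label, False, 0.0, ev.window_time, ev.kind)
            events.append(ev)
    return events


def accumulate(events: list[EventRecord], config: PostConfig, location: str = "") -> list[ActivityRecord]:
    """Fold a time-ordered event stream into activity records.

    Per label: open on the first occurred event, reset the tolerance counter
    on every occurrence, decrement it on every non-occurred window, close
    when it goes below zero (end time = last occurred window). The stream
    end flushes open activities.
    """
    state: dict[str, dict] = {}
    out: list[ActivityRecord] = []

    def close(label: str) -> None:
        s = state.pop(label)
        out.append(
            ActivityRecord(
                label=label,
                start_time=s["start"],
                end_time=s["last"],
                duration=s["last"] - s["start"],
                location=location,
                confidence=s["sum_conf"] / s["count"],
            )
        )

    for ev in events:
        s = state.get(ev.label)
        if ev.occurred:
            if s is None:
                s = state[ev.label] = {
                    "start": ev.window_time,
                    "last": ev.window_time,
                    "count": 0,
                    "sum_conf": 0.0,
                    "tol": config.label_tolerance(ev.label),
                }
            s["tol"] = config.label_tolerance(ev.label)
            s["last"] = ev.window_time
            s["count"] += 1
            s["sum_conf"] += ev.confidence
        elif s is not None:
            s["tol"] -= 1
            if s["tol"] < 0:
                close(ev.label)
    for label in sorted(state):
        close(label)
    out.sort(key=lambda r: (r.start_time, r.label))
    return out


def filter_logs(
    records: list[ActivityRecord],
    config: PostConfig,
    allowed_labels=None,
) -> list[ActivityRecord]:
    """Drop too-short, low-confidence, or location-impossible activities."""
    allowed = None if allowed_labels is None else set(allowed_labels)
    return [
        r
        for r in records
        if r.duration >= config.min_duration
        and r.confidence >= config.min_confidence
        and (allowed is None or r.label in allowed)
    ]


def process_stream(
    predictions: list[PredictionFrame],
    config: PostConfig,
    location: str = "",
    allowed_labels=None,
) -> list[ActivityRecord]:
    """Full post-processing chain: vote -> accumulate -> filter."""
    events = smooth_stream(predictions, config)
    return filter_logs(accumulate(events, config, location), config, allowed_labels)
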
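"""Multi-node orchestration: per-node pipeline, log merging, log scoring.

A node is the software twin of one edge device: it gates a recording into
active segments, extracts 48x32 log-Mel features for overlapping 1 s frames
(0.5 s hop), classifies each frame (float or emulated int8 path), and
post-processes the prediction stream into location-tagged activity records.
Voting buffers never straddle gated silence — each active segment is
post-processed independently, which is safe because any gap long enough to
close the gate also exceeds the continuous-event tolerance.

The hub side is plain data plumbing: chronological merging of per-node logs
and event-level scoring against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import features as F
from .capture import gate_stream
from .postprocess import ActivityRecord, PostConfig, PredictionFrame, process_stream
from .synth import SAMPLE_RATE, AudioClip, GroundTruth, read_wav

#: Labels that a given room cannot physically produce (editable via config).
DEFAULT_EXCLUSIONS: dict[str, tuple[str, ...]] = {
    "bathroom": ("tv", "microwave", "cooking"),
    "kitchen": (),
    "livingroom": ("flushing", "peeing"),
}


@dataclass
class NodeConfig:
    name: str = "node0"
    location: str = "bathroom"
    allowed_labels: tuple[str, ...] | None = None  # None -> all minus exclusions
    wake_threshold: float = 0.01
    stop_silence_s: float = 5.0
    use_quantized: bool = False
    post: PostConfig = field(default_factory=PostConfig)
    exclusions: dict[str, tuple[str, ...]] | None = None  # None -> DEFAULT_EXCLUSIONS

    def __post_init__(self) -> None:
        if not self.location:
            raise ValueError("location must be nonempty")
        if self.allowed_labels is not None:
            bad = set(self.allowed_labels) - set(self.post.labels)
            if bad:
                raise ValueError(f"allowed_labels not in class list: {sorted(bad)}")

    def effective_allowed(self) -> tuple[str, ...]:
        if self.allowed_labels is not None:
            return tuple(self.allowed_labels)
        table = DEFAULT_EXCLUSIONS if self.exclusions is None else self.exclusions
        excluded = set(table.get(self.location, ()))
        return tuple(l for l in self.post.labels if l not in excluded)


def frame_stream(segment_samples: np.ndarray, start_sample: int, filterbank: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Overlapping 1 s feature frames (0.5 s hop) for one active segment.

    Returns ``(features (n, 48, 32), center_times (n,))`` with times in
    stream seconds. The tail is zero-padded to a whole hop.
    """
    hop = SAMPLE_RATE // 2
    n = segment_samples.size
    n_frames = max(1, int(np.ceil(max(n - SAMPLE_RATE, 0) / hop)) + 1)
    feats, times = [], []
    for i in range(n_frames):
        a = i * hop
        chunk = segment_samples[a : a + SAMPLE_RATE]
        feats.append(F.extract(chunk, filterbank))
        times.append((start_sample + a + SAMPLE_RATE // 2) / SAMPLE_RATE)
    return np.stack(feats), np.asarray(times)


def run_node(
    wav: AudioClip | str,
    node: NodeConfig,
    model,
    filterbank: np.ndarray | None = None,
) -> list[ActivityRecord]:
    """Full per-node pipeline over one recording.

    ``model`` is anything with ``predict_proba`` over (n, 48, 32) features
    ordered like ``node.post.labels`` (a trained float model or its
    quantized twin). Deterministic given the model and input.
    """
    if model is None:
        raise ValueError("a trained model is required")
    clip = read_wav(wav) if isinstance(wav, str) else wav
    if filterbank is None:
        filterbank = F.mel_filterbank()
    records: list[ActivityRecord] = []
    for seg in gate_stream(clip, node.wake_threshold, node.stop_silence_s):
        feats, times = frame_stream(seg.samples, seg.start_sample, filterbank)
        probs = model.predict_proba(feats)
        frames = [PredictionFrame(t, p) for t, p in zip(times, probs)]
        records.extend(
            process_stream(frames, node.post, node.location, node.effective_allowed())
        )
    records.sort(key=lambda r: (r.start_time, r.label))
    return records


# ---------------------------------------------------------------------------
# household log handling
# ---------------------------------------------------------------------------


def merge_logs(logs: list[list[ActivityRecord]]) -> list[ActivityRecord]:
    """Stable chronological merge of per-node logs.

    Sorted by start time; ties broken by (location, label) so merges are
    deterministic. The output is a permutation of the inputs.
    """
    merged = [r for log in logs for r in log]
    merged.sort(key=lambda r: (r.start_time, r.location, r.label))
    return merged


def score_log(
    log: list[ActivityRecord],
    truth: GroundTruth,
    overlap_fraction: float = 0.5,
) -> dict:
    """Event-level precision/recall/F1 with greedy one-to-one matching.

    A truth interval is detected when a same-label activity overlaps it by
    at least ``overlap_fraction`` of the truth duration; pairs are matched
    greedily by overlap, each activity and each truth interval at most once.
    """
    pairs = []
    for ti, (label, start, end) in enumerate(truth.intervals):
        need = overlap_fraction * (end - start)
        for ri, rec in enumerate(log):
            if rec.label != label:
                continue
            ov = min(end, rec.end_time) - max(start, rec.start_time)
            if ov >= need - 1e-12:
                pairs.append((ov, ti, ri))
    pairs.sort(key=lambda p: -p[0])
    used_t, used_r = set(), set()
    matched = 0
    for _, ti, ri in pairs:
        if ti not in used_t and ri not in used_r:
            used_t.add(ti)
            used_r.add(ri)
            matched += 1
    precision = matched / len(log) if log else (1.0 if not truth.intervals else 0.0)
    recall = matched / len(truth.intervals) if truth.intervals else 1.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {"precision": precision, "recall": recall, "f1": f1, "matched": matched}


# ---------------------------------------------------------------------------
# on-disk log formats (CSV and JSONL)
# ---------------------------------------------------------------------------

_COLUMNS = ["start", "end", "label", "duration", "location", "reliability"]


def log_to_frame(records: list[ActivityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.start_time, r.end_time, r.label, r.duration, r.location, r.confidence)
            for r in records
        ],
        columns=_COLUMNS,
    )


def write_log(records: list[ActivityRecord], path: str) -> None:
    path = str(path)
    df = log_to_frame(records)
    if path.endswith(".jsonl"):
        with open(path, "w") as fh:
            for row in df.to_dict(orient="records"):
                fh.write(json.dumps(row) + "\n")
    else:
        df.to_csv(path, index=False)


def read_log(path: str) -> list[ActivityRecord]:
    path = str(path)
    if path.endswith(".jsonl"):
        with open(path) as fh:
            df = pd.DataFrame([json.loads(line) for line in fh if line.strip()])
    else:
        df = pd.read_csv(path)
    return [
        ActivityRecord(
            label=row.label,
            start_time=float(row.start),
            end_time=float(row.end),
            duration=float(row.duration),
            location=str(row.location),
            confidence=float(row.reliability),
        )
        for row in df.itertuples()
    ]
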
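"""Balanced, augmented training-set construction.

Real activity recordings are heavily imbalanced (hundreds of flushes vs.
thousands of seconds of TV), so training pools are rebalanced per label:
base-pool clips are resampled to 1500 per label and site-specific "domain"
clips to 250 per label, then every clip receives two masked-augmentation
copies (random contiguous time-frame and mel-band regions set to the dB
floor). A label covered by both pools therefore contributes
(1500 + 250) * 3 = 5250 rows; a base-only label contributes 4500.

Oversampling duplicates clips *before* augmentation, so repeated originals
are diversified by independent masks. Train/test splitting happens at the
source-clip level, before any balancing, so an original and its repeats or
masked copies never straddle the split.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from . import features as F
from .synth import INSTANT_LABELS, SAMPLE_RATE, AudioClip

BALANCE_TARGET = 1500
DOMAIN_TARGET = 250
N_AUGMENT = 2


def event_type(label: str) -> str:
    return "instant" if label in INSTANT_LABELS else "continuous"


@dataclass
class LabeledClip:
    """One training atom: a 48x32 log-Mel feature with its provenance."""

    feature: np.ndarray
    label: str
    event_type: Literal["continuous", "instant"]
    origin: Literal["base", "domain"] = "base"
    source_id: int = -1  # identifies the originating recording/segment


def segment_continuous(clip: AudioClip, label: str) -> list[AudioClip]:
    """Cut a continuous recording into non-overlapping 1 s clips.

    The trailing remainder shorter than 1 s is dropped. Clips shorter than
    1 s belong in :func:`pad_short_event` instead.
    """
    n = clip.samples.size
    if n < SAMPLE_RATE:
        raise ValueError(f"clip shorter than 1 s ({n} samples): use pad_short_event")
    return [
        AudioClip(clip.samples[i * SAMPLE_RATE : (i + 1) * SAMPLE_RATE])
        for i in range(n // SAMPLE_RATE)
    ]


def pad_short_event(clip: AudioClip, label: str, seed: int = 0) -> AudioClip:
    """Place a sub-second event at a seeded random offset in a 1 s zero buffer.

    Short events yield exactly one training clip per occurrence; the random
    placement keeps the model from keying on absolute position.
    """
    n = clip.samples.size
    if n >= SAMPLE_RATE:
        raise ValueError(f"clip is >= 1 s ({n} samples): use segment_continuous")
    rng = np.random.default_rng(seed)
    out = np.zeros(SAMPLE_RATE, dtype=np.float32)
    offset = int(rng.integers(0, SAMPLE_RATE - n + 1))
    out[offset : offset + n] = clip.samples
    return AudioClip(out)


def balance_label(clips: list, target: int = BALANCE_TARGET, seed: int = 0) -> list:
    """Resample one label's clip list to exactly ``target`` items.

    Under-represented labels are oversampled by whole-set repetition plus a
    seeded remainder draw without replacement (each original appears
    floor(target/n) or ceil(target/n) times); over-represented labels are
    subsampled without replacement. Items are returned by reference.
    """
    n = len(clips)
    if n == 0:
        raise ValueError("cannot balance an empty label")
    rng = np.random.default_rng(seed)
    if n == target:
        return list(clips)
    if n > target:
        idx = rng.choice(n, size=target, replace=False)
        return [clips[i] for i in idx]
    reps, rem = divmod(target, n)
    out = list(clips) * reps
    out.extend(clips[i] for i in rng.choice(n, size=rem, replace=False))
    return out


def augment_mask(
    feature: np.ndarray,
    seed: int,
    n_copies: int = N_AUGMENT,
    max_time_width: int = 8,
    max_mel_width: int = 8,
    floor: float | None = None,
) -> list[np.ndarray]:
    """Masked copies of a log-Mel feature (the original is untouched).

    Each copy independently erases 1-2 contiguous time-frame bands and 1-2
    contiguous mel bands down to the dB floor, removing random
    time/frequency information the way occlusion and overlap do in real
    rooms. Band widths total at most ``max_time_width`` frames and
    ``max_mel_width`` mel bands per copy, so the altered fraction is bounded
    by (8*48 + 8*32) / (48*32) cells.
    """
    feature = np.asarray(feature)
    n_mels, n_frames = feature.shape
    if floor is None:
        floor = float(feature.max() - F.DB_FLOOR)
    rng = np.random.default_rng(seed)

    def band_widths(budget: int) -> list[int]:
        if int(rng.integers(1, 3)) == 1:
            return [int(rng.integers(1, budget + 1))]
        w1 = int(rng.integers(1, budget))
        return [w1, int(rng.integers(1, budget - w1 + 1))]

    out = []
    for _ in range(n_copies):
        for _attempt in range(8):  # re-draw if the mask hit an already-floored region
            masked = feature.copy()
            for w in band_widths(max_time_width):
                t0 = int(rng.integers(0, n_frames - w + 1))
                masked[:, t0 : t0 + w] = floor
            for h in band_widths(max_mel_width):
                m0 = int(rng.integers(0, n_mels - h + 1))
                masked[m0 : m0 + h, :] = floor
            if not np.array_equal(masked, feature):
                break
        out.append(masked)
    return out


def build_training_set(
    base: dict[str, list[np.ndarray]],
    domain: dict[str, list[np.ndarray]] | None = None,
    seed: int = 0,
    balance_target: int = BALANCE_TARGET,
    domain_target: int = DOMAIN_TARGET,
    n_augment: int = N_AUGMENT,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Balanced, augmented training arrays from per-label feature pools.

    Per label: ``balance_target`` base clips plus ``domain_target`` domain
    clips (0 if the label is absent from the domain pool, which is normal —
    a bathroom node never hears a microwave), each expanded with
    ``n_augment`` masked copies.

    Returns ``(manifest, X, y)``: a manifest DataFrame with columns
    (id, label, event_type, origin, aug), a float32 feature array
    ``(N, 48, 32)`` and an integer label array indexing into the sorted
    label list.
    """
    domain = domain or {}
    labels = sorted(base)
    missing = [l for l in labels if len(base[l]) == 0]
    if missing:
        raise ValueError(f"labels missing from base pool: {missing}")
    rng = np.random.default_rng(seed)
    rows, feats, ys = [], [], []
    for yi, label in enumerate(labels):
        chosen = [
            ("base", f)
            for f in balance_label(base[label], balance_target, seed=int(rng.integers(2**31)))
        ]
        if domain.get(label):
            chosen += [
                ("domain", f)
                for f in balance_label(domain[label], domain_target, seed=int(rng.integers(2**31)))
            ]
        for origin, feat in chosen:
            variants = [("orig", np.asarray(feat))]
            masked = augment_mask(feat, seed=int(rng.integers(2**31)), n_copies=n_augment)
            variants += [(f"mask{j}", m) for j, m in enumerate(masked)]
            for tag, v in variants:
                rows.append((len(rows), label, event_type(label), origin, tag))
                feats.append(v.astype(np.float32))
                ys.append(yi)
    manifest = pd.DataFrame(rows, columns=["id", "label", "event_type", "origin", "aug"])
    return manifest, np.stack(feats), np.asarray(ys, dtype=np.int64)


def split_pool(
    pool: dict[str, list],
    test_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[dict[str, list], dict[str, list]]:
    """Stratified source-level train/test split of a per-label pool."""
    rng = np.random.default_rng(seed)
    train, test = {}, {}
    for label in sorted(pool):
        items = pool[label]
        idx = rng.permutation(len(items))
        n_test = int(round(len(items) * test_fraction))
        test[label] = [items[i] for i in idx[:n_test]]
        train[label] = [items[i] for i in idx[n_test:]]
    return train, test
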
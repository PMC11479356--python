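"""Voting, tolerance accumulation and log filtering.

The vote operation is checked against a brute-force re-count oracle; the
accumulator against hand-traced merge/split cases; smoothing against a
flip-noise recovery experiment.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adlsound.postprocess import (
    ActivityRecord,
    EventRecord,
    PostConfig,
    PredictionFrame,
    VoteWindow,
    accumulate,
    filter_logs,
    smooth_stream,
    stream_windows,
    vote,
)

TWO = ("water", "hit")  # minimal continuous + instant label pair


def _cfg(**kw):
    kw.setdefault("labels", TWO)
    kw.setdefault("instant_labels", frozenset({"hit"}))
    return PostConfig(**kw)


def _frames(prob_rows, t0=0.0):
    out = []
    for i, row in enumerate(prob_rows):
        row = np.asarray(row, dtype=float)
        rest = (1.0 - row.sum()) if row.sum() < 1 else 0.0
        out.append(PredictionFrame(t0 + 0.5 * i, np.append(row, rest)))
    return out


def _window(cont_probs, inst_probs=None):
    inst = inst_probs if inst_probs is not None else [0.0] * len(cont_probs)
    frames = _frames([[c, h] for c, h in zip(cont_probs, inst)])
    return VoteWindow(frames, 0)


class TestStreamWindows:
    @pytest.mark.parametrize("n,expected", [(7, 1), (20, 14), (6, 0), (0, 0)])
    def test_window_count_is_n_minus_6(self, n, expected):
        frames = _frames([[0.5, 0.1]] * n)
        assert len(stream_windows(frames)) == expected

    def test_out_of_order_rejected(self):
        frames = _frames([[0.5, 0.1]] * 7)
        frames[3] = PredictionFrame(0.2, frames[3].probs)
        with pytest.raises(ValueError, match="order|spacing"):
            stream_windows(frames)


class TestVote:
    def test_continuous_majority_and_whole_buffer_confidence(self):
        ev = vote(_window([0.9, 0.9, 0.9, 0.9, 0.9, 0.1, 0.1]), _cfg())[0]
        assert ev.occurred  # 5 of 7 above 0.5 beats the strict majority of 3.5
        assert ev.confidence == pytest.approx((5 * 0.9 + 2 * 0.1) / 7)

    def test_continuous_minority_fails_strict_majority(self):
        ev = vote(_window([0.9, 0.9, 0.9, 0.1, 0.1, 0.1, 0.1]), _cfg())[0]
        assert not ev.occurred  # 3 <= 3.5

    def test_instant_single_frame_with_supra_threshold_confidence(self):
        ev = vote(_window([0.0] * 7, [0.0, 0.0, 0.8, 0.0, 0.0, 0.0, 0.0]), _cfg())[1]
        assert ev.occurred
        assert ev.confidence == pytest.approx(0.8)

    def test_labels_judged_independently(self):
        cont = [0.9, 0.3, 0.9, 0.9, 0.9, 0.9, 0.9]
        inst = [0.0, 0.6, 0.0, 0.0, 0.0, 0.0, 0.0]  # clang during running water
        evs = vote(_window(cont, inst), _cfg())
        assert evs[0].occurred and evs[1].occurred

    def test_matches_brute_force_oracle(self):
        """Exact agreement with an explicit re-count loop on 300 random windows."""
        cfg = _cfg()
        rng = np.random.default_rng(42)
        for _ in range(300):
            p = rng.random((7, 2)) * 0.5
            frames = [PredictionFrame(0.5 * i, np.append(r, 1 - r.sum())) for i, r in enumerate(p)]
            got = vote(VoteWindow(frames, 0), cfg)
            for li, label in enumerate(TWO):
                count = 0
                total = 0.0
                supra = []
                for f in frames:
                    total += f.probs[li]
                    if f.probs[li] > cfg.threshold:
                        count += 1
                        supra.append(f.probs[li])
                if label == "water":
                    occ = count > 3.5
                    conf = total / 7
                else:
                    occ = count >= 1
                    conf = sum(supra) / len(supra) if supra else 0.0
                assert got[li].occurred == occ
                assert got[li].confidence == pytest.approx(conf, abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000), thr_lo=st.floats(0.1, 0.5), delta=st.floats(0.01, 0.4))
    def test_raising_threshold_never_turns_occurrence_on(self, seed, thr_lo, delta):
        p = np.random.default_rng(seed).random((7, 2)) * 0.5
        frames = [PredictionFrame(0.5 * i, np.append(r, 1 - r.sum())) for i, r in enumerate(p)]
        low = vote(VoteWindow(frames, 0), _cfg(threshold=thr_lo))
        high = vote(VoteWindow(frames, 0), _cfg(threshold=thr_lo + delta))
        for lo_ev, hi_ev in zip(low, high):
            if hi_ev.kind == "continuous":
                assert not (hi_ev.occurred and not lo_ev.occurred)


class TestInstantDedup:
    def test_single_transient_credited_once_across_overlapping_windows(self):
        rows = [[0.0, 0.0]] * 20
        rows[9] = [0.0, 0.9]  # one supra-threshold instant frame
        events = smooth_stream(_frames(rows), _cfg())
        hits = [e for e in events if e.label == "hit" and e.occurred]
        assert len(hits) == 1
        assert hits[0].confidence == pytest.approx(0.9)


class TestAccumulate:
    def _events(self, flags, conf=0.9, label="water", kind="continuous", t0=3.0):
        return [
            EventRecord(label, bool(f), conf if f else 0.0, t0 + 0.5 * i, kind)
            for i, f in enumerate(flags)
        ]

    def test_uninterrupted_run_yields_one_activity_with_exact_duration(self):
        confs = np.linspace(0.6, 0.99, 20)
        events = [
            EventRecord("water", True, c, 3.0 + 0.5 * i, "continuous") for i, c in enumerate(confs)
        ]
        (act,) = accumulate(events, _cfg())
        assert act.start_time == 3.0
        assert act.end_time == pytest.approx(3.0 + 19 * 0.5)
        assert act.duration == pytest.approx(act.end_time - act.start_time)
        assert act.duration == pytest.approx(9.5)
        assert act.confidence == pytest.approx(confs.mean())

    def test_gap_shorter_than_tolerance_merges(self):
        flags = [1] * 10 + [0] * 8 + [1] * 10
        acts = accumulate(self._events(flags), _cfg(tolerance_continuous=10))
        assert len(acts) == 1

    def test_gap_longer_than_tolerance_splits(self):
        flags = [1] * 10 + [0] * 12 + [1] * 10
        acts = accumulate(self._events(flags), _cfg(tolerance_continuous=10))
        assert len(acts) == 2
        assert acts[0].end_time == pytest.approx(3.0 + 9 * 0.5)
        assert acts[1].start_time == pytest.approx(3.0 + 22 * 0.5)

    def test_stream_end_flushes_open_activity(self):
        acts = accumulate(self._events([1, 1, 1]), _cfg())
        assert len(acts) == 1

    def test_confidence_is_mean_of_occurred_events_only(self):
        flags = [1, 1, 0, 1]
        events = self._events(flags, conf=0.8)
        (act,) = accumulate(events, _cfg())
        assert act.confidence == pytest.approx(0.8)


class TestFilterLogs:
    def _rec(self, label="water", dur=5.0, conf=0.9, loc="bathroom"):
        return ActivityRecord(label, 10.0, 10.0 + dur, dur, loc, conf)

    def test_permissive_config_is_identity(self):
        recs = [self._rec(), self._rec("hit", 0.4, 0.1)]
        cfg = _cfg(min_duration=0.0, min_confidence=0.0)
        assert filter_logs(recs, cfg) == recs

    def test_location_exclusion_drops_impossible_labels(self):
        recs = [self._rec("tv"), self._rec("water")]
        cfg = _cfg(labels=("tv", "water"), instant_labels=frozenset())
        assert filter_logs(recs, cfg, allowed_labels=("water",)) == [recs[1]]

    def test_short_and_low_confidence_dropped(self):
        recs = [self._rec(dur=0.4), self._rec(conf=0.05), self._rec()]
        out = filter_logs(recs, _cfg(min_duration=0.5, min_confidence=0.3))
        assert out == [recs[2]]


def test_flip_noise_recovery_single_seed():
    """Window-level decisions beat raw argmax under 10% frame flips."""
    raw_acc, win_acc = flip_noise_trial(seed=0)
    assert win_acc > raw_acc


def flip_noise_trial(seed: int, n_frames: int = 400, p_flip: float = 0.1, n_labels: int = 4):
    """One flip-noise experiment on a constant continuous-label stream.

    Frames carry probability 0.9 for the true label; with probability
    ``p_flip`` the argmax is flipped to a random other label. Returns
    (raw frame accuracy, post-processed window accuracy), where a window is
    correct when the true label occurred and no other continuous label did.
    """
    labels = tuple(f"c{i}" for i in range(n_labels))
    cfg = PostConfig(labels=labels, instant_labels=frozenset())
    rng = np.random.default_rng(seed)
    true_idx = 0
    frames = []
    raw_correct = 0
    for i in range(n_frames):
        probs = np.full(n_labels, 0.1 / (n_labels - 1))
        if rng.random() < p_flip:
            probs[int(rng.integers(1, n_labels))] = 0.9
        else:
            probs[true_idx] = 0.9
        probs /= probs.sum()
        raw_correct += int(probs.argmax() == true_idx)
        frames.append(PredictionFrame(0.5 * i, probs))
    raw_acc = raw_correct / n_frames
    windows = stream_windows(frames, cfg.window_size, cfg.frame_hop_s)
    win_correct = 0
    for w in windows:
        evs = vote(w, cfg)
        win_correct += int(evs[true_idx].occurred and not any(e.occurred for e in evs[1:]))
    return raw_acc, win_correct / len(windows)
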
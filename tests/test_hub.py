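"""Node pipeline, log merging/scoring, config loading and the CLI surface."""

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from adlsound.cli import main as cli_main
from adlsound.config import load_node_config
from adlsound.hub import (
    NodeConfig,
    merge_logs,
    read_log,
    run_node,
    score_log,
    write_log,
)
from adlsound.postprocess import ActivityRecord
from adlsound.synth import (
    AudioClip,
    GroundTruth,
    ScriptEntry,
    SessionScript,
    synth_session,
)

BATHROOM_LABELS = (
    "airutils", "brushing", "flushing", "hitting", "peeing", "speech", "watering1", "watering2",
)

#: Ten scripted bathroom events over ten minutes: shower, toothbrushing with
#: cup clinks, toileting with a flush, a second washing round.
BATHROOM_ENTRIES = [
    ScriptEntry("watering2", 20.0, 40.0),
    ScriptEntry("hitting", 62.5, 0.3),
    ScriptEntry("brushing", 70.0, 20.0),
    ScriptEntry("hitting", 93.0, 0.3),
    ScriptEntry("peeing", 100.0, 15.0),
    ScriptEntry("flushing", 116.0, 3.0),
    ScriptEntry("watering1", 130.0, 30.0),
    ScriptEntry("airutils", 170.0, 20.0),
    ScriptEntry("brushing", 200.0, 15.0),
    ScriptEntry("watering2", 216.0, 14.0),
]


def _bathroom_node():
    return NodeConfig(name="bath", location="bathroom", allowed_labels=BATHROOM_LABELS)


def _rec(label, start, end, loc="bathroom", conf=0.9):
    return ActivityRecord(label, start, end, end - start, loc, conf)


class TestRunNode:
    def test_silent_wav_yields_empty_log(self, trained_setup):
        clip = AudioClip(np.zeros(16000 * 8, dtype=np.float32))
        assert run_node(clip, _bathroom_node(), trained_setup.model) == []

    def test_missing_model_rejected(self):
        with pytest.raises(ValueError, match="model"):
            run_node(AudioClip(np.zeros(16000, dtype=np.float32)), _bathroom_node(), None)

    def test_single_event_session_yields_one_overlapping_activity(self, trained_setup):
        script = SessionScript(
            entries=[ScriptEntry("watering1", 10.0, 20.0)],
            noise_floor_db=-40.0,
            total_duration=60.0,
        )
        clip, truth = synth_session(script, seed=6)
        recs = run_node(clip, _bathroom_node(), trained_setup.model)
        watering = [r for r in recs if r.label == "watering1"]
        assert len(watering) == 1
        (label, t0, t1) = truth.intervals[0]
        assert watering[0].start_time < t1 and watering[0].end_time > t0

    def test_same_input_twice_is_deterministic(self, trained_setup):
        script = SessionScript(
            entries=[ScriptEntry("brushing", 5.0, 10.0)], noise_floor_db=-40.0, total_duration=30.0
        )
        clip, _ = synth_session(script, seed=3)
        a = run_node(clip, _bathroom_node(), trained_setup.model)
        b = run_node(clip, _bathroom_node(), trained_setup.model)
        assert a == b

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_ten_minute_bathroom_session_event_f1(self, trained_setup, seed):
        """Full pipeline on a scripted session: event F1 >= 0.8."""
        script = SessionScript(entries=BATHROOM_ENTRIES, noise_floor_db=-40.0, total_duration=600.0)
        clip, truth = synth_session(script, seed)
        recs = run_node(clip, _bathroom_node(), trained_setup.model)
        s = score_log(recs, truth)
        assert s["f1"] >= 0.8

    def test_every_long_event_yields_exactly_one_overlapping_activity(self, trained_setup):
        script = SessionScript(entries=BATHROOM_ENTRIES, noise_floor_db=-40.0, total_duration=600.0)
        clip, truth = synth_session(script, seed=1)
        recs = run_node(clip, _bathroom_node(), trained_setup.model)
        for label, t0, t1 in truth.intervals:
            if t1 - t0 < 3.0:
                continue
            hits = [
                r for r in recs if r.label == label and r.start_time < t1 and r.end_time > t0
            ]
            assert len(hits) == 1, f"{label} [{t0}, {t1}] -> {len(hits)} activities"
        for r in recs:
            assert r.duration == r.end_time - r.start_time


class TestMergeLogs:
    def test_orders_by_start_time(self):
        a = [_rec("speech", 3.0, 5.0, "livingroom")]
        b = [_rec("watering1", 1.0, 2.0)]
        merged = merge_logs([a, b])
        assert [r.start_time for r in merged] == [1.0, 3.0]

    def test_single_log_identity(self):
        log = [_rec("tv", 0.0, 4.0, "livingroom")]
        assert merge_logs([log]) == log

    def test_merge_is_a_sorted_permutation(self):
        rng = np.random.default_rng(12)
        logs = [
            [_rec("speech", float(t), float(t) + 1.0, loc) for t in rng.uniform(0, 500, 100)]
            for loc in ("kitchen", "bathroom", "livingroom")
        ]
        merged = merge_logs(logs)
        assert len(merged) == 300
        starts = [r.start_time for r in merged]
        assert starts == sorted(starts)
        flat = [r for log in logs for r in log]
        assert sorted(map(repr, merged)) == sorted(map(repr, flat))


class TestScoreLog:
    def test_perfect_log(self):
        truth = GroundTruth([("speech", 0.0, 5.0), ("tv", 10.0, 20.0)])
        log = [_rec("speech", 0.0, 5.0), _rec("tv", 10.0, 20.0)]
        s = score_log(log, truth)
        assert s["precision"] == 1.0 and s["recall"] == 1.0

    def test_empty_log_has_zero_recall(self):
        s = score_log([], GroundTruth([("speech", 0.0, 5.0)]))
        assert s["recall"] == 0.0

    def test_one_miss_one_false_alarm(self):
        truth = GroundTruth([("speech", 0.0, 5.0), ("tv", 10.0, 20.0), ("speech", 30.0, 35.0)])
        log = [
            _rec("speech", 0.5, 5.0),
            _rec("tv", 11.0, 19.0),
            _rec("flushing", 40.0, 43.0),  # false alarm; speech at 30 missed
        ]
        s = score_log(log, truth)
        assert s["precision"] == pytest.approx(2 / 3)
        assert s["recall"] == pytest.approx(2 / 3)

    def test_matching_is_one_to_one(self):
        truth = GroundTruth([("speech", 0.0, 4.0), ("speech", 4.0, 8.0)])
        log = [_rec("speech", 0.0, 8.0)]  # one long activity cannot match both
        s = score_log(log, truth)
        assert s["matched"] == 1


class TestConfigAndLogs:
    def test_yaml_node_config(self, tmp_path):
        cfg = {
            "name": "bath1",
            "location": "bathroom",
            "capture": {"wake_threshold": 0.02, "stop_silence_s": 4.0},
            "post": {"threshold": 0.6, "tolerance_continuous": 12},
            "exclusions": {"bathroom": ["tv", "microwave", "cooking", "speech"]},
        }
        p = tmp_path / "node.yaml"
        p.write_text(yaml.safe_dump(cfg))
        node = load_node_config(str(p))
        assert node.wake_threshold == 0.02
        assert node.post.threshold == 0.6
        assert node.post.tolerance_continuous == 12
        allowed = node.effective_allowed()
        assert "tv" not in allowed and "speech" not in allowed and "watering1" in allowed

    def test_log_round_trip_csv_and_jsonl(self, tmp_path):
        recs = [_rec("speech", 1.0, 3.5, conf=0.75), _rec("hitting", 4.0, 4.5, conf=0.5)]
        for name in ("log.csv", "log.jsonl"):
            path = tmp_path / name
            write_log(recs, str(path))
            assert read_log(str(path)) == recs


class TestCli:
    def test_synth_and_score_commands(self, tmp_path):
        runner = CliRunner()
        wav = tmp_path / "clip.wav"
        res = runner.invoke(cli_main, ["synth", "--label", "speech", "--seed", "3", "--out", str(wav)])
        assert res.exit_code == 0, res.output
        assert wav.exists()

        truth = tmp_path / "truth.csv"
        truth.write_text("label,start,end\nspeech,0.0,5.0\n")
        log = tmp_path / "log.csv"
        write_log([_rec("speech", 0.0, 5.0)], str(log))
        res = runner.invoke(cli_main, ["score", "--log", str(log), "--truth", str(truth)])
        assert res.exit_code == 0, res.output
        assert '"f1": 1.0' in res.output

    def test_session_synthesis_writes_truth(self, tmp_path):
        script = {
            "total_duration": 12.0,
            "noise_floor_db": -50.0,
            "entries": [{"label": "flushing", "onset": 2.0, "duration": 3.0}],
        }
        sp = tmp_path / "script.yaml"
        sp.write_text(yaml.safe_dump(script))
        wav = tmp_path / "session.wav"
        res = CliRunner().invoke(cli_main, ["synth", "--script", str(sp), "--seed", "1", "--out", str(wav)])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "session.truth.csv").read_text().splitlines()[1] == "flushing,2.0,5.0"

    def test_merge_command(self, tmp_path):
        a, b, out = (tmp_path / n for n in ("a.csv", "b.csv", "merged.csv"))
        write_log([_rec("speech", 5.0, 8.0, "livingroom")], str(a))
        write_log([_rec("watering1", 1.0, 2.0)], str(b))
        res = CliRunner().invoke(cli_main, ["merge", str(a), str(b), "--out", str(out)])
        assert res.exit_code == 0, res.output
        merged = read_log(str(out))
        assert [r.label for r in merged] == ["watering1", "speech"]
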
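import json

import numpy as np
import pytest

from melophys.core import ANNOTATION_CATEGORIES, ConfigError
from melophys.baseline import hrv_summary
from melophys.events import window_diff
from melophys.preprocess import process_session
from melophys.synthetic import (
    ARCHETYPES,
    Coupling,
    SimConfig,
    archetype_counts,
    generate_annotations,
    generate_cohort,
    generate_listener,
    generate_music,
    write_cohort,
)


def make_config(**kw):
    defaults = dict(n_pieces=2, piece_duration_s=120.0, n_listeners=4,
                    playlist_length=3, annotation_counts={"Novel Melody": 2}, seed=5)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestConfigValidation:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            make_config(archetype_mix=(0.5, 0.5, 0.5))

    def test_negative_duration_rejected(self):
        with pytest.raises(ConfigError):
            make_config(piece_duration_s=-10)

    def test_playlist_longer_than_available(self):
        with pytest.raises(ConfigError):
            make_config(playlist_length=10)  # only 2 pieces x 2 versions

    def test_negative_noise_rejected(self):
        with pytest.raises(ConfigError):
            make_config(music_noise_sd={"tempo": -1.0})


class TestGenerateMusic:
    def test_noiseless_shift_is_exact(self):
        cfg = make_config(music_noise_sd={c: 0.0 for c in
                                          ("tempo", "loudness", "spectral_centroid", "mfcc", "diameter")},
                          cp_per_channel=1)
        m = generate_music(cfg, "piece_00")
        for t_cp, channel, direction in m.truth_changepoints:
            s = m.channels[channel]
            before = s.values[s.times < t_cp]
            after = s.values[s.times >= t_cp]
            diff = after.mean() - before.mean()
            expected = cfg.shift(channel) * (1 if direction == "up" else -1)
            assert diff == pytest.approx(expected, abs=1e-9)

    def test_same_seed_identical(self):
        cfg = make_config()
        a = generate_music(cfg, "piece_00")
        b = generate_music(cfg, "piece_00")
        for ch in a.channels:
            np.testing.assert_array_equal(a.channels[ch].values, b.channels[ch].values)

    def test_truth_changepoint_count(self):
        cfg = make_config(cp_per_channel=4)
        m = generate_music(cfg, "piece_00")
        per_channel = {}
        for _, ch, _ in m.truth_changepoints:
            per_channel[ch] = per_channel.get(ch, 0) + 1
        assert all(v == 4 for v in per_channel.values())

    def test_truth_onsets_inside_piece(self):
        m = generate_music(make_config(), "piece_01")
        for t, _, _ in m.truth_changepoints:
            assert 0 <= t <= m.duration


class TestGenerateAnnotations:
    def test_counts_and_gaps(self):
        cfg = make_config(piece_duration_s=300.0, annotation_counts={"Novel Melody": 5})
        ann = generate_annotations(cfg, "piece_00")
        assert len(ann.events) == 5
        onsets = [t for t, _ in ann.events]
        assert np.all(np.diff(onsets) >= 20.0)  # 2 x 10-s window

    def test_empty_targets(self):
        cfg = make_config(annotation_counts={})
        assert generate_annotations(cfg, "piece_00").events == []

    def test_histogram_matches_targets(self):
        cfg = make_config(piece_duration_s=600.0,
                          annotation_counts={"Novel Melody": 10, "Return": 10})
        ann = generate_annotations(cfg, "piece_00")
        counts = {}
        for _, c in ann.events:
            counts[c] = counts.get(c, 0) + 1
        assert counts == {"Novel Melody": 10, "Return": 10}

    def test_unsatisfiable_counts_rejected(self):
        cfg = make_config(piece_duration_s=60.0, annotation_counts={"Novel Melody": 10})
        with pytest.raises(ConfigError):
            generate_annotations(cfg, "piece_00")

    def test_onsets_strictly_increasing(self):
        cfg = make_config(piece_duration_s=400.0,
                          annotation_counts={c: 1 for c in ANNOTATION_CATEGORIES})
        onsets = [t for t, _ in generate_annotations(cfg, "piece_00").events]
        assert np.all(np.diff(onsets) > 0)


class TestGenerateListener:
    def test_unknown_archetype(self):
        cfg = make_config()
        m = generate_music(cfg, "piece_00")
        a = generate_annotations(cfg, "piece_00")
        with pytest.raises(ConfigError):
            generate_listener(cfg, "vagal", {"piece_00__V1": m}, {"piece_00__V1": a},
                              ["piece_00__V1"])

    def test_physiological_bounds(self, tiny_cohort):
        for rec in tiny_cohort.listeners:
            assert np.all((rec.baseline_rr > 0.3) & (rec.baseline_rr < 2.0))
            for s in rec.sessions.values():
                assert np.all((s.rr > 0.3) & (s.rr < 2.0))
                assert np.all(s.sys > s.dia)

    def test_baseline_long_enough(self, tiny_cohort):
        for rec in tiny_cohort.listeners:
            assert rec.baseline_rr.sum() >= 300.0

    def test_rmssd_ordering_pns_vs_sns(self):
        # [oracle] simulate both archetype groups and compare group means
        cfg = make_config(n_listeners=3)
        m = generate_music(cfg, "piece_00")
        a = generate_annotations(cfg, "piece_00")
        perfs = {"piece_00__V1": m}
        anns = {"piece_00__V1": a}
        rmssd = {}
        for arch in ("pns_dominant", "sns_dominant"):
            vals = []
            for i in range(20):
                rec = generate_listener(cfg, arch, perfs, anns, ["piece_00__V1"],
                                        f"listener_{i:03d}")
                vals.append(hrv_summary(rec.baseline_rr).rmssd)
            rmssd[arch] = np.mean(vals)
        assert rmssd["pns_dominant"] > rmssd["sns_dominant"]

    def test_zero_coupling_zero_expected_response(self, tiny_cohort):
        # no planted effect: event-locked mean difference ~ 0 across many events
        diffs = []
        for rec in tiny_cohort.listeners:
            for perf, s in rec.sessions.items():
                chans = process_session(s)
                for t, _ in tiny_cohort.annotations[perf].events:
                    d = window_diff(chans["rr"], t, 10.0)
                    if d is not None:
                        diffs.append(d)
        assert abs(np.mean(diffs)) < 0.02

    def test_planted_resp_response_recovered(self, coupled_cohort):
        # [oracle] sustained -0.15 s planted respiratory-interval response,
        # measured on the ground-truth breath intervals: mean interval of
        # breaths well inside the post window vs the pre window
        diffs = []
        for rec in coupled_cohort.listeners:
            for perf, s in rec.sessions.items():
                mid = (s.resp_truth_peaks[:-1] + s.resp_truth_peaks[1:]) / 2
                for t, cat in coupled_cohort.annotations[perf].events:
                    if cat != "Novel Melody":
                        continue
                    pre = s.resp_truth_intervals[(mid >= t - 10) & (mid < t)]
                    post = s.resp_truth_intervals[(mid > t + 2) & (mid <= t + 10)]
                    if len(pre) and len(post):
                        diffs.append(post.mean() - pre.mean())
        assert len(diffs) > 30
        assert np.mean(diffs) == pytest.approx(-0.15, abs=0.03)


class TestGenerateCohort:
    def test_archetype_rounding(self):
        assert archetype_counts((0.2, 0.6, 0.2), 10) == [2, 6, 2]

    def test_counts_match_mix(self, tiny_cohort):
        counts = {a: 0 for a in ARCHETYPES}
        for rec in tiny_cohort.listeners:
            counts[rec.archetype] += 1
        assert sum(counts.values()) == 6

    def test_playlist_first_last_same_piece(self, tiny_cohort):
        for rec in tiny_cohort.listeners:
            first_piece = rec.playlist[0].split("__")[0]
            last_piece = rec.playlist[-1].split("__")[0]
            assert first_piece == last_piece
            assert rec.playlist[0] != rec.playlist[-1]

    def test_every_performance_heard(self, tiny_cohort):
        heard = {p for rec in tiny_cohort.listeners for p in rec.playlist}
        assert heard == set(tiny_cohort.music)

    def test_too_few_listeners(self):
        cfg = make_config(n_listeners=4)
        cfg.n_listeners = 2
        with pytest.raises(ConfigError):
            generate_cohort(cfg)

    def test_serialization_deterministic(self, tmp_path):
        cfg = make_config()
        for sub in ("a", "b"):
            write_cohort(generate_cohort(cfg), tmp_path / sub)
        files_a = sorted((tmp_path / "a").rglob("*"))
        for fa in files_a:
            if fa.is_file():
                fb = tmp_path / "b" / fa.relative_to(tmp_path / "a")
                assert fa.read_bytes() == fb.read_bytes(), fa.name

    def test_truth_ledger_complete(self, coupled_cohort):
        truth = coupled_cohort.truth
        assert set(truth["changepoints"]) == set(coupled_cohort.music)
        assert truth["couplings"][0]["amplitude"] == -0.15
        assert set(truth["archetypes"]) == {r.listener_id for r in coupled_cohort.listeners}
        json.dumps(truth)  # serializable
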
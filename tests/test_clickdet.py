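"""Teager–Kaiser detection, feature extraction, deletion and segment rules."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pamscape import SceneSpec, ScheduledEvent, assemble_scene, cuvier_template
from pamscape import clickdet
from pamscape.clickdet import ClassifierConfig, DetectorConfig

FS = 200_000.0


class TestTkOperator:
    def test_constant_signal_is_zero(self):
        psi = clickdet.tk_energy(np.full(100, 3.7))
        assert np.allclose(psi[1:-1], 0.0)

    def test_sinusoid_closed_form(self):
        """Ψ of A·cos(Ωn+φ) is the constant A²·sin²(Ω)."""
        for amp, omega in [(1.0, 0.3), (2.5, 1.2), (0.3, 0.05)]:
            n = np.arange(400)
            psi = clickdet.tk_energy(amp * np.cos(omega * n + 0.7))
            expected = amp**2 * np.sin(omega) ** 2
            assert np.allclose(psi[1:-1], expected, rtol=1e-9)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            clickdet.tk_energy(np.array([1.0, 2.0]))

    def test_single_click_localized(self):
        """One click 15+ dB over the floor produces one TK excursion at the
        true click time within ±1 ms."""
        spec = SceneSpec(
            duration_s=3.0,
            sample_rate=FS,
            seed=21,
            events=[ScheduledEvent(template=cuvier_template(), start_s=1.0, count=1)],
        )
        rec, truth = assemble_scene(spec)
        cand = clickdet.detect_candidates(rec)
        assert len(cand) == 1
        true_center = (truth["start_s"].iloc[0] + truth["end_s"].iloc[0]) / 2.0
        assert abs(cand["time_s"].iloc[0] - true_center) <= 1e-3


class TestDetection:
    def test_silent_scene_no_candidates(self, silent_scene):
        rec, _ = silent_scene
        assert len(clickdet.detect_candidates(rec)) == 0

    def test_train_recall_is_one(self, click_train_scene):
        rec, truth = click_train_scene
        cand = clickdet.detect_candidates(rec)
        assert len(cand) == len(truth) == 10
        matched = [
            np.min(np.abs(cand["time_s"].to_numpy() - (row.start_s + row.end_s) / 2))
            for row in truth.itertuples()
        ]
        assert max(matched) <= 1e-3

    def test_confusers_detected_prefilter(self, mixed_train_scene):
        rec, truth = mixed_train_scene
        cand = clickdet.detect_candidates(rec)
        # 15 real transients; the robust threshold may admit an occasional
        # noise excursion but every scheduled event must be found
        assert len(cand) >= 15
        retained = clickdet.apply_deletion_criteria(cand)
        whale_rows = retained[retained["retained"]]
        assert (truth["signal_class"] == "cuvier_fm").sum() <= len(whale_rows)

    def test_sample_rate_too_low_rejected(self):
        from pamscape.calib import CalibratedRecording

        rec = CalibratedRecording(samples=np.zeros(1000), sample_rate=8_000.0)
        with pytest.raises(ValueError, match="too low"):
            clickdet.detect_candidates(rec)

    def test_exclude_intervals_skip_candidates(self, click_train_scene):
        rec, truth = click_train_scene
        cfg = DetectorConfig(exclude_intervals=((0.0, truth["end_s"].iloc[4]),))
        cand = clickdet.detect_candidates(rec, cfg)
        assert len(cand) == 5


class TestFeatures:
    def test_tone_burst_sweep_near_zero(self):
        t = np.arange(int(1e-3 * FS)) / FS
        burst = np.hanning(len(t)) * np.cos(2 * np.pi * 50_000.0 * t)
        pf, _, _, sr = clickdet.extract_features(burst, FS)
        assert abs(pf - 50_000.0) <= 500.0
        assert abs(sr) < 1e6  # ≪ any click sweep

    def test_constructed_chirp_sweep(self):
        """A 25→45 kHz linear chirp over 800 µs measures 25 kHz/ms ± 10%
        (built directly, independent of the pulse synthesiser)."""
        dur = 800e-6
        t = np.arange(int(dur * FS)) / FS
        phase = 2 * np.pi * (25_000.0 * t + 0.5 * (20_000.0 / dur) * t**2)
        x = np.hanning(len(t)) * np.cos(phase)
        sr = clickdet.extract_features(x, FS)[3]
        assert abs(sr - 25e6) <= 2.5e6

    def test_all_zero_snippet_rejected(self):
        with pytest.raises(ValueError):
            clickdet.extract_features(np.zeros(512), FS)


def _brute_force_deleted(flags: tuple[bool, bool, bool, bool], logic: str) -> bool:
    return all(flags) if logic == "conjunctive" else any(flags)


IN_REGION = {
    "peak_freq_hz": (20_000.0, 40_000.0),  # (inside deletion region, outside)
    "center_freq_hz": (18_000.0, 33_000.0),
    "duration_s": (100e-6, 500e-6),
    "sweep_rate_hz_per_s": (5e6, 30e6),
}


class TestDeletionCriteria:
    @pytest.mark.parametrize("logic", ["conjunctive", "disjunctive"])
    def test_all_16_feature_combinations(self, logic):
        """Brute-force enumeration of every in/out combination of the four
        deletion criteria matches the rule under both connectives."""
        rows, expected = [], []
        for combo in product([True, False], repeat=4):
            rows.append(
                {
                    "time_s": 0.0,
                    **{
                        name: vals[0] if inside else vals[1]
                        for (name, vals), inside in zip(IN_REGION.items(), combo)
                    },
                    "tk_score": 1.0,
                }
            )
            expected.append(not _brute_force_deleted(combo, logic))
        out = clickdet.apply_deletion_criteria(
            pd.DataFrame(rows), ClassifierConfig(deletion_logic=logic)
        )
        assert out["retained"].tolist() == expected

    def test_spec_examples(self):
        strong = {"time_s": 0, "peak_freq_hz": 40e3, "center_freq_hz": 33e3,
                  "duration_s": 500e-6, "sweep_rate_hz_per_s": 30e6, "tk_score": 1}
        weak = {"time_s": 0, "peak_freq_hz": 20e3, "center_freq_hz": 18e3,
                "duration_s": 100e-6, "sweep_rate_hz_per_s": 5e6, "tk_score": 1}
        short_strong = dict(strong, duration_s=200e-6)
        for logic, retained in [("conjunctive", [True, False, True]),
                                ("disjunctive", [True, False, False])]:
            out = clickdet.apply_deletion_criteria(
                pd.DataFrame([strong, weak, short_strong]),
                ClassifierConfig(deletion_logic=logic),
            )
            assert out["retained"].tolist() == retained

    @given(
        peak=st.floats(1e3, 99e3),
        center=st.floats(1e3, 99e3),
        dur=st.floats(1e-6, 5e-3),
        sweep=st.floats(-5e7, 5e7),
        logic=st.sampled_from(["conjunctive", "disjunctive"]),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_bruteforce_on_random_features(self, peak, center, dur, sweep, logic):
        cfg = ClassifierConfig(deletion_logic=logic)
        flags = (
            peak < cfg.peak_freq_min_hz,
            center < cfg.center_freq_min_hz,
            dur < cfg.duration_min_s,
            sweep < cfg.sweep_rate_min_hz_per_s,
        )
        df = pd.DataFrame([
            {"time_s": 0.0, "peak_freq_hz": peak, "center_freq_hz": center,
             "duration_s": dur, "sweep_rate_hz_per_s": sweep, "tk_score": 1.0}
        ])
        out = clickdet.apply_deletion_criteria(df, cfg)
        assert out["retained"].iloc[0] == (not _brute_force_deleted(flags, logic))

    def test_threshold_boundary_strict(self):
        """A feature exactly at its cutoff never deletes; deletion flips at
        exactly the configured value."""
        cfg = ClassifierConfig()
        base = {"time_s": 0.0, "peak_freq_hz": 20e3, "center_freq_hz": 18e3,
                "sweep_rate_hz_per_s": 5e6, "tk_score": 1.0}
        at = dict(base, duration_s=cfg.duration_min_s)
        below = dict(base, duration_s=np.nextafter(cfg.duration_min_s, 0.0))
        out = clickdet.apply_deletion_criteria(pd.DataFrame([at, below]), cfg)
        assert out["retained"].tolist() == [True, False]


class TestSegmentRules:
    @pytest.mark.parametrize(
        "n_det,n_ret,label",
        [
            (7, 7, "insufficient"),  # "more than seven" is exclusive
            (8, 2, "beaked_whale"),
            (100, 13, "not_beaked_whale"),  # exactly 13% is not "more than 13%"
            (100, 14, "beaked_whale"),
            (0, 0, "insufficient"),
        ],
    )
    def test_boundary_cases(self, n_det, n_ret, label):
        assert clickdet.segment_label(n_det, n_ret, ClassifierConfig()) == label

    def test_oracle_equivalence_on_random_tables(self, rng):
        """1,000 random candidate tables: the segment label matches an
        independent re-application of the count/fraction rules."""
        cfg = ClassifierConfig()
        for _ in range(1000):
            n_det = int(rng.integers(0, 30))
            n_ret = int(rng.integers(0, n_det + 1))
            got = clickdet.segment_label(n_det, n_ret, cfg)
            if n_det <= 7:
                want = "insufficient"
            elif n_ret / n_det > 0.13:
                want = "beaked_whale"
            else:
                want = "not_beaked_whale"
            assert got == want

    def test_segment_decisions_windows_and_trailing(self):
        cand = pd.DataFrame(
            {
                "time_s": list(np.linspace(1, 70, 10)) + [80.0],
                "peak_freq_hz": 40e3,
                "center_freq_hz": 33e3,
                "duration_s": 500e-6,
                "sweep_rate_hz_per_s": 30e6,
                "tk_score": 1.0,
            }
        )
        dec = clickdet.segment_decisions(cand, 100.0, ClassifierConfig())
        assert dec["start_s"].tolist() == [0.0, 75.0]
        assert dec["end_s"].tolist() == [75.0, 100.0]
        assert dec["label"].tolist() == ["beaked_whale", "insufficient"]


def _decisions(labels, seg=75.0):
    return pd.DataFrame(
        {
            "start_s": [i * seg for i in range(len(labels))],
            "end_s": [(i + 1) * seg for i in range(len(labels))],
            "n_detected": 10,
            "n_retained": 5,
            "fraction_retained": 0.5,
            "label": labels,
        }
    )


class TestPresenceLog:
    def test_consecutive_positives_merge(self):
        log = clickdet.log_bw_presence(
            _decisions(["beaked_whale"] * 4 + ["not_beaked_whale"]),
            "2019-07-01T00:00:00Z",
        )
        enc = log["encounters"]
        assert len(enc) == 1
        assert (enc["end_utc"] - enc["start_utc"]).iloc[0] == pd.Timedelta(seconds=300)
        assert log["hourly"]["bw_minutes"].tolist() == [5]  # minutes 0–4 touched

    def test_no_positives_all_zero(self):
        log = clickdet.log_bw_presence(
            _decisions(["not_beaked_whale", "insufficient"]), "2019-07-01T00:00:00Z"
        )
        assert len(log["encounters"]) == 0
        assert len(log["hourly"]) == 0
        assert len(log["weekly"]) == 0

    def test_positives_spanning_two_hours(self):
        labels = ["not_beaked_whale"] * 47 + ["beaked_whale"] * 2  # crosses 3600 s
        log = clickdet.log_bw_presence(_decisions(labels), "2019-07-01T00:00:00Z")
        assert len(log["hourly"]) == 2

    def test_minutes_conserve_into_hours(self):
        labels = (["beaked_whale"] * 3 + ["not_beaked_whale"] * 5) * 12
        log = clickdet.log_bw_presence(_decisions(labels), "2019-07-01T00:00:00Z")
        per_hour = (
            log["minutes"]
            .assign(h=lambda d: d["minute_utc"].dt.floor("h"))
            .groupby("h")
            .size()
        )
        assert per_hour.tolist() == log["hourly"]["bw_minutes"].tolist()

    def test_overlapping_segments_rejected(self):
        dec = _decisions(["beaked_whale", "beaked_whale"])
        dec.loc[1, "start_s"] = 50.0
        with pytest.raises(ValueError, match="overlap"):
            clickdet.log_bw_presence(dec, "2019-07-01T00:00:00Z")


class TestRecallProperty:
    def test_recall_and_no_false_positive_segments(self):
        """Scenes with click trains well over the floor yield positive
        segments (recall 1 here, mirroring a ≤5% miss ceiling); click-free
        scenes yield none."""
        fs = 125_000.0
        events = [
            ScheduledEvent(template=cuvier_template(), start_s=10.0, count=12),
            ScheduledEvent(template=cuvier_template(), start_s=90.0, count=12),
        ]
        rec, _ = assemble_scene(
            SceneSpec(duration_s=150.0, sample_rate=fs, seed=31, events=events)
        )
        cand = clickdet.detect_candidates(rec)
        dec = clickdet.segment_decisions(cand, rec.duration)
        assert dec["label"].tolist() == ["beaked_whale", "beaked_whale"]

        quiet, _ = assemble_scene(SceneSpec(duration_s=150.0, sample_rate=fs, seed=32))
        dec_q = clickdet.segment_decisions(clickdet.detect_candidates(quiet), quiet.duration)
        assert (dec_q["label"] != "beaked_whale").all()
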
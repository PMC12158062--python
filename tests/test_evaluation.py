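import json

import numpy as np
import pandas as pd
import pytest

from conftest import make_constant_session
from rtee.agent import DQNAgent, TrainingConfig, train
from rtee.evaluation import (
    MET_LOOKUP,
    EvaluationReport,
    MetLookup,
    compare_methods,
    fill_missing_hr,
    keytel_series,
    mae,
    met_series,
    scenario_length_ablation,
    segment_mae,
    split_sessions,
)
from rtee.formulas import ParticipantProfile
from rtee.synth import NoiseParams, generate_profile, generate_session


class TestMetLookup:
    @pytest.mark.parametrize(
        "activity,met",
        [
            ("Resting", 1.0),
            ("office work", 1.5),
            ("cycling 10 mph", 4.0),
            ("Cycling at 10 mph", 4.0),
            ("food serving", 8.0),
            ("firefighting", 13.0),
            ("cycling over 20 mph", 16.0),
        ],
    )
    def test_entries(self, activity, met):
        assert MET_LOOKUP[activity] == met

    def test_resting_is_one(self):
        assert MET_LOOKUP["resting"] == 1.0

    def test_missing_key(self):
        with pytest.raises(KeyError):
            MET_LOOKUP["juggling"]
        assert "juggling" not in MET_LOOKUP

    def test_custom_table(self):
        table = MetLookup({"walking": 3.3})
        assert table["Walking"] == 3.3


class TestKeytelSeries:
    def test_constant_hr_constant_series(self, male_profile):
        s = make_constant_session(male_profile, vo2=10.0, hr=120.0, n=100)
        series = keytel_series(s)
        assert len(set(series.tolist())) == 1

    def test_hand_computed_value(self, male_profile):
        # oracle: (-55.0969 + 0.6309*120 + 0.1988*70 + 0.2017*30) / 4.184 / 60
        s = make_constant_session(male_profile, vo2=10.0, hr=120.0, n=10)
        expected = 40.5781 / 4.184 / 60
        assert np.allclose(keytel_series(s), expected, rtol=1e-12)

    def test_clamped_below_zero_crossing(self, male_profile):
        # male branch crosses zero at HR = (55.0969 - 0.1988*70 - 0.2017*30) / 0.6309
        hr_zero = (55.0969 - 0.1988 * 70 - 0.2017 * 30) / 0.6309
        s = make_constant_session(male_profile, vo2=10.0, hr=hr_zero - 5, n=10)
        assert np.all(keytel_series(s, clamp_negative=True) == 0.0)
        assert np.all(keytel_series(s, clamp_negative=False) < 0.0)

    def test_missing_hr_filled(self, male_profile):
        s = make_constant_session(male_profile, vo2=10.0, hr=120.0, n=10)
        s.samples.loc[3:5, "hr_bpm"] = np.nan
        series = keytel_series(s)
        assert np.all(np.isfinite(series))
        with pytest.raises(ValueError):
            keytel_series(s, fill_missing=False)


class TestFillMissingHr:
    def test_forward_and_leading_backfill(self):
        filled, n = fill_missing_hr(np.array([np.nan, 60.0, np.nan, 62.0]))
        assert n == 2
        assert filled.tolist() == [60.0, 60.0, 60.0, 62.0]

    def test_all_missing(self):
        with pytest.raises(ValueError):
            fill_missing_hr(np.array([np.nan, np.nan]))


class TestMetSeries:
    def test_sitting_hand_computed(self, male_profile):
        # oracle: 1 * 70 * 3.5 / 200 / 60
        s = make_constant_session(male_profile, vo2=3.5, n=10, label="Sitting")
        assert np.allclose(met_series(s), 70 * 3.5 / 200 / 60, rtol=1e-12)

    def test_piecewise_constant_by_segment(self, noise_free_session):
        series = met_series(noise_free_session)
        labels = noise_free_session.labels
        for lab in np.unique(labels):
            assert len(np.unique(series[labels == lab])) == 1

    def test_weight_linearity(self):
        light = make_constant_session(ParticipantProfile(50, 170, 30, 1), vo2=14.0, n=10)
        heavy = make_constant_session(ParticipantProfile(100, 170, 30, 1), vo2=14.0, n=10)
        assert np.allclose(met_series(heavy), 2 * met_series(light))

    def test_segment_table_override(self, noise_free_session):
        table = {lab: 2.0 for lab in np.unique(noise_free_session.labels)}
        series = met_series(noise_free_session, table)
        w = noise_free_session.profile.weight
        assert np.allclose(series, 2.0 * w * 3.5 / 200 / 60)

    def test_missing_segment_errors(self, noise_free_session):
        with pytest.raises(ValueError):
            met_series(noise_free_session, {"Sitting": 1.0})


class TestMae:
    def test_exact_prediction(self):
        x = np.arange(6, dtype=float)
        assert mae(x, x) == 0.0

    def test_constant_offset(self, noise_free_session):
        gt = noise_free_session.gt_ee
        labels = noise_free_session.labels
        seg = segment_mae(gt + 0.01, gt, labels)
        assert all(v == pytest.approx(0.01, rel=1e-9) for v in seg.values())
        assert mae(gt + 0.01, gt) == pytest.approx(0.01, rel=1e-9)

    def test_toy_series_hand_computed(self):
        pred = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        gt = np.array([1.5, 2.0, 2.0, 5.0, 4.0, 6.5])
        labels = np.array(["a", "a", "b", "b", "c", "c"])
        # oracle by hand: errors 0.5, 0, 1, 1, 1, 0.5
        assert mae(pred, gt) == pytest.approx(4.0 / 6)
        seg = segment_mae(pred, gt, labels)
        assert seg == {
            "a": pytest.approx(0.25),
            "b": pytest.approx(1.0),
            "c": pytest.approx(0.75),
        }

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mae(np.zeros(3), np.zeros(4))
        with pytest.raises(ValueError):
            segment_mae(np.zeros(3), np.zeros(3), np.array(["a"]))

    def test_relabel_and_shift_invariance(self, noise_free_session):
        gt = noise_free_session.gt_ee
        pred = gt + 0.005
        labels = noise_free_session.labels
        renamed = np.array([f"X_{lab}" for lab in labels])
        seg1 = segment_mae(pred, gt, labels)
        seg2 = segment_mae(pred, gt, renamed)
        assert {f"X_{k}": v for k, v in seg1.items()} == seg2
        assert mae(np.roll(pred, 7), np.roll(gt, 7)) == pytest.approx(mae(pred, gt))


def tiny_config(**overrides):
    defaults = dict(
        epochs=1,
        window_length_s=60,
        train_stride_s=120,
        warmup_transitions=64,
        update_every=10,
        seed=0,
    )
    defaults.update(overrides)
    return TrainingConfig(**defaults)


@pytest.fixture
def small_cohort(short_protocol):
    rng = np.random.default_rng(11)
    sessions = []
    genders = [1, 0, 1, 0]
    for g in genders:
        p = generate_profile(rng)
        p = ParticipantProfile(p.weight, p.height, p.age, g)
        # tau short relative to the 60-s segments so per-segment effective
        # MET stays close to its target (as with 300-s segments at tau=30)
        sessions.append(
            generate_session(p, short_protocol, NoiseParams(noise_sd=0.0, tau=5.0), rng)
        )
    return sessions


class TestCompareMethods:
    def test_report_shape_and_total_invariant(self, small_cohort):
        agent, _ = train(small_cohort[:3], tiny_config())
        report = compare_methods(agent, small_cohort[3:])
        frame = report.to_frame()
        assert set(frame.index) == {"ours", "keytel", "met"}
        assert frame.shape == (3, 7)
        # Total equals the duration-weighted mean of segment MAEs
        for est, vals in report.maes.items():
            weighted = sum(
                vals[lab] * report.segment_counts[lab] for lab in report.segment_counts
            ) / report.n_seconds
            assert vals["Total"] == pytest.approx(weighted, rel=1e-9)

    def test_keytel_independent_of_agent(self, small_cohort):
        a1, _ = train(small_cohort[:3], tiny_config())
        a2, _ = train(small_cohort[:3], tiny_config(seed=5))
        r1 = compare_methods(a1, small_cohort[3:])
        r2 = compare_methods(a2, small_cohort[3:])
        assert r1.maes["keytel"] == r2.maes["keytel"]

    def test_met_near_exact_on_sitting_noise_free(self, small_cohort):
        # sitting has no transient: target MET == effective MET == 1
        report = compare_methods(None, small_cohort)
        assert report.maes["met"]["Sitting"] == pytest.approx(0.0, abs=1e-12)

    def test_misspecified_met_inflates_activity_error(self, small_cohort):
        true_levels = {"Sitting": 1.0, "Standing": 1.2, "Cycle1": 10.0,
                       "Cycle2": 14.0, "Run1": 8.0, "Run2": 16.0}
        shifted = {k: v + 2.0 for k, v in true_levels.items()}
        base = compare_methods(None, small_cohort, met_per_segment=true_levels)
        off = compare_methods(None, small_cohort, met_per_segment=shifted)
        for lab in ("Cycle1", "Cycle2", "Run1", "Run2"):
            assert off.maes["met"][lab] > base.maes["met"][lab]

    def test_requires_gt_and_labels(self, male_profile, small_cohort):
        s = make_constant_session(male_profile, vo2=3.5, n=60)
        s.samples = s.samples.drop(columns=["vo2_ml_kg_min"])
        with pytest.raises(ValueError):
            compare_methods(None, [s])


class TestReportSerialization:
    def test_json_round_trip(self, small_cohort):
        report = compare_methods(None, small_cohort)
        back = EvaluationReport.from_json(report.to_json())
        assert back.maes == report.maes
        assert back.n_seconds == report.n_seconds
        assert back.segment_counts == report.segment_counts

    def test_save(self, tmp_path, small_cohort):
        report = compare_methods(None, small_cohort)
        report.save(tmp_path / "r.json", tmp_path / "r.csv")
        loaded = json.loads((tmp_path / "r.json").read_text())
        assert "maes" in loaded
        frame = pd.read_csv(tmp_path / "r.csv", index_col="method")
        assert list(frame.columns) == ["Total", "Sitting", "Standing",
                                       "Cycle1", "Cycle2", "Run1", "Run2"]


class TestSplit:
    def test_one_male_one_female_held_out(self, small_cohort):
        train_set, test_set = split_sessions(small_cohort, np.random.default_rng(0))
        assert len(test_set) == 2
        assert {s.profile.gender_flag for s in test_set} == {0, 1}
        assert len(train_set) + len(test_set) == len(small_cohort)

    def test_too_few_sessions(self, small_cohort):
        with pytest.raises(ValueError):
            split_sessions(small_cohort[:2], np.random.default_rng(0))


class TestScenarioLengthAblation:
    def test_two_labeled_rows_and_reproducible(self, small_cohort):
        cfg = tiny_config()
        r1 = scenario_length_ablation(small_cohort, cfg, lengths={"5Min": 120, "1Min": 60})
        r2 = scenario_length_ablation(small_cohort, cfg, lengths={"5Min": 120, "1Min": 60})
        assert set(r1) == {"5Min", "1Min"}
        assert r1 == r2
        assert all(v >= 0 for v in r1.values())
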
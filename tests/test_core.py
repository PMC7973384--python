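"""Core domain types: validation, conversions, windowing, splitting, I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hypnocycle as hc
from hypnocycle.errors import HypnodensityParseError

from conftest import random_simplex_series


class TestValidateSeries:
    def test_one_hot_rows_pass(self):
        probs = np.eye(5)[:3]
        s = hc.HypnodensitySeries(times=[2.5, 7.5, 12.5], probs=probs)
        assert hc.validate_series(s).ok

    def test_bad_row_sum_reports_row(self):
        probs = np.eye(5)[:3].astype(float)
        probs[1] *= 0.8
        s = hc.HypnodensitySeries(times=[2.5, 7.5, 12.5], probs=probs)
        report = hc.validate_series(s)
        assert not report.ok
        assert "row 1" in report.message and "0.8" in report.message

    def test_out_of_range_probability_fails(self):
        probs = np.array([[1.2, -0.2, 0, 0, 0]])
        report = hc.validate_series(hc.HypnodensitySeries(times=[2.5], probs=probs))
        assert not report.ok and "outside" in report.message

    def test_non_monotone_times_fail(self):
        probs = np.eye(5)[:3]
        s = hc.HypnodensitySeries(times=[2.5, 2.0, 7.5], probs=probs)
        assert not hc.validate_series(s).ok

    def test_generator_output_passes(self):
        h = hc.simulate_hypnogram(hc.CyclicSleepModel(), seed=0)
        s = hc.simulate_noisy_hypnodensity(h, seed=1)
        assert hc.validate_series(s).ok

    def test_validation_does_not_mutate(self):
        s = random_simplex_series(10, seed=0)
        before = s.probs.copy()
        hc.validate_series(s)
        np.testing.assert_array_equal(s.probs, before)


class TestSlidingWindowTimes:
    def test_enumerated_example(self):
        centers = hc.sliding_window_times(60, 30, 5)
        np.testing.assert_allclose(centers, [15, 20, 25, 30, 35, 40, 45])

    def test_single_full_window(self):
        np.testing.assert_allclose(hc.sliding_window_times(30, 30, 5), [15])

    def test_window_longer_than_record_is_empty(self):
        assert hc.sliding_window_times(29, 30, 5).size == 0

    @given(
        record=st.integers(30, 2000),
        window=st.integers(1, 100),
        step=st.integers(1, 50),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_count_matches_brute_force(self, record, window, step):
        centers = hc.sliding_window_times(record, window, step)
        brute = [
            window / 2 + k * step
            for k in range(record * 2)
            if k * step + window <= record
        ]
        assert centers.size == len(brute)
        if brute:
            np.testing.assert_allclose(centers, brute)


class TestHypnogramConversions:
    def test_one_hot_embedding(self):
        h = hc.Hypnogram(stages=[0, 2])
        s = hc.hypnogram_to_hypnodensity(h, step_seconds=30)
        np.testing.assert_array_equal(s.probs, [np.eye(5)[0], np.eye(5)[2]])

    def test_step_subdivision_counts(self):
        h = hc.Hypnogram(stages=[4])
        s = hc.hypnogram_to_hypnodensity(h, step_seconds=5)
        assert s.n_frames == 6
        assert np.all(s.probs == np.eye(5)[4])

    def test_step_not_dividing_epoch_raises(self):
        with pytest.raises(ValueError, match="divide"):
            hc.hypnogram_to_hypnodensity(hc.Hypnogram(stages=[0]), step_seconds=7)

    def test_artifact_epochs_dropped(self):
        h = hc.Hypnogram(stages=[0, 2], artifact_mask=[False, True])
        s = hc.hypnogram_to_hypnodensity(h, step_seconds=30)
        assert s.n_frames == 1
        np.testing.assert_array_equal(s.probs[0], np.eye(5)[0])

    def test_split_gap_policy_keeps_timestamps(self):
        h = hc.Hypnogram(stages=[0, 1, 2, 3], artifact_mask=[False, True, False, False])
        parts = hc.hypnogram_to_hypnodensity(h, step_seconds=30, gap_policy="split")
        assert [p.n_frames for p in parts] == [1, 2]
        assert parts[1].times[0] == pytest.approx(2 * 30 + 15)

    def test_argmax_collapse_and_tie_break(self):
        probs = np.array([[0.1, 0.1, 0.6, 0.1, 0.1], [0.5, 0.5, 0, 0, 0]])
        s = hc.HypnodensitySeries(times=[2.5, 7.5], probs=probs)
        h = hc.hypnodensity_to_hypnogram(s)
        assert list(h.stages) == [2, 0]  # ties go to the lowest stage index

    @given(st.lists(st.integers(0, 4), min_size=1, max_size=60), st.sampled_from([5, 10, 30]))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_round_trip_identity(self, stages, step):
        h = hc.Hypnogram(stages=np.array(stages))
        back = hc.hypnodensity_to_hypnogram(hc.hypnogram_to_hypnodensity(h, step_seconds=step))
        per_epoch = int(30 // step)
        np.testing.assert_array_equal(np.repeat(h.stages, per_epoch), back.stages)


class TestTrainTestSplit:
    def test_published_68_80_20_split(self):
        train, test = hc.train_test_split_datasets(68, 0.8, seed=0)
        assert train.size == 54 and test.size == 14

    def test_exact_fraction(self):
        train, test = hc.train_test_split_datasets(10, 0.8, seed=3)
        assert train.size == 8 and test.size == 2

    def test_partition_disjoint_exhaustive_deterministic(self):
        a = hc.train_test_split_datasets(25, 0.7, seed=11)
        b = hc.train_test_split_datasets(25, 0.7, seed=11)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])
        assert sorted(np.concatenate(a).tolist()) == list(range(25))

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.2, 1.5])
    def test_invalid_fraction_rejected(self, fraction):
        with pytest.raises(ValueError):
            hc.train_test_split_datasets(10, fraction)


class TestHypnodensityCsv:
    def test_round_trip_lossless(self, tmp_path):
        s = random_simplex_series(100, seed=7, channel="C4")
        path = tmp_path / "s.csv"
        hc.write_hypnodensity_csv(s, path)
        back = hc.read_hypnodensity_csv(path)
        np.testing.assert_allclose(back.probs, s.probs, atol=1e-12)
        np.testing.assert_allclose(back.times, s.times, atol=1e-12)
        assert back.channel == "C4"
        assert back.step_seconds == s.step_seconds

    def test_wrong_column_count_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_s,Wake,N1,N2,N3\n2.5,1,0,0,0\n")
        with pytest.raises(HypnodensityParseError, match="columns"):
            hc.read_hypnodensity_csv(path)

    def test_simplex_violation_rejected_on_load(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_s,Wake,N1,N2,N3,REM\n2.5,1.0,0.5,0,0,0\n")
        with pytest.raises(HypnodensityParseError, match="sum"):
            hc.read_hypnodensity_csv(path)

    def test_non_numeric_value_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_s,Wake,N1,N2,N3,REM\n2.5,1,0,0,0,0\n7.5,x,0,0,0,1\n")
        with pytest.raises(HypnodensityParseError, match="line 2"):
            hc.read_hypnodensity_csv(path)


class TestHypnogramTsv:
    def test_round_trip(self, tmp_path):
        h = hc.Hypnogram(stages=[0, 1, 2, 3, 4], artifact_mask=[0, 0, 1, 0, 0])
        path = tmp_path / "h.tsv"
        hc.write_hypnogram_tsv(h, path)
        back = hc.read_hypnogram_tsv(path)
        np.testing.assert_array_equal(back.stages, h.stages)
        np.testing.assert_array_equal(back.artifact_mask, h.artifact_mask)
        assert back.epoch_seconds == 30.0

    def test_unknown_stage_label_rejected(self, tmp_path):
        path = tmp_path / "h.tsv"
        path.write_text("epoch_index\tstage\tartifact\n0\tN9\t0\n")
        with pytest.raises(HypnodensityParseError, match="N9"):
            hc.read_hypnogram_tsv(path)


class TestTypes:
    def test_stage_set_requires_five_distinct(self):
        with pytest.raises(ValueError):
            hc.StageSet(labels=("W", "N1", "N2", "N3"))
        with pytest.raises(ValueError):
            hc.StageSet(labels=("W", "W", "N2", "N3", "REM"))

    def test_hypnogram_rejects_bad_stage_index(self):
        with pytest.raises(ValueError):
            hc.Hypnogram(stages=[0, 7])

    def test_mean_vector_on_simplex(self):
        s = random_simplex_series(50, seed=3)
        mv = s.mean_vector()
        assert mv.values.sum() == pytest.approx(1.0, abs=1e-9)
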
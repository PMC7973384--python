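"""Vectorial correlations, peak detection and period estimation."""

import numpy as np
import pytest

import hypnocycle as hc
from hypnocycle.correlation import CorrelationCurve
from hypnocycle.errors import DegenerateInputError

from conftest import oracle_lagged_correlation, random_simplex_series


class TestAutocorrelation:
    def test_lag_zero_is_exactly_one(self):
        for seed in range(5):
            s = random_simplex_series(80, seed=seed)
            curve = hc.autocorrelation(s, max_lag=100)
            assert curve.values[0] == 1.0

    def test_constant_series_degenerate(self):
        probs = np.tile(np.eye(5)[2], (40, 1))
        s = hc.HypnodensitySeries(times=2.5 + 5 * np.arange(40), probs=probs)
        with pytest.raises(DegenerateInputError):
            hc.autocorrelation(s, max_lag=50)

    def test_max_lag_beyond_duration_rejected(self):
        s = random_simplex_series(40, seed=0)
        with pytest.raises(ValueError, match="max_lag"):
            hc.autocorrelation(s, max_lag=1e6)

    def test_alternating_one_hot_matches_oracle(self):
        probs = np.tile(np.vstack([np.eye(5)[0], np.eye(5)[2]]), (20, 1))
        s = hc.HypnodensitySeries(times=2.5 + 5 * np.arange(40), probs=probs)
        curve = hc.autocorrelation(s, max_lag=50)
        expected = oracle_lagged_correlation(probs, probs, 11)
        np.testing.assert_allclose(curve.values, expected, atol=1e-12)
        # period-2 alternation: r alternates sign with maxima at even lags
        assert np.all(curve.values[::2] > 0) and np.all(curve.values[1::2] < 0)

    def test_agrees_with_double_loop_oracle_on_random_series(self):
        rng = np.random.default_rng(99)
        for _ in range(15):
            T = int(rng.integers(20, 200))
            s = random_simplex_series(T, seed=int(rng.integers(2**31)))
            n_lags = min(20, T - 1)
            curve = hc.autocorrelation(s, max_lag=(n_lags - 1) * 5.0)
            expected = oracle_lagged_correlation(s.probs, s.probs, n_lags)
            np.testing.assert_allclose(curve.values, expected, atol=1e-12)

    def test_stage_relabeling_invariance(self):
        s = random_simplex_series(60, seed=4)
        perm = np.array([3, 0, 4, 1, 2])
        sp = hc.HypnodensitySeries(times=s.times, probs=s.probs[:, perm])
        a = hc.autocorrelation(s, max_lag=80).values
        b = hc.autocorrelation(sp, max_lag=80).values
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestCrosscorrelation:
    def test_cross_with_self_equals_auto(self):
        s = random_simplex_series(100, seed=1)
        auto = hc.autocorrelation(s, max_lag=200)
        cross = hc.crosscorrelation(s, s, max_lag=200)
        np.testing.assert_allclose(cross.values, auto.values, atol=1e-12)

    def test_identical_channels_unit_at_lag_zero(self):
        s = random_simplex_series(100, seed=2, channel="C4")
        s2 = hc.HypnodensitySeries(
            times=s.times, probs=s.probs.copy(), channel="F4", step_seconds=s.step_seconds
        )
        curve = hc.crosscorrelation(s, s2, max_lag=100)
        assert curve.values[0] == pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_double_loop_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            T = int(rng.integers(20, 150))
            x = random_simplex_series(T, seed=int(rng.integers(2**31)))
            y = random_simplex_series(T, seed=int(rng.integers(2**31)))
            n_lags = min(15, T - 1)
            curve = hc.crosscorrelation(x, y, max_lag=(n_lags - 1) * 5.0)
            expected = oracle_lagged_correlation(x.probs, y.probs, n_lags)
            np.testing.assert_allclose(curve.values, expected, atol=1e-12)

    def test_lag_shift_recovered(self):
        # y delayed by k frames relative to x: argmax of r_xy at tau = k
        base = random_simplex_series(80, seed=5)
        k = 7
        x = hc.HypnodensitySeries(times=base.times[: 80 - k], probs=base.probs[k:])
        y = hc.HypnodensitySeries(times=base.times[: 80 - k], probs=base.probs[: 80 - k])
        curve = hc.crosscorrelation(x, y, max_lag=30 * 5.0)
        assert curve.lags[np.argmax(curve.values)] == pytest.approx(k * 5.0)

    def test_symmetric_curve_mirrors_swapped_arguments(self):
        x = random_simplex_series(60, seed=8, channel="a")
        y = random_simplex_series(60, seed=9, channel="b")
        sym = hc.crosscorrelation(x, y, max_lag=50, symmetric=True)
        swapped = hc.crosscorrelation(y, x, max_lag=50)
        neg = sym.values[sym.lags < 0][::-1]  # r_xy(-tau) for tau = 1..L
        np.testing.assert_allclose(neg, swapped.values[1:], atol=1e-12)

    def test_mismatched_step_rejected(self):
        x = random_simplex_series(40, seed=0, step=5.0)
        y = random_simplex_series(40, seed=1, step=30.0)
        with pytest.raises(ValueError, match="step"):
            hc.crosscorrelation(x, y)

    def test_trimming_to_common_span(self):
        x = random_simplex_series(60, seed=3)
        y_full = random_simplex_series(60, seed=4)
        y = hc.HypnodensitySeries(
            times=y_full.times[10:], probs=y_full.probs[10:], step_seconds=5.0
        )
        curve = hc.crosscorrelation(x, y, max_lag=40)
        assert curve.T == 50


class TestDetectLocalMaxima:
    @staticmethod
    def _cosine_curve(period_s: float, step: float = 5.0, n: int = 600) -> CorrelationCurve:
        lags = step * np.arange(n)
        return CorrelationCurve(
            lags=lags, values=np.cos(2 * np.pi * lags / period_s),
            kind="auto", step_seconds=step, T=n,
        )

    def test_cosine_maxima_at_multiples_of_period(self):
        period = 600.0
        curve = self._cosine_curve(period)
        est = hc.detect_local_maxima(curve, min_lag=period / 2, smooth_width=30.0,
                                     min_prominence=0.05)
        assert est.found
        for i, lag in enumerate(est.maxima_lags[:3], start=1):
            assert abs(lag - i * period) <= curve.step_seconds

    def test_monotone_decreasing_curve_reports_no_cycle(self):
        lags = 5.0 * np.arange(200)
        curve = CorrelationCurve(lags=lags, values=np.exp(-lags / 100), kind="auto",
                                 step_seconds=5.0)
        est = hc.detect_local_maxima(curve, min_lag=30.0)
        assert not est.found
        assert est.status == "no cycle detected"
        assert est.period_seconds is None

    def test_min_lag_must_be_positive(self):
        with pytest.raises(ValueError, match="min_lag"):
            hc.detect_local_maxima(self._cosine_curve(600.0), min_lag=0.0)

    def test_period_is_first_maximum(self):
        curve = self._cosine_curve(900.0)
        est = hc.detect_local_maxima(curve, min_lag=450.0, smooth_width=30.0,
                                     min_prominence=0.05)
        assert est.period_seconds == est.maxima_lags[0]


class TestPeriodRecovery:
    @pytest.mark.parametrize("period_min", [60, 75, 90, 100, 120])
    def test_first_maximum_within_one_step_in_90pct_of_runs(self, period_min):
        """Full pipeline: cyclic night -> noisy hypnodensity -> correlation ->
        first local maximum lands on the nominal period for >= 90% of nights."""
        period_s = period_min * 60.0
        hits = 0
        second_devs = []
        n_runs = 50
        for seed in range(n_runs):
            model = hc.CyclicSleepModel(cycle_period=period_s)
            h = hc.simulate_hypnogram(model, seed=seed)
            s = hc.simulate_noisy_hypnodensity(h, seed=seed + 1000)
            curve = hc.autocorrelation(s, max_lag=240 * 60.0)
            est = hc.detect_local_maxima(curve, min_lag=30 * 60.0)
            if est.found:
                hits += abs(est.maxima_lags[0] - period_s) <= s.step_seconds + 1e-9
                if 2 * period_s < 240 * 60.0 and len(est.maxima_lags) > 1:
                    second_devs.append(est.maxima_lags[1] - 2 * period_s)
        assert hits >= 0.9 * n_runs
        if 2 * period_s < 240 * 60.0:
            # the repeat at 2P: its run-median lies within two lag steps
            assert abs(np.median(second_devs)) <= 2 * 5.0 + 1e-9

    def test_multichannel_cross_peaks_at_lag_zero(self):
        h = hc.simulate_hypnogram(hc.CyclicSleepModel(cycle_period=90 * 60.0), seed=3)
        chans = hc.simulate_multichannel(h, channels=("C4", "F4", "O2"), seed=4)
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                curve = hc.crosscorrelation(chans[i], chans[j], max_lag=60 * 60.0,
                                            symmetric=True)
                assert curve.lags[np.argmax(curve.values)] == 0.0


class TestChannelSummary:
    def test_identical_channels_give_identical_unit_curves(self):
        base = random_simplex_series(120, seed=6)
        chans = [
            hc.HypnodensitySeries(times=base.times, probs=base.probs.copy(), channel=c)
            for c in ("C4", "F4", "O2")
        ]
        summary = hc.channel_correlation_summary(chans, max_lag=100)
        ref = summary[("C4", "C4")].values
        for key, curve in summary.items():
            np.testing.assert_allclose(curve.values, ref, atol=1e-12)
            assert curve.values[0] == pytest.approx(1.0, abs=1e-12)
        assert len(summary) == 9

    def test_diagonal_equals_autocorrelation(self):
        chans = [random_simplex_series(100, seed=s, channel=f"ch{s}") for s in range(2)]
        summary = hc.channel_correlation_summary(chans, max_lag=80)
        for s in chans:
            auto = hc.autocorrelation(s, max_lag=80)
            np.testing.assert_allclose(
                summary[(s.channel, s.channel)].values, auto.values, atol=1e-12
            )


class TestWindowedPeriodTrack:
    def test_single_part_reduces_to_global_estimate(self):
        h = hc.simulate_hypnogram(hc.CyclicSleepModel(cycle_period=90 * 60.0), seed=0)
        s = hc.simulate_noisy_hypnodensity(h, seed=1)
        track = hc.windowed_period_track(s, part_duration=s.duration_seconds)
        assert len(track) == 1
        global_est = hc.detect_local_maxima(hc.autocorrelation(s))
        assert track[0][1].period_seconds == global_est.period_seconds

    def test_stationary_night_gives_consistent_parts(self):
        model = hc.CyclicSleepModel(cycle_period=90 * 60.0, total_duration=9 * 3600.0,
                                    dwell_jitter=0.0, wake_insertion_rate=0.0)
        h = hc.simulate_hypnogram(model, seed=10)
        s = hc.simulate_noisy_hypnodensity(h, seed=11)
        track = hc.windowed_period_track(
            s, part_duration=3 * 3600.0, max_lag=120 * 60.0, min_lag=60 * 60.0
        )
        periods = [est.period_seconds for _, est in track if est.found]
        assert len(periods) == 3
        assert max(periods) - min(periods) <= s.step_seconds + 1e-9

    def test_lengthening_cycles_give_increasing_estimates(self):
        # three 3-h thirds with 70/90/110-min cycles stitched together
        parts = []
        for i, pm in enumerate((70, 90, 110)):
            model = hc.CyclicSleepModel(cycle_period=pm * 60.0, total_duration=3 * 3600.0,
                                        wake_insertion_rate=0.0)
            h = hc.simulate_hypnogram(model, seed=20 + i)
            parts.append(hc.simulate_noisy_hypnodensity(h, seed=30 + i).probs)
        probs = np.concatenate(parts)
        s = hc.HypnodensitySeries(times=2.5 + 5.0 * np.arange(len(probs)), probs=probs)
        track = hc.windowed_period_track(
            s, part_duration=3 * 3600.0, max_lag=130 * 60.0, min_lag=50 * 60.0
        )
        periods = [est.period_seconds for _, est in track]
        assert all(p is not None for p in periods)
        assert periods[0] < periods[1] < periods[2]

    def test_part_longer_than_record_rejected(self):
        s = random_simplex_series(100, seed=0)
        with pytest.raises(ValueError, match="part_duration"):
            hc.windowed_period_track(s, part_duration=1e6)

    def test_short_parts_warn_against_expected_period(self):
        s = random_simplex_series(2000, seed=0)
        with pytest.warns(UserWarning, match="4x"):
            hc.windowed_period_track(
                s, part_duration=2000.0, expected_period=1000.0, min_lag=100.0
            )
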
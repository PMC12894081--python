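import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from mmscoord import (AngleSeries, CrossCorrelogram, WindowSpec,
                      average_correlogram, classify_strength,
                      coefficient_of_determination, cross_correlogram,
                      normality_gate, peak_lag, rolling_cross_correlogram,
                      summarize_lags, windowed_pearson)
from tests.conftest import sine_series


def naive_pearson(x, y):
    """Two-pass textbook oracle for the windowed correlation."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    mx, my = sum(x) / len(x), sum(y) / len(y)
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = math.sqrt(sum((a - mx) ** 2 for a in x))
    dy = math.sqrt(sum((b - my) ** 2 for b in y))
    return num / (dx * dy)


def shifted_pair(lead_s, rate=10.0, duration=60.0, period=8.0):
    steer = sine_series(period, duration, rate)
    head = sine_series(period, duration, rate, phase_s=lead_s, channel="head_yaw")
    return head, steer


class TestWindowedPearson:
    def test_self_correlation_is_one(self):
        assert windowed_pearson([1, 2, 3], [1, 2, 3]) == 1.0

    def test_exact_anticorrelation(self):
        assert windowed_pearson([1, 2, 3], [3, 2, 1]) == -1.0

    def test_hand_computed_example(self):
        assert windowed_pearson([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            windowed_pearson([1, 2, 3], [1, 2])

    def test_zero_variance_is_undefined_not_zero(self):
        assert np.isnan(windowed_pearson([5, 5, 5], [1, 2, 3]))

    @given(arrays(np.float64, st.integers(3, 60),
                  elements=st.floats(-1e3, 1e3, allow_nan=False)),
           st.integers(0, 2 ** 31 - 1))
    @settings(deadline=None, max_examples=500, derandomize=True)
    def test_matches_naive_two_pass_oracle(self, x, seed):
        y = np.random.default_rng(seed).normal(size=x.size)
        if np.std(x) == 0 or np.std(y) == 0:
            return
        got = windowed_pearson(x, y)
        assert got == pytest.approx(naive_pearson(x, y), abs=1e-12)
        assert -1.0 <= got <= 1.0


class TestCrossCorrelogram:
    def test_identical_series_peak_at_zero(self):
        head, steer = shifted_pair(0.0)
        lag, r = peak_lag(cross_correlogram(head, steer))
        assert lag == 0.0 and r == pytest.approx(1.0)

    def test_constructed_shift_peaks_at_minus_lead(self):
        head, steer = shifted_pair(0.4)
        lag, r = peak_lag(cross_correlogram(head, steer))
        assert lag == pytest.approx(-0.4)
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_sinusoid_secondary_peaks_outside_range(self):
        # period 8 s, offset 1 s: within +-5 s only the -1 s peak survives
        head, steer = shifted_pair(1.0, period=8.0, duration=120.0)
        c = cross_correlogram(head, steer)
        lag, _ = peak_lag(c)
        assert lag == pytest.approx(-1.0)
        assert np.max(np.abs(c.lags)) <= 5.0 + 1e-9

    def test_short_series_rejected(self):
        head, steer = shifted_pair(0.4, duration=10.0)
        with pytest.raises(ValueError, match="window"):
            cross_correlogram(head, steer)

    def test_antisymmetry_swapping_series_negates_lag(self):
        head, steer = shifted_pair(0.6)
        lag_fwd, _ = peak_lag(cross_correlogram(head, steer))
        lag_rev, _ = peak_lag(cross_correlogram(steer, head))
        assert lag_fwd == pytest.approx(-lag_rev, abs=0.1 + 1e-9)

    def test_rate_mismatch_rejected(self):
        head = sine_series(8.0, 60.0, 10.0, channel="head_yaw")
        steer = sine_series(8.0, 60.0, 20.0)
        with pytest.raises(ValueError, match="rate"):
            cross_correlogram(head, steer)


class TestPeakLag:
    def test_unique_maximum_returned(self):
        lags = np.arange(-5, 6) / 10.0
        r = -np.abs(lags + 0.4)
        lag, rv = peak_lag(CrossCorrelogram(lags, r, 10.0))
        assert lag == pytest.approx(-0.4) and rv == pytest.approx(0.0)

    def test_symmetric_tie_breaks_to_negative_smallest_lag(self):
        lags = np.array([-0.4, -0.2, 0.0, 0.2, 0.4])
        r = np.array([0.1, 0.9, 0.5, 0.9, 0.1])
        lag, _ = peak_lag(CrossCorrelogram(lags, r, 5.0))
        assert lag == -0.2

    def test_all_undefined_rejected(self):
        c = CrossCorrelogram(np.array([-0.1, 0.0, 0.1]),
                             np.full(3, np.nan), 10.0)
        with pytest.raises(ValueError):
            peak_lag(c)

    def test_parabolic_refinement_recovers_subsample_lag(self):
        # truth 0.45 s is between samples at 10 Hz; compare against the
        # correlogram of the same pair sampled at 1 kHz
        head, steer = shifted_pair(0.45, rate=10.0, duration=120.0)
        lag, _ = peak_lag(cross_correlogram(head, steer), refine=True)
        head_hi, steer_hi = shifted_pair(0.45, rate=1000.0, duration=120.0)
        oracle, _ = peak_lag(cross_correlogram(head_hi, steer_hi))
        assert oracle == pytest.approx(-0.45, abs=1e-3)
        assert lag == pytest.approx(oracle, abs=0.02)


class TestRollingCorrelogram:
    def test_epoch_count_formula(self):
        head, steer = shifted_pair(0.0, duration=100.0)
        rc = rolling_cross_correlogram(head, steer, WindowSpec(20.0, 1.0, 5.0))
        assert rc.epoch_starts.size == 81

    def test_stationary_coupling_gives_constant_peak_trace(self):
        head, steer = shifted_pair(0.5, duration=80.0)
        rc = rolling_cross_correlogram(head, steer)
        assert np.all(rc.defined)
        assert np.allclose(rc.peak_lags, -0.5, atol=1e-9)

    def test_two_regime_coupling_steps_in_peak_trace(self):
        rate, dur = 10.0, 120.0
        t = np.arange(int(dur * rate)) / rate
        steer_v = 20 * np.sin(2 * np.pi * t / 8.0)
        half = t.size // 2
        head_v = np.empty_like(steer_v)
        head_v[:half] = 20 * np.sin(2 * np.pi * (t[:half] + 0.8) / 8.0)
        head_v[half:] = 20 * np.sin(2 * np.pi * (t[half:] + 0.4) / 8.0)
        steer = AngleSeries(t, steer_v, rate, "steering")
        head = AngleSeries(t, head_v, rate, "head_yaw")
        rc = rolling_cross_correlogram(head, steer)
        early = rc.peak_lags[rc.epoch_starts < 30.0]
        late = rc.peak_lags[rc.epoch_starts > 70.0]
        assert np.allclose(early, -0.8, atol=1e-9)
        assert np.allclose(late, -0.4, atol=1e-9)

    def test_zero_variance_epochs_masked(self):
        rate = 10.0
        t = np.arange(600) / rate
        flat = AngleSeries(t, np.zeros(600), rate, "steering")
        wavy = AngleSeries(t, np.sin(t), rate, "head_yaw")
        rc = rolling_cross_correlogram(wavy, flat)
        assert not rc.defined.any()


class TestAverageCorrelogram:
    def _c(self, r):
        lags = np.arange(-2, 3) / 10.0
        return CrossCorrelogram(lags, np.asarray(r, float), 10.0)

    def test_identical_trials_have_zero_sd(self):
        trials = [self._c([0.1, 0.5, 0.9, 0.5, 0.1])] * 5
        _, mean, sd, count = average_correlogram(trials)
        assert np.allclose(mean, trials[0].r)
        assert np.allclose(sd, 0.0)
        assert np.all(count == 5)

    def test_two_trial_sample_sd(self):
        trials = [self._c([0.2] * 5), self._c([0.6] * 5)]
        _, mean, sd, _ = average_correlogram(trials)
        assert np.allclose(mean, 0.4)
        assert np.allclose(sd, 0.2828, atol=1e-4)

    def test_single_trial_sd_undefined(self):
        _, mean, sd, _ = average_correlogram([self._c([0.1, 0.2, 0.3, 0.2, 0.1])])
        assert np.all(np.isnan(sd))
        assert np.allclose(mean, [0.1, 0.2, 0.3, 0.2, 0.1])

    def test_undefined_cells_excluded_pairwise(self):
        a = self._c([0.2, np.nan, 0.4, 0.2, 0.2])
        b = self._c([0.6, 0.5, np.nan, 0.4, 0.2])
        _, mean, _, count = average_correlogram([a, b])
        assert count.tolist() == [2, 1, 1, 2, 2]
        assert mean[1] == pytest.approx(0.5)

    def test_mismatched_axes_rejected(self):
        a = self._c([0.1] * 5)
        b = CrossCorrelogram(np.arange(-3, 4) / 10.0, np.zeros(7), 10.0)
        with pytest.raises(ValueError, match="lag axes"):
            average_correlogram([a, b])


class TestStrengthAndR2:
    @pytest.mark.parametrize("r,label", [
        (0.79, "strong"),
        (0.25, "very weak"),
        (-0.91, "very strong"),
        (0.30, "very weak"),
        (0.31, "weak"),
        (0.50, "weak"),
        (0.51, "moderate"),
        (0.70, "moderate"),
        (0.71, "strong"),
        (0.90, "strong"),
        (1.00, "very strong"),
        (0.0, "very weak"),
    ])
    def test_strength_bands(self, r, label):
        assert classify_strength(r) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_strength(1.2)

    @pytest.mark.parametrize("r,r2", [(0.79, 0.624), (1.0, 1.0), (0.5, 0.25)])
    def test_coefficient_of_determination(self, r, r2):
        assert coefficient_of_determination(r) == pytest.approx(r2)


class TestNormalityGate:
    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            normality_gate([1.0, 2.0])

    def test_gaussian_sample_passes(self):
        x = np.random.default_rng(42).normal(size=500)
        w, p, ok = normality_gate(x)
        assert ok and p >= 0.05 and 0.9 < w <= 1.0

    def test_type_one_error_rate_near_alpha(self):
        rng = np.random.default_rng(7)
        rejections = sum(
            not normality_gate(rng.normal(size=100))[2] for _ in range(200))
        assert abs(rejections / 200 - 0.05) <= 0.03

    def test_skewed_sample_fails(self):
        x = np.random.default_rng(0).exponential(size=500)
        assert not normality_gate(x)[2]


class TestSummarizeLags:
    def test_quarter_turn_row(self):
        s = summarize_lags([(-0.8, 0.90), (-0.6, 0.88), (-1.0, 0.89)],
                           "quarter_turn")
        assert round(s.lag_mean, 2) == -0.80
        assert round(s.lag_sd, 2) == 0.20
        assert round(s.r_mean, 2) == 0.89
        assert round(s.r_sd, 2) == 0.01

    def test_left_curving_row(self):
        s = summarize_lags([(-0.4, 0.92), (-0.6, 0.89), (-0.45, 0.93)])
        assert round(s.lag_mean, 2) == -0.48
        assert round(s.lag_sd, 2) == 0.10

    def test_identical_lags_zero_sd(self):
        s = summarize_lags([(-0.5, 0.9), (-0.5, 0.8)])
        assert s.lag_sd == 0.0

    def test_single_entry_sd_undefined(self):
        s = summarize_lags([(-0.5, 0.9)])
        assert math.isnan(s.lag_sd) and math.isnan(s.r_sd)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_lags([])
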
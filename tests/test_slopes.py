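"""Slope pipeline: window extraction, OLS fits, unit conversion, background
correction — checked against closed-form oracles and simulator truth."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import shoalresp as sr
from conftest import piecewise_trace


def closed_form_ols(t, y):
    """Normal-equation OLS via explicit sums; independent of scipy."""
    n = len(t)
    sx, sy = np.sum(t), np.sum(y)
    sxx, sxy = np.sum(t * t), np.sum(t * y)
    syy = np.sum(y * y)
    slope = (n * sxy - sx * sy) / (n * sxx - sx**2)
    intercept = (sy - slope * sx) / n
    denom = (n * sxx - sx**2) * (n * syy - sy**2)
    r2 = (n * sxy - sx * sy) ** 2 / denom if denom > 0 else 0.0
    return slope, intercept, r2


class TestExtractWindows:
    def test_540s_period_minus_1min_each_side(self, chamber):
        trace = piecewise_trace(chamber, [0.5])
        (w,) = sr.extract_windows(trace)
        assert (w.start_s, w.end_s) == (60.0, 480.0)
        assert w.time_s[0] == 60.0 and w.time_s[-1] == 478.0
        assert w.end_s - w.start_s == 420.0

    def test_zero_exclusion_keeps_full_period(self, chamber):
        trace = piecewise_trace(chamber, [0.5])
        (w,) = sr.extract_windows(trace, exclusion_s=0.0)
        assert (w.start_s, w.end_s) == (0.0, 540.0)
        assert len(w.time_s) == 270

    def test_short_period_dropped_with_warning(self, chamber):
        short = sr.ChamberSpec(measure_duration=100.0, flush_duration=60.0,
                               sample_interval=2.0)
        trace = piecewise_trace(short, [0.5, 0.5])
        with pytest.warns(UserWarning, match="dropped"):
            windows = sr.extract_windows(trace, exclusion_s=60.0,
                                         min_window_s=120.0)
        assert windows == []


class TestFitSlope:
    def test_exact_line_recovered(self, chamber):
        t = np.arange(0.0, 420.0, 2.0)
        o2 = 8.0 - 0.5 * (t / 3600.0)
        w = sr.Window(0, 0.0, 420.0, t, o2)
        est = sr.fit_slope(w)
        assert est.slope == pytest.approx(-0.5, rel=1e-12)
        assert est.intercept == pytest.approx(8.0, rel=1e-12)
        assert est.r_squared == pytest.approx(1.0, abs=1e-12)
        assert est.qc_pass

    def test_flat_response_defined_as_zero_r2(self):
        t = np.arange(0.0, 100.0, 2.0)
        w = sr.Window(0, 0.0, 100.0, t, np.full(t.size, 6.0))
        est = sr.fit_slope(w)
        assert est.slope == 0.0
        assert est.r_squared == 0.0
        assert not est.qc_pass

    def test_identical_timestamps_singular(self):
        w = sr.Window(0, 0.0, 10.0, np.zeros(5), np.arange(5.0))
        with pytest.raises(sr.SingularFitError):
            sr.fit_slope(w)

    def test_too_few_samples(self):
        w = sr.Window(0, 0.0, 4.0, np.array([0.0, 2.0]), np.array([6.0, 5.9]))
        with pytest.raises(sr.InsufficientDataError):
            sr.fit_slope(w)

    def test_21_noisy_samples_match_closed_form_to_1e10(self):
        rng = np.random.default_rng(42)
        t = np.arange(0.0, 42.0, 2.0)
        o2 = 7.5 - 1.2e-4 * t + rng.normal(0, 0.01, t.size)
        est = sr.fit_slope(sr.Window(0, 0.0, 42.0, t, o2))
        slope, intercept, r2 = closed_form_ols(t, o2)
        assert est.slope == pytest.approx(slope * 3600.0, rel=1e-10)
        assert est.intercept == pytest.approx(intercept, rel=1e-10)
        assert est.r_squared == pytest.approx(r2, rel=1e-10)

    @settings(max_examples=60, derandomize=True)
    @given(st.integers(0, 10**6), st.integers(5, 60))
    def test_matches_normal_equations_on_random_windows(self, seed, n):
        rng = np.random.default_rng(seed)
        t = np.sort(rng.uniform(0, 500, n))
        if np.ptp(t) == 0:
            return
        o2 = rng.uniform(5, 8) - rng.uniform(0, 2e-4) * t + rng.normal(0, 0.02, n)
        est = sr.fit_slope(sr.Window(0, t[0], t[-1], t, o2))
        slope, intercept, _ = closed_form_ols(t, o2)
        assert est.slope == pytest.approx(slope * 3600.0, rel=1e-9, abs=1e-12)
        assert est.intercept == pytest.approx(intercept, rel=1e-9)


class TestSlopeToMo2:
    def _est(self, slope):
        return sr.SlopeEstimate(0, 60.0, 480.0, slope=slope, intercept=8.0,
                                r_squared=1.0, n_samples=210, qc_pass=True)

    def test_hand_arithmetic_with_fish_volume(self, chamber):
        est = sr.slope_to_mo2(self._est(-0.5), chamber, 1.84)
        assert est.mo2 == pytest.approx(0.5 * 0.09816, rel=1e-12)

    def test_hand_arithmetic_without_fish_volume(self, chamber):
        est = sr.slope_to_mo2(self._est(-0.5), chamber, 1.84,
                              subtract_fish_volume=False)
        assert est.mo2 == pytest.approx(0.05, rel=1e-12)

    def test_zero_slope_zero_mo2(self, chamber):
        assert sr.slope_to_mo2(self._est(0.0), chamber, 1.84).mo2 == 0.0

    def test_fish_larger_than_chamber(self, chamber):
        with pytest.raises(sr.PhysicallyImpossibleError):
            sr.slope_to_mo2(self._est(-0.5), chamber, 120.0)


class TestFitBackground:
    def test_flat_traces_give_zero_rates(self, chamber):
        flat = piecewise_trace(chamber, [0.0, 0.0, 0.0])
        bg = sr.fit_background(flat, flat, chamber)
        assert (bg.rate_pre, bg.rate_post) == (0.0, 0.0)

    def test_mean_of_three_period_rates(self, chamber):
        pre = piecewise_trace(chamber, [0.001, 0.002, 0.003])
        post = piecewise_trace(chamber, [0.004, 0.004, 0.004])
        bg = sr.fit_background(pre, post, chamber)
        assert bg.rate_pre == pytest.approx(0.002, rel=1e-9)
        assert bg.rate_post == pytest.approx(0.004, rel=1e-9)

    def test_simulated_rates_recovered_within_noise(self, chamber):
        cfg = sr.SimulationConfig(seed=7, background_rate_start=0.002,
                                  background_rate_end=0.010)
        pre = sr.simulate_background_trial(chamber, cfg, "pre")
        post = sr.simulate_background_trial(chamber, cfg, "post")
        bg = sr.fit_background(pre, post, chamber)
        assert bg.rate_pre == pytest.approx(0.002, abs=0.002)
        assert bg.rate_post == pytest.approx(0.010, abs=0.002)

    def test_unusable_trace_raises(self, chamber):
        short = piecewise_trace(chamber, [0.001])
        broken = sr.O2Trace(short.time_s, short.o2_mgL,
                            np.full(len(short), "flush", dtype=object),
                            chamber=chamber)
        with pytest.raises(sr.InsufficientDataError):
            sr.fit_background(broken, short, chamber)


class TestCorrectBackground:
    def _ests(self, mo2s, t_mids):
        return [sr.SlopeEstimate(i, t - 210.0, t + 210.0, slope=-1.0,
                                 intercept=8.0, r_squared=1.0, n_samples=210,
                                 mo2=m, qc_pass=True)
                for i, (m, t) in enumerate(zip(mo2s, t_mids))]

    def test_zero_rates_identity(self):
        ests = self._ests([0.5, 0.4], [1000.0, 2000.0])
        out = sr.correct_background(ests, sr.BackgroundModel(0.0, 0.0),
                                    0.0, 3600.0)
        assert [e.mo2 for e in out] == [0.5, 0.4]
        assert all(e.corrected for e in out)

    def test_midpoint_subtracts_half_the_end_rate(self):
        ests = self._ests([0.5], [1800.0])
        out = sr.correct_background(ests, sr.BackgroundModel(0.0, 0.010),
                                    0.0, 3600.0)
        assert out[0].mo2 == pytest.approx(0.5 - 0.005, rel=1e-12)

    def test_correction_monotone_for_nonnegative_rates(self):
        ests = self._ests([0.5, 0.4, 0.3], [500.0, 1500.0, 2500.0])
        out = sr.correct_background(ests, sr.BackgroundModel(0.002, 0.01),
                                    0.0, 3600.0)
        assert all(c.mo2 <= e.mo2 for c, e in zip(out, ests))

    def test_invalid_interval(self):
        with pytest.raises(sr.InvalidIntervalError):
            sr.correct_background(self._ests([0.5], [100.0]),
                                  sr.BackgroundModel(0.0, 0.0), 100.0, 100.0)

    def test_negative_corrected_floored_with_warning(self):
        ests = self._ests([0.001], [1800.0])
        with pytest.warns(UserWarning, match="floored"):
            out = sr.correct_background(ests, sr.BackgroundModel(0.01, 0.01),
                                        0.0, 3600.0)
        assert out[0].mo2 == 0.0


class TestEndToEnd:
    def test_noiseless_recovery_within_0p1_percent(self, chamber, mean_fish,
                                                   noiseless_config):
        """Corrected MO2 equals floor + stress(midpoint) in every window."""
        cfg = noiseless_config
        trace, truth = sr.simulate_trial(chamber, mean_fish, "shoal", cfg)
        pre = sr.simulate_background_trial(chamber, cfg, "pre")
        post = sr.simulate_background_trial(chamber, cfg, "post")
        slopes = sr.process_trial(trace, pre, post, chamber, mean_fish.mass_g)
        t_mid_h = slopes["t_mid_s"].to_numpy() / 3600.0
        expected = (truth.floor_shoal + truth.stress_amplitude
                    * np.exp(-t_mid_h / truth.stress_tau_h))
        rel = np.abs(slopes["mo2_corrected"].to_numpy() - expected) / expected
        assert rel.max() <= 1e-3

    def test_background_correction_improves_accuracy(self, chamber, mean_fish):
        """With drift on, the corrected overnight mean is closer to the
        truth floor than the raw mean, across >= 20 seeds."""
        wins = 0
        for seed in range(1, 21):
            cfg = sr.SimulationConfig(seed=seed, stress_amplitude=0.0,
                                      background_rate_start=0.005,
                                      background_rate_end=0.030,
                                      trial_duration=6.0)
            trace, truth = sr.simulate_trial(chamber, mean_fish, "solitary", cfg)
            pre = sr.simulate_background_trial(chamber, cfg, "pre", seed_key=seed)
            post = sr.simulate_background_trial(chamber, cfg, "post", seed_key=seed)
            slopes = sr.process_trial(trace, pre, post, chamber, mean_fish.mass_g)
            err_raw = abs(slopes["mo2_raw"].mean() - truth.floor_solitary)
            err_cor = abs(slopes["mo2_corrected"].mean() - truth.floor_solitary)
            wins += err_cor < err_raw
        assert wins >= 19

    def test_default_noise_trials_pass_qc_everywhere(self, default_slopes):
        assert (default_slopes["r2"] > 0.97).all()
        assert default_slopes["qc_pass"].all()
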
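"""Trace preprocessing, peak metrics, cosine fitting and circular statistics."""

import warnings

import numpy as np
import pytest

from clockworks import synthetic as syn, traces
from clockworks.traces import PeakSet, Trace


def make_trace(t, v, epochs=None):
    return Trace(time_h=np.asarray(t, float), value=np.asarray(v, float),
                 epochs=epochs or {})


class TestDetrend:
    def test_pure_line_removed(self):
        t = np.arange(0, 120, 0.5)
        tr = make_trace(t, 2 * t + 5, {"baseline": (0.0, 120.0)})
        out = traces.detrend(tr, 72.0)
        region = out.time_h >= 120 - 72
        np.testing.assert_allclose(out.value[region], 0.0, atol=1e-9)

    def test_line_plus_cosine_leaves_cosine(self):
        # window phased so the cosine is orthogonal to the line fit
        t = np.arange(0, 192, 0.5)
        cos = np.cos(2 * np.pi * (t - 6) / 24)
        tr = make_trace(t, 0.3 * t + 4 + cos, {"baseline": (0.0, 126.0)})
        out = traces.detrend(tr, 72.0)
        region = out.time_h >= 54
        np.testing.assert_allclose(out.value[region], cos[region], atol=0.02)

    def test_fitted_slope_matches_generator_drift(self):
        spec = syn.TraceSimSpec(duration_h=120, dt_h=0.1, period_h=24, phase_h=6,
                                amplitude=1.0, drift_slope=0.8, drift_intercept=10,
                                noise_sd=0.05, seed=2)
        tr = syn.simulate_trace(spec)
        out = traces.detrend(tr, 96.0)
        # residual over the fit window should be close to the zero-mean cosine
        region = (out.time_h >= 24) & (out.time_h <= 120)
        assert abs(np.mean(out.value[region])) < 0.05

    def test_short_baseline_is_error(self):
        tr = make_trace(np.arange(0, 50, 0.5), np.zeros(100),
                        {"baseline": (0.0, 50.0)})
        with pytest.raises(ValueError, match="shorter"):
            traces.detrend(tr, 72.0)


class TestSmooth:
    def test_constant_unchanged(self):
        tr = make_trace(np.arange(10.0), np.full(10, 3.0))
        np.testing.assert_allclose(traces.smooth(tr, 5).value, 3.0)

    def test_impulse_spread(self):
        tr = make_trace(np.arange(5.0), [0, 0, 5, 0, 0])
        out = traces.smooth(tr, 5)
        assert out.value[2] == pytest.approx(1.0)

    def test_variance_nonincreasing(self):
        rng = np.random.default_rng(0)
        tr = make_trace(np.arange(200.0), rng.normal(size=200))
        once = traces.smooth(tr, 5)
        twice = traces.smooth(once, 5)
        assert once.value.var() <= tr.value.var()
        assert twice.value.var() <= once.value.var()

    def test_even_or_long_window_rejected(self):
        tr = make_trace(np.arange(10.0), np.zeros(10))
        with pytest.raises(ValueError):
            traces.smooth(tr, 4)
        with pytest.raises(ValueError):
            traces.smooth(tr, 11)


class TestFindPeaks:
    def test_noiseless_cosine_five_peaks(self, clean_cosine_trace):
        pk = traces.find_peaks_troughs(clean_cosine_trace)
        np.testing.assert_allclose(pk.peak_times_h, [6, 30, 54, 78, 102], atol=0.05)
        np.testing.assert_allclose(pk.trough_times_h, [18, 42, 66, 90, 114], atol=0.05)

    def test_close_lesser_peak_dropped(self):
        t = np.arange(0, 60, 0.5)
        v = np.exp(-((t - 20) ** 2) / 8) + 0.6 * np.exp(-((t - 30) ** 2) / 8)
        tr = make_trace(t, v)
        pk = traces.find_peaks_troughs(tr, min_separation_h=16)
        assert pk.n_peaks == 1
        assert pk.peak_times_h[0] == pytest.approx(20, abs=0.5)

    def test_noisy_peaks_near_truth(self):
        spec = syn.TraceSimSpec(duration_h=130, dt_h=0.1, period_h=24, phase_h=6,
                                amplitude=1.0, noise_sd=0.05, seed=3)
        tr = syn.simulate_trace(spec)
        pk = traces.find_peaks_troughs(traces.smooth(tr, 25))
        truth = tr.truth["true_peak_times_h"]
        for pt in pk.peak_times_h:
            assert np.min(np.abs(truth - pt)) < 0.5

    def test_alternation_enforced(self):
        with pytest.raises(ValueError, match="alternate"):
            PeakSet([1.0, 2.0], [1.0, 1.0], [3.0], [0.0])


class TestPeriodAndShift:
    def test_period_from_equally_spaced_peaks(self):
        pk = PeakSet([0.0, 24.0, 48.0], [1, 1, 1], [12.0, 36.0], [0, 0])
        assert traces.compute_period(pk) == 24.0

    def test_delta_period_sign(self):
        assert traces.delta_period(24.0, 24.8) == pytest.approx(0.8)

    def test_phase_shift_arithmetic(self):
        # last pre-peak 100 h, baseline period 24 h, observed second
        # post-treatment peak at 151 h -> 3 h delay (negative)
        pk = PeakSet([76.0, 100.0, 127.0, 151.0], [1] * 4,
                     [88.0, 113.0, 139.0], [0] * 3)
        assert traces.phase_shift(pk, 24.0, 110.0) == pytest.approx(-3.0)

    def test_zero_shift_when_on_schedule(self):
        pk = PeakSet([100.0, 124.0, 148.0], [1] * 3, [112.0, 136.0], [0] * 2)
        assert traces.phase_shift(pk, 24.0, 110.0) == pytest.approx(0.0)

    def test_insufficient_peaks_flagged(self):
        pk = PeakSet([100.0], [1.0], [], [])
        with pytest.warns(UserWarning):
            assert np.isnan(traces.phase_shift(pk, 24.0, 110.0))

    def test_generator_phase_offsets_recovered(self):
        base = dict(duration_h=288, dt_h=0.1, period_h=24.8, phase_h=6,
                    amplitude=1.0, noise_sd=0.02)
        for offset, seed in ((+2.0, 5), (-3.0, 6)):
            ep = syn.EpochEffect(start_h=133, end_h=288, phase_offset_h=offset)
            tr = syn.simulate_trace(syn.TraceSimSpec(**base, epochs=[ep], seed=seed))
            pk = traces.find_peaks_troughs(traces.smooth(tr, 25))
            baseline_period = traces.compute_period(pk, (0, 133))
            shift = traces.phase_shift(pk, baseline_period, 133)
            assert shift == pytest.approx(offset, abs=0.5)
            assert np.sign(shift) == np.sign(offset)


class TestAmplitudesAndBa:
    def test_stationary_oscillation_unit_amplitude_and_ba(self, clean_cosine_trace):
        pk = traces.find_peaks_troughs(clean_cosine_trace)
        amps = traces.cycle_amplitudes(pk, treatment_start_h=60.0)
        complete = amps.dropna()
        np.testing.assert_allclose(complete["normalized_amplitude"], 1.0, atol=1e-3)
        ba = traces.ba_ratio(pk)
        np.testing.assert_allclose(ba["ba_ratio"], 1.0, atol=1e-3)

    def test_scale_invariance(self, clean_cosine_trace):
        tr2 = clean_cosine_trace.copy()
        tr2.value = tr2.value * 37.0
        pk1 = traces.find_peaks_troughs(clean_cosine_trace)
        pk2 = traces.find_peaks_troughs(tr2)
        a1 = traces.cycle_amplitudes(pk1, 60.0)["normalized_amplitude"].dropna()
        a2 = traces.cycle_amplitudes(pk2, 60.0)["normalized_amplitude"].dropna()
        np.testing.assert_allclose(a1, a2, atol=1e-9)

    def test_growing_oscillation_ba_below_one(self):
        t = np.arange(0, 120, 0.1)
        v = 1.2 ** (t / 24.0) * np.cos(2 * np.pi * (t - 6) / 24)
        tr = make_trace(t, v)
        ba = traces.ba_ratio(traces.find_peaks_troughs(tr))
        assert (ba["ba_ratio"] < 1).all()

    def test_treatment_suppression_recovered(self):
        ep = syn.EpochEffect(start_h=133, end_h=230, amplitude_factor=0.15)
        tr = syn.simulate_trace(
            syn.TraceSimSpec(duration_h=288, dt_h=0.1, period_h=24.8, phase_h=6,
                             amplitude=1.0, noise_sd=0.02, epochs=[ep], seed=7)
        )
        pk = traces.find_peaks_troughs(traces.smooth(tr, 25),
                                       min_prominence_frac=0.02)
        amps = traces.cycle_amplitudes(pk, 133)
        inside = amps[(amps.peak_time_h > 150) & (amps.peak_time_h < 230)]
        assert inside["normalized_amplitude"].mean() == pytest.approx(0.15, abs=0.05)

    def test_washout_recovery_ba_rises_to_one(self):
        ep = syn.EpochEffect(start_h=120, end_h=170, amplitude_factor=0.1,
                             recovery_halflife_h=24.0)
        tr = syn.simulate_trace(
            syn.TraceSimSpec(duration_h=320, dt_h=0.1, period_h=24.8, phase_h=6,
                             amplitude=1.0, noise_sd=0.02, epochs=[ep], seed=8)
        )
        pk = traces.find_peaks_troughs(traces.smooth(tr, 25),
                                       min_prominence_frac=0.02)
        ba = traces.ba_ratio(pk)
        post = ba[ba.peak_time_h > 170]["ba_ratio"].to_numpy()
        assert (np.diff(post) > -0.02).all()  # monotone rise (tiny noise slack)
        assert post[-1] == pytest.approx(1.0, abs=0.05)
        ss = traces.steady_state_ba(pk, 170)
        assert 0 < ss < 1


class TestFitAndRae:
    def test_noiseless_cosine_rae_near_zero(self, clean_cosine_trace):
        fit = traces.fit_fft_nlls(clean_cosine_trace)
        assert fit.period_h == pytest.approx(24.0, abs=0.05)
        assert fit.amplitude == pytest.approx(1.0, abs=0.01)
        assert traces.rae(fit) <= 0.01

    def test_white_noise_rae_high(self):
        raes = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for seed in range(30):
                tr = syn.simulate_trace(
                    syn.TraceSimSpec(duration_h=120, dt_h=0.5, period_h=24,
                                     phase_h=6, amplitude=0.0, noise_sd=1.0,
                                     seed=seed)
                )
                raes.append(traces.rae(traces.fit_fft_nlls(tr)))
        assert np.mean(raes) >= 0.8

    def test_rae_monotone_in_noise(self):
        from scipy.stats import spearmanr

        noise = np.linspace(0.02, 1.0, 25)
        raes = []
        for i, sd in enumerate(noise):
            tr = syn.simulate_trace(
                syn.TraceSimSpec(duration_h=120, dt_h=0.5, period_h=24, phase_h=6,
                                 amplitude=1.0, noise_sd=sd, seed=100 + i)
            )
            raes.append(traces.rae(traces.fit_fft_nlls(tr)))
        rho, p = spearmanr(noise, raes)
        assert rho > 0 and p < 0.01

    def test_rae_normalized_ratio(self):
        assert traces.rae_normalized(0.4, 0.1) == pytest.approx(4.0)
        with pytest.raises(ValueError):
            traces.rae_normalized(0.4, 0.0)


class TestRayleigh:
    def test_identical_phases_full_concentration(self):
        r, p, mean_ct = traces.rayleigh([17.0] * 8)
        assert r == pytest.approx(1.0)
        assert p < 0.01
        assert mean_ct == pytest.approx(17.0)

    def test_symmetric_four_phase_set_null(self):
        r, p, _ = traces.rayleigh([0.0, 6.0, 12.0, 18.0])
        assert r == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=0.05)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(0)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            _, p, _ = traces.rayleigh(rng.uniform(0, 24, 10))
            rejections += p <= 0.05
        rate = rejections / n_sim
        assert rate == pytest.approx(0.05, abs=0.02)

    def test_too_few_phases_is_error(self):
        with pytest.raises(ValueError):
            traces.rayleigh([3.0])


class TestCtAndIntegration:
    def test_reference_peak_maps_to_reference_ct(self):
        ct = traces.assign_ct(np.array([50.0, 62.0]), reference_peak_time_h=50.0)
        assert ct[0] == pytest.approx(6.0)
        assert ct[1] == pytest.approx(18.0)  # antiphase -> CT18 at period 24

    def test_astrocyte_like_offset_maps_near_ct17(self):
        # a peak 11 h after the neuronal reference peak sits at ~CT17
        ct = traces.assign_ct(np.array([61.0]), reference_peak_time_h=50.0)
        assert ct[0] == pytest.approx(17.0)

    def test_constant_signal_integral(self):
        tr = make_trace(np.arange(0, 72.5, 0.5), np.ones(145))
        np.testing.assert_allclose(traces.integrate_24h(tr, 0.0), [24.0, 24.0, 24.0])

    def test_zero_mean_cosine_integrates_to_zero(self, clean_cosine_trace):
        out = traces.integrate_24h(clean_cosine_trace, 0.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-6)

    def test_step_increase_changes_integral_by_step(self):
        t = np.arange(0, 96.5, 0.5)
        v = np.where(t < 48, 1.0, 3.0)
        tr = make_trace(t, v)
        out = traces.integrate_24h(tr, 0.0)
        # compare windows clear of the discontinuity (trapezoid smears one bin)
        assert out[3] - out[0] == pytest.approx(2.0 * 24.0)

    def test_no_complete_window_is_error(self):
        tr = make_trace(np.arange(0, 10, 0.5), np.ones(20))
        with pytest.raises(ValueError):
            traces.integrate_24h(tr, 0.0)


class TestPseudoAlign:
    def test_identical_traces_zero_sem(self, clean_cosine_trace):
        out = traces.pseudo_align([clean_cosine_trace, clean_cosine_trace],
                                  [54.0, 54.0])
        np.testing.assert_allclose(out["sem"].dropna(), 0.0, atol=1e-12)

    def test_offset_traces_coincide_after_shift(self):
        a = syn.simulate_trace(syn.TraceSimSpec(duration_h=120, dt_h=0.5,
                                                period_h=24, phase_h=6,
                                                amplitude=1.0, seed=0))
        b = syn.simulate_trace(syn.TraceSimSpec(duration_h=120, dt_h=0.5,
                                                period_h=24, phase_h=9,
                                                amplitude=1.0, seed=0))
        out = traces.pseudo_align([a, b], [54.0, 57.0])
        np.testing.assert_allclose(out["sem"].dropna(), 0.0, atol=1e-6)

    def test_cohort_mean_profile_period(self):
        cohort, refs = [], []
        for seed in range(6):
            tr = syn.simulate_trace(
                syn.TraceSimSpec(duration_h=150, dt_h=0.5, period_h=24.8,
                                 phase_h=6 + seed, amplitude=1.0, noise_sd=0.05,
                                 seed=seed)
            )
            pk = traces.find_peaks_troughs(traces.smooth(tr, 5))
            cohort.append(tr)
            refs.append(pk.peak_times_h[-1])
        profile = traces.pseudo_align(cohort, refs)
        mean_tr = make_trace(profile["time_h"], profile["mean"])
        period = traces.compute_period(traces.find_peaks_troughs(mean_tr))
        assert period == pytest.approx(24.8, abs=0.2)

    def test_missing_reference_excluded_with_warning(self, clean_cosine_trace):
        with pytest.warns(UserWarning):
            out = traces.pseudo_align(
                [clean_cosine_trace] * 3, [54.0, None, 54.0]
            )
        assert (out["n"] <= 2).all()
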
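"""Spectral parameterization: recovery, robustness, edge rule, TFR maps."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from specdyn.specparam import (
    SpecparamSettings,
    extract_peaks,
    fit_spectrum,
    parameterize_tfr,
    reconstruct_periodic,
    robust_aperiodic_fit,
)
from specdyn.synth import simulate_power_spectrum


class TestRobustAperiodicFit:
    def test_noiseless_pure_aperiodic_exact(self, freqs):
        log_p = simulate_power_spectrum((1.0, 1.5), [], freqs)
        fit = robust_aperiodic_fit(freqs, log_p)
        assert abs(fit.offset - 1.0) < 1e-6
        assert abs(fit.exponent - 1.5) < 1e-6

    def test_beats_naive_fit_under_large_peak(self, freqs):
        log_p = simulate_power_spectrum((0.0, 1.0), [(10.0, 1.0, 1.5)], freqs)
        robust = robust_aperiodic_fit(freqs, log_p)
        naive_slope = np.polyfit(np.log10(freqs), log_p, 1)[0]
        assert abs(robust.exponent - 1.0) < abs(-naive_slope - 1.0)

    def test_flat_spectrum_with_noise(self, freqs):
        errs = []
        for s in range(60):
            log_p = simulate_power_spectrum((0.0, 0.0), [], freqs,
                                            noise_sd=0.05, seed=s)
            errs.append(abs(robust_aperiodic_fit(freqs, log_p).exponent))
        assert np.median(errs) < 0.05

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            robust_aperiodic_fit(np.array([1.0, 2.0, 3.0]), np.zeros(3))


def _lsq_gaussian_oracle(freqs, flat, n_peaks):
    """Direct bounded least squares on the known number of Gaussians."""

    def model(f, *p):
        out = np.zeros_like(f)
        for c, a, w in zip(p[0::3], p[1::3], p[2::3]):
            out = out + a * np.exp(-((f - c) ** 2) / (2 * w**2))
        return out

    order = np.argsort(flat)[::-1]
    p0 = []
    for i in range(n_peaks):
        p0 += [freqs[order[i * 3]], flat[order[i * 3]], 1.5]
    popt, _ = curve_fit(model, freqs, flat, p0=p0,
                        bounds=([3, 0, 0.25] * n_peaks,
                                [50, np.inf, 6.0] * n_peaks))
    return popt


class TestExtractPeaks:
    def test_single_interior_gaussian_matches_lsq_oracle(self, freqs):
        flat = 0.8 * np.exp(-((freqs - 25.0) ** 2) / (2 * 2.0**2))
        peaks = extract_peaks(freqs, flat)
        assert len(peaks) == 1
        oracle = _lsq_gaussian_oracle(freqs, flat, 1)
        assert abs(peaks[0].center - oracle[0]) < 0.1
        assert abs(peaks[0].height - oracle[1]) < 0.05
        assert abs(peaks[0].center - 25.0) < 0.1

    def test_edge_peak_dropped(self, freqs):
        flat = 0.8 * np.exp(-((freqs - 3.0) ** 2) / (2 * 1.5**2))
        peaks = extract_peaks(freqs, flat)
        assert all(p.center >= 3.0 + p.sd for p in peaks)

    def test_all_zero_input_gives_no_peaks(self, freqs):
        assert extract_peaks(freqs, np.zeros_like(freqs)) == []

    def test_width_limits_respected(self, freqs):
        settings = SpecparamSettings(peak_width_limits=(0.5, 12.0))
        flat = 0.6 * np.exp(-((freqs - 20.0) ** 2) / (2 * 1.0**2))
        for p in extract_peaks(freqs, flat, settings):
            assert 0.25 <= p.sd <= 6.0


class TestFitSpectrum:
    def test_noiseless_recovery_exact(self, freqs):
        log_p = simulate_power_spectrum((1.0, 1.5), [(10.0, 0.6, 1.5)], freqs)
        m = fit_spectrum(freqs, 10.0**log_p)
        assert abs(m.aperiodic.offset - 1.0) < 1e-4
        assert abs(m.aperiodic.exponent - 1.5) < 1e-4
        assert len(m.peaks) == 1
        assert abs(m.peaks[0].center - 10.0) < 1e-4
        assert abs(m.peaks[0].height - 0.6) < 1e-4
        assert abs(m.peaks[0].sd - 1.5) < 1e-3

    def test_pure_aperiodic_fit_metrics(self, freqs):
        m = fit_spectrum(freqs, 10.0**simulate_power_spectrum((1.0, 1.5), [],
                                                              freqs))
        assert m.r_squared > 0.999
        assert m.mean_abs_error < 1e-3

    def test_two_separated_peaks_found(self, freqs):
        log_p = simulate_power_spectrum(
            (0.0, 1.0), [(10.0, 0.6, 1.5), (22.0, 0.6, 1.5)], freqs)
        m = fit_spectrum(freqs, 10.0**log_p)
        assert len(m.peaks) == 2

    def test_reported_mae_equals_residual_mean(self, freqs):
        log_p = simulate_power_spectrum((0.5, 1.2), [(12.0, 0.5, 2.0)], freqs,
                                        noise_sd=0.05, seed=1)
        m = fit_spectrum(freqs, 10.0**log_p)
        model = m.aperiodic.evaluate(freqs) + reconstruct_periodic(m, freqs)
        assert m.mean_abs_error == pytest.approx(
            np.mean(np.abs(log_p - model)), abs=1e-12)

    def test_nonpositive_power_rejected(self, freqs):
        power = np.ones_like(freqs)
        power[3] = 0.0
        with pytest.raises(ValueError):
            fit_spectrum(freqs, power)


class TestReconstructPeriodic:
    def test_no_peaks_gives_zeros(self, freqs):
        assert np.all(reconstruct_periodic([], freqs) == 0)

    def test_gaussian_closed_form(self, freqs):
        from specdyn.specparam import PeakFit

        peak = PeakFit(center=10.0, height=0.7, sd=2.0)
        out = reconstruct_periodic([peak], freqs)
        assert out[freqs == 10.0][0] == pytest.approx(0.7)
        assert out[freqs == 12.0][0] == pytest.approx(0.7 * np.exp(-0.5))
        assert np.all(out >= 0)


class TestParameterizeTfr:
    def test_exponent_bump_timing_and_periodic_silence(self, exponent_shift_tfr):
        from dataclasses import replace

        spec, tfr = exponent_shift_tfr
        # subject-averaged TFR, as in grand-average illustrations
        ga = replace(tfr, power=np.nanmean(tfr.power, axis=0, keepdims=True))
        par = parameterize_tfr(ga, time_step=2)
        expo = np.nanmean(par.exponent, axis=(0, 1, 2))
        tt = par.times
        pre = np.nanmean(expo[tt < 0])
        during = np.nanmean(expo[(tt >= 0.3) & (tt <= 0.7)])
        # planted plateau of +0.3 between 0.2 and 0.8 s
        assert during - pre == pytest.approx(0.3, abs=0.1)
        # no oscillation was planted: periodic power at 4-6 Hz stays silent
        lows = (par.frequencies >= 4) & (par.frequencies <= 6)
        assert np.nanmean(par.periodic[:, :, :, lows, :]) < 0.02
        assert par.failed.mean() < 0.05

    def test_window_restriction(self, exponent_shift_tfr):
        _, tfr = exponent_shift_tfr
        par = parameterize_tfr(tfr, window=(-0.5, 2.0), time_step=4)
        assert par.times[0] >= -0.5
        assert par.times[-1] <= 2.0
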
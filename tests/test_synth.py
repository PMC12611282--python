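"""Ground-truth generators: closed forms, spectral targets, determinism."""

import numpy as np
import pytest
from scipy.signal import welch

from specdyn.synth import (
    EpochedData,
    ExGaussParams,
    GroundTruthSpec,
    OscillationSpec,
    default_spec,
    simulate_aperiodic_timeseries,
    simulate_epochs,
    simulate_power_spectrum,
    simulate_rts,
)


class TestSimulatePowerSpectrum:
    @pytest.mark.parametrize(
        "aperiodic, peaks, f, expected",
        [
            ((0.0, 0.0), [], 10.0, 0.0),
            ((1.0, 1.0), [], 10.0, 0.0),
            ((0.0, 2.0), [(10.0, 0.5, 1.0)], 10.0, -1.5),
        ],
    )
    def test_closed_forms(self, aperiodic, peaks, f, expected):
        out = simulate_power_spectrum(aperiodic, peaks, np.array([f]))
        assert out[0] == pytest.approx(expected, abs=1e-12)

    def test_noise_is_seeded(self, freqs):
        a = simulate_power_spectrum((0, 1), [], freqs, noise_sd=0.1, seed=3)
        b = simulate_power_spectrum((0, 1), [], freqs, noise_sd=0.1, seed=3)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize(
        "bad",
        [
            {"freqs": np.array([-1.0, 2.0])},
            {"aperiodic": (np.nan, 1.0)},
            {"peaks": [(10.0, 0.5, -1.0)]},
        ],
    )
    def test_invalid_inputs(self, bad, freqs):
        kwargs = {"aperiodic": (0.0, 1.0), "peaks": [], "freqs": freqs}
        kwargs.update(bad)
        with pytest.raises(ValueError):
            simulate_power_spectrum(**kwargs)


def _welch_slope(x, fs, lo=3.0, hi=50.0):
    f, p = welch(x, fs=fs, nperseg=int(2 * fs))
    sel = (f >= lo) & (f <= hi)
    return np.polyfit(np.log10(f[sel]), np.log10(p[sel]), 1)[0]


class TestAperiodicTimeseries:
    def test_flat_exponent_gives_flat_spectrum(self):
        x = simulate_aperiodic_timeseries(0.0, 0.0, 500.0, 60.0, seed=1)
        assert -0.1 < _welch_slope(x, 500.0) < 0.1

    def test_exponent_two_recovered(self):
        x = simulate_aperiodic_timeseries(2.0, 0.0, 500.0, 60.0, seed=1)
        assert -2.1 < _welch_slope(x, 500.0) < -1.9

    def test_slope_bias_over_realizations(self):
        # mean fitted slope over seeded realizations tracks -chi closely
        for chi in (0.5, 1.0, 1.5, 2.0):
            slopes = [
                _welch_slope(
                    simulate_aperiodic_timeseries(chi, 0.0, 250.0, 30.0, seed=s)
                    , 250.0)
                for s in range(12)
            ]
            assert abs(np.mean(slopes) + chi) < 0.05

    def test_offset_scales_power_tenfold(self):
        x0 = simulate_aperiodic_timeseries(1.0, 0.0, 500.0, 30.0, seed=2)
        x1 = simulate_aperiodic_timeseries(1.0, 1.0, 500.0, 30.0, seed=2)
        f, p0 = welch(x0, fs=500, nperseg=1000)
        _, p1 = welch(x1, fs=500, nperseg=1000)
        sel = (f >= 3) & (f <= 50)
        assert np.mean(np.log10(p1[sel] / p0[sel])) == pytest.approx(1.0, abs=0.01)

    def test_negative_exponent_rejected(self):
        with pytest.raises(ValueError):
            simulate_aperiodic_timeseries(-0.5, 0.0, 250.0, 1.0, seed=0)


class TestSimulateRts:
    def test_mean_matches_mu_plus_tau(self):
        rts = simulate_rts((0.5, 0.05, 0.15), 10000, seed=4)
        assert rts.mean() == pytest.approx(0.65, abs=0.01)

    def test_deterministic(self):
        a = simulate_rts((0.5, 0.05, 0.15), 100, seed=9)
        b = simulate_rts((0.5, 0.05, 0.15), 100, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_near_gaussian_limit_has_low_skewness(self):
        from scipy.stats import skew

        rts = simulate_rts((0.5, 0.05, 1e-6), 10000, seed=5)
        assert abs(skew(rts)) < 0.2

    def test_nonpositive_parameter_rejected(self):
        with pytest.raises(ValueError):
            simulate_rts((0.5, 0.0, 0.1), 10, seed=0)


class TestSimulateEpochs:
    def test_bit_identical_given_seed(self, small_epochs):
        spec, epochs = small_epochs
        again = simulate_epochs(spec)
        np.testing.assert_array_equal(epochs.samples, again.samples)
        np.testing.assert_array_equal(epochs.reaction_times,
                                      again.reaction_times)

    def test_epoched_data_invariants(self, small_epochs):
        _, epochs = small_epochs
        epochs.validate()
        assert np.all(np.isfinite(epochs.samples))
        rts = epochs.reaction_times
        assert np.all(rts[np.isfinite(rts)] > 0)

    def test_zero_erp_averages_to_noise_level(self):
        spec = default_spec(
            n_subjects=1, trials_per_condition=40, n_channels=2,
            condition_labels=[("verbal", "0back", "nontarget")],
            oscillations=[], exponent_events=[], erp_template=None,
            aperiodic_offset=-3.0,  # background far below the sensor noise
            sensor_noise_sd=0.5, subject_sd_offset=0.0,
            subject_sd_exponent=0.0, seed=3,
        )
        epochs = simulate_epochs(spec)
        erp = epochs.samples[0, 0].mean(axis=0)
        bound = 3 * 0.5 / np.sqrt(spec.trials_per_condition)
        assert np.abs(erp).max() <= bound * 2  # background contributes a little

    def test_suppression_depth_zero_keeps_alpha_stationary(self):
        from specdyn.tfr import superlet_power

        # background pushed far below the oscillation so the measured
        # power reflects the amplitude envelope alone
        spec = GroundTruthSpec(
            n_subjects=1,
            condition_labels=[("verbal", "0back", "nontarget")],
            trials_per_condition=10, n_channels=1, channel_groups={},
            sampling_rate=200.0, epoch_window=(-1.0, 2.0),
            aperiodic_offset=-4.0, subject_sd_offset=0.0,
            oscillations=[OscillationSpec(10.0, 15.0, suppression_depth=0.0)],
            exponent_events=[], erp_template=None, sensor_noise_sd=0.01,
            seed=7,
        )
        epochs = simulate_epochs(spec)
        power, valid = superlet_power(
            epochs.samples[0, 0, :, 0, :], 200.0, np.array([8.0, 10.0, 12.0]),
            order_min=1, order_max=1, return_valid=True,
        )
        p10 = power.mean(axis=0)[1][valid[1]]
        assert p10.std() / p10.mean() < 0.05

    def test_condition_modulation_raises_exponent_for_target(self):
        spec = default_spec(n_subjects=1, trials_per_condition=4, seed=2)
        spec.validate()
        # target modulation factor on the first exponent event is 1.2
        ev = spec.exponent_events[0]
        lab_t = ("verbal", "0back", "target")
        lab_n = ("verbal", "0back", "nontarget")
        from specdyn.synth import _condition_factor

        assert _condition_factor(ev.condition_modulation, lab_t) == 1.2
        assert _condition_factor(ev.condition_modulation, lab_n) == 1.0

    def test_bad_channel_group_rejected(self):
        spec = default_spec(n_subjects=1, trials_per_condition=2)
        spec.channel_groups["frontal"] = np.ones(3)  # wrong length
        with pytest.raises(ValueError):
            simulate_epochs(spec)
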
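"""Wavelet and superlet decomposition properties."""

import numpy as np
import pytest

from specdyn.synth import default_spec, simulate_epochs
from specdyn.tfr import (
    morlet_coefficients,
    superlet_orders,
    superlet_power,
    tfr_epochs,
)

FS = 500.0


@pytest.fixture(scope="module")
def tone10():
    t = np.arange(0, 4, 1 / FS)
    return np.cos(2 * np.pi * 10 * t)


class TestMorlet:
    def test_stationary_tone_magnitude_constant(self, tone10):
        coefs, valid = morlet_coefficients(tone10, FS, [10.0], 3)
        mag = np.abs(coefs[0])[valid[0]]
        assert mag.std() / mag.mean() < 0.01

    def test_phase_advances_at_tone_frequency(self, tone10):
        coefs, valid = morlet_coefficients(tone10, FS, [10.0], 3)
        phase = np.unwrap(np.angle(coefs[0][valid[0]]))
        rate = np.diff(phase)
        assert np.allclose(rate, 2 * np.pi * 10 / FS, atol=1e-3)

    def test_linearity(self, tone10):
        c1, _ = morlet_coefficients(tone10, FS, [10.0], 3)
        c3, _ = morlet_coefficients(3 * tone10, FS, [10.0], 3)
        np.testing.assert_allclose(np.abs(c3), 3 * np.abs(c1), rtol=1e-12)

    def test_frequency_above_nyquist_rejected(self, tone10):
        with pytest.raises(ValueError):
            morlet_coefficients(tone10, FS, [300.0], 3)

    def test_agrees_with_mne_oracle(self, tone10):
        """Independent cross-check of Morlet power against mne."""
        mne = pytest.importorskip("mne")

        freqs = np.array([8.0, 10.0, 15.0])
        ours, valid = morlet_coefficients(tone10, FS, freqs, 7.0)
        theirs = mne.time_frequency.tfr_array_morlet(
            tone10[None, None, :], FS, freqs, n_cycles=7.0, output="complex",
            zero_mean=False,
        )[0, 0]
        interior = np.all(valid, axis=0)
        # normalisation conventions differ by a per-frequency constant;
        # compare shape of the power envelope per frequency
        for i in range(freqs.size):
            a = np.abs(ours[i][interior])
            b = np.abs(theirs[i][interior])
            np.testing.assert_allclose(a / a.max(), b / b.max(), atol=1e-6)


class TestSuperlets:
    def test_order_one_equals_morlet_power(self, tone10):
        freqs = np.arange(5.0, 30.0, 1.0)
        p_super = superlet_power(tone10, FS, freqs, base_cycles=3,
                                 order_min=1, order_max=1)
        coefs, _ = morlet_coefficients(tone10, FS, freqs, 3)
        p_morlet = np.abs(coefs) ** 2
        np.testing.assert_allclose(p_super, p_morlet, rtol=1e-10)

    def test_tone_localised_at_every_interior_timepoint(self):
        t = np.arange(0, 4, 1 / FS)
        tone = np.cos(2 * np.pi * 20 * t)
        freqs = np.arange(3.0, 51.0, 1.0)
        power, valid = superlet_power(tone, FS, freqs, return_valid=True)
        interior = np.all(valid, axis=0)
        peaks = freqs[np.argmax(power[:, interior], axis=0)]
        assert np.all(peaks == 20.0)

    def test_geometric_mean_between_min_and_max_member(self, tone10):
        """The combined magnitude lies within the member wavelets' range."""
        freqs = np.array([10.0, 20.0])
        p_super = superlet_power(tone10, FS, freqs, base_cycles=3,
                                 order_min=3, order_max=3)
        mags = []
        for k in (1, 2, 3):
            coefs, _ = morlet_coefficients(tone10, FS, freqs, 3 * k)
            mags.append(np.abs(coefs))
        stack = np.stack(mags)
        combined = np.sqrt(p_super)
        assert np.all(combined <= stack.max(axis=0) + 1e-12)
        assert np.all(combined >= stack.min(axis=0) - 1e-12)

    def test_superlet_sharper_than_base_morlet_at_40hz(self):
        t = np.arange(0, 4, 1 / FS)
        tone = np.cos(2 * np.pi * 40 * t)
        grid = np.arange(30.0, 50.5, 0.5)
        centre = t.size // 2
        prof_s = superlet_power(tone, FS, grid, base_cycles=3,
                                order_min=16, order_max=16)[:, centre]
        coefs, _ = morlet_coefficients(tone, FS, grid, 3)
        prof_m = np.abs(coefs[:, centre]) ** 2

        def bw(p):
            above = grid[p >= p.max() / 2]
            return above.max() - above.min()

        assert bw(prof_s) <= bw(prof_m)

    def test_time_shift_equivariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=1500)
        shift = 40
        freqs = np.array([10.0, 25.0])
        p0 = superlet_power(x, FS, freqs, order_min=2, order_max=2)
        p1 = superlet_power(np.roll(x, shift), FS, freqs, order_min=2,
                            order_max=2)
        # compare interior region away from the rolled edge
        sl = slice(400, 1000)
        np.testing.assert_allclose(p1[:, sl], p0[:, slice(sl.start - shift,
                                                          sl.stop - shift)],
                                   rtol=1e-6)

    def test_single_frequency_with_order_range_rejected(self, tone10):
        with pytest.raises(ValueError):
            superlet_power(tone10, FS, [10.0], order_min=1, order_max=20)

    def test_orders_interpolate_linearly(self):
        freqs = np.arange(3.0, 51.0, 1.0)
        orders = superlet_orders(freqs, 1, 20)
        assert orders[0] == 1
        assert orders[-1] == 20
        assert np.allclose(np.diff(orders), np.diff(orders)[0])


class TestTfrEpochs:
    @pytest.fixture(scope="class")
    def tiny_epochs(self):
        spec = default_spec(
            n_subjects=1, trials_per_condition=4, n_channels=2,
            condition_labels=[("verbal", "0back", "nontarget")],
            sampling_rate=200.0, epoch_window=(-1.0, 2.0), seed=5,
        )
        return simulate_epochs(spec)

    def test_identical_trials_average_to_single_trial(self, tiny_epochs):
        ep = tiny_epochs
        ep.samples[0, 0] = ep.samples[0, 0, 0]  # make all trials identical
        tfr = tfr_epochs(ep, frequencies=np.arange(5.0, 31.0, 5.0))
        single = tfr_epochs(
            type(ep)(samples=ep.samples[:, :, :1], sampling_rate=ep.sampling_rate,
                     times=ep.times, channel_names=ep.channel_names,
                     condition_labels=ep.condition_labels,
                     reaction_times=ep.reaction_times[:, :, :1],
                     accuracy=ep.accuracy[:, :, :1]),
            frequencies=np.arange(5.0, 31.0, 5.0),
        )
        np.testing.assert_allclose(tfr.power, single.power, rtol=1e-12)

    def test_amplitude_doubling_quadruples_power(self, tiny_epochs):
        ep = tiny_epochs
        freqs = np.arange(5.0, 31.0, 5.0)
        tfr1 = tfr_epochs(ep, frequencies=freqs)
        doubled = type(ep)(
            samples=2 * ep.samples, sampling_rate=ep.sampling_rate,
            times=ep.times, channel_names=ep.channel_names,
            condition_labels=ep.condition_labels,
            reaction_times=ep.reaction_times, accuracy=ep.accuracy,
        )
        tfr2 = tfr_epochs(doubled, frequencies=freqs)
        np.testing.assert_allclose(tfr2.power, 4 * tfr1.power, rtol=1e-10)

    def test_incorrect_trials_excluded_and_empty_cell_flagged(self, tiny_epochs):
        ep = tiny_epochs
        ep.accuracy[0, 0] = False
        tfr = tfr_epochs(ep, frequencies=np.array([10.0, 20.0]))
        assert tfr.missing_cells[0, 0]
        assert np.all(np.isnan(tfr.power[0, 0]))
        ep.accuracy[0, 0] = True

    def test_power_nonnegative_and_decimated(self, tiny_epochs):
        tfr = tfr_epochs(tiny_epochs, frequencies=np.array([10.0, 20.0]))
        tfr.validate()
        assert tfr.times.size == tiny_epochs.times.size // 2  # 200 -> 100 Hz
        finite = tfr.power[np.isfinite(tfr.power)]
        assert np.all(finite >= 0)
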
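"""Phase-autocorrelation function (pACF): amplitude-independent rhythmicity.

A genuinely oscillatory signal keeps a stable phase velocity, so the phase
difference between the analytic signal and a delayed copy of itself is
nearly constant in time.  The pACF quantifies this: per lag ``l`` (measured
in cycles of the evaluated frequency) the unit phasors
``z_t = exp(j * (phi_t - phi_{t-l}))`` are averaged in a short centred
window and the magnitude of the average is taken; the pACF at a timepoint
is the mean of these magnitudes over a grid of lags (default 1.0–3.0
cycles in 0.1 steps, window 2.5 cycles).  Normalising to unit phasors
removes all amplitude information, so pACF(c*x) == pACF(x) for any c > 0,
and all values lie in [0, 1].

The analytic signal comes from 3-cycle Morlet convolution (not superlets,
whose mixed-width combination distorts phase autocorrelation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .tfr import morlet_coefficients

__all__ = [
    "RhythmicityMap",
    "phase_increments",
    "pacf_time_resolved",
    "pacf_epochs",
    "default_lags",
]


def default_lags() -> np.ndarray:
    return np.round(np.arange(1.0, 3.0 + 1e-9, 0.1), 10)


def phase_increments(analytic_signal, lag_samples: int) -> np.ndarray:
    """Unit phasors of the phase difference at a given sample lag.

    Returns an array of the same shape; the first ``lag_samples`` entries,
    which have no delayed counterpart, are NaN.
    """
    analytic_signal = np.asarray(analytic_signal)
    if lag_samples < 1:
        raise ValueError("lag_samples must be >= 1")
    if lag_samples >= analytic_signal.shape[-1]:
        raise ValueError("lag exceeds signal length")
    phi = np.angle(analytic_signal)
    z = np.full(analytic_signal.shape, np.nan, dtype=complex)
    z[..., lag_samples:] = np.exp(1j * (phi[..., lag_samples:] - phi[..., :-lag_samples]))
    return z


def pacf_time_resolved(
    analytic_signal,
    sampling_rate: float,
    frequency: float,
    lags_cycles=None,
    window_cycles: float = 2.5,
) -> np.ndarray:
    """Time-resolved pACF of one frequency's analytic signal.

    Lags (cycles) convert to samples by rounding; duplicates after rounding
    are dropped.  Positions whose averaging window or maximal lag reaches
    outside the signal are NaN.  Values are in [0, 1].
    """
    analytic_signal = np.asarray(analytic_signal)
    if lags_cycles is None:
        lags_cycles = default_lags()
    n = analytic_signal.shape[-1]
    window = int(round(window_cycles * sampling_rate / frequency))
    if window < 3:
        raise ValueError("averaging window shorter than 3 samples")
    lag_samples = sorted(
        {int(round(l * sampling_rate / frequency)) for l in lags_cycles}
    )
    lag_samples = [l for l in lag_samples if l >= 1]
    if not lag_samples or lag_samples[-1] >= n:
        raise ValueError("lag grid empty or exceeds signal length")

    acc = np.zeros(analytic_signal.shape, dtype=float)
    for lag in lag_samples:
        z = phase_increments(analytic_signal, lag)
        z_filled = np.where(np.isnan(z), 0, z)
        # centred moving average of the unit phasors
        mean_re = uniform_filter1d(z_filled.real, window, axis=-1, mode="constant")
        mean_im = uniform_filter1d(z_filled.imag, window, axis=-1, mode="constant")
        acc += np.hypot(mean_re, mean_im)
    pacf = acc / len(lag_samples)
    np.clip(pacf, 0.0, 1.0, out=pacf)  # guard float rounding above 1

    half = window // 2
    max_lag = lag_samples[-1]
    invalid_head = max_lag + half
    pacf[..., : min(invalid_head, n)] = np.nan
    if half > 0:
        pacf[..., -half:] = np.nan
    return pacf


@dataclass
class RhythmicityMap:
    """pACF over (subject, condition, channel, frequency, time) in [0, 1]."""

    pacf: np.ndarray
    frequencies: np.ndarray
    times: np.ndarray
    lags_cycles: np.ndarray
    window_cycles: float
    n_cycles: float = 3.0
    condition_labels: list | None = None
    channel_names: list | None = None
    params: dict = field(default_factory=dict)


def pacf_epochs(
    epochs,
    frequencies=None,
    lags_cycles=None,
    window_cycles: float = 2.5,
    n_cycles: float = 3.0,
    output_rate: float = 100.0,
) -> RhythmicityMap:
    """Trial-level pACF averaged within subject x condition, then decimated.

    The analytic signal per frequency is the 3-cycle Morlet convolution of
    each correct trial; pACF is computed per trial and averaged, analogous
    to trial-averaged power.
    """
    if frequencies is None:
        frequencies = np.arange(3.0, 51.0, 1.0)
    frequencies = np.asarray(frequencies, dtype=float)
    if lags_cycles is None:
        lags_cycles = default_lags()
    fs = epochs.sampling_rate
    step = int(round(fs / output_rate))
    S, C, T, Ch, N = epochs.samples.shape
    idx = np.arange(0, N, step)
    out = np.full((S, C, Ch, frequencies.size, idx.size), np.nan)
    for s in range(S):
        for c in range(C):
            good = epochs.accuracy[s, c]
            if not np.any(good):
                continue
            sig = epochs.samples[s, c, good].reshape(-1, N)
            coefs, _ = morlet_coefficients(sig, fs, frequencies, n_cycles)
            per_freq = []
            for i, f in enumerate(frequencies):
                p = pacf_time_resolved(coefs[:, i, :], fs, f, lags_cycles,
                                       window_cycles)
                per_freq.append(p)
            stack = np.stack(per_freq, axis=1)  # (trials*ch, F, N)
            stack = stack.reshape(int(good.sum()), Ch, frequencies.size, N)
            out[s, c] = stack.mean(axis=0)[..., idx]
    return RhythmicityMap(
        pacf=out,
        frequencies=frequencies,
        times=epochs.times[idx],
        lags_cycles=np.asarray(lags_cycles, dtype=float),
        window_cycles=window_cycles,
        n_cycles=n_cycles,
        condition_labels=list(epochs.condition_labels),
        channel_names=list(epochs.channel_names),
    )
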
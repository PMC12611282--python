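"""Event-related potentials: computation, single-trial subtraction, controls.

Evoked transients are phase-locked across trials and therefore survive
trial averaging; induced (random-phase) activity averages out.  Subtracting
each cell's ERP from its single trials before time-frequency decomposition
removes the evoked contribution while preserving induced power, which is
the control used to show that aperiodic dynamics are not merely ERPs in
disguise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .mixedstats import StatMap, mass_univariate_r2
from .synth import EpochedData

__all__ = ["ERPData", "compute_erp", "subtract_erp", "response_locked_erp",
           "erp_aperiodic_r2"]


@dataclass
class ERPData:
    """Trial-average waveform per subject x condition x channel x time."""

    waveform: np.ndarray  # (S, C, Ch, N); NaN where the cell is empty
    times: np.ndarray
    n_trials: np.ndarray  # (S, C) trials used
    channel_names: list | None = None
    condition_labels: list | None = None

    @property
    def missing_cells(self) -> np.ndarray:
        return self.n_trials == 0


def compute_erp(epochs: EpochedData) -> ERPData:
    """Arithmetic mean over correct-response trials, per subject x condition.

    Empty cells (no correct trial) are flagged missing rather than raising.
    """
    S, C, T, Ch, N = epochs.samples.shape
    wave = np.full((S, C, Ch, N), np.nan)
    counts = np.zeros((S, C), dtype=int)
    for s in range(S):
        for c in range(C):
            good = epochs.accuracy[s, c]
            counts[s, c] = int(good.sum())
            if counts[s, c]:
                wave[s, c] = epochs.samples[s, c, good].mean(axis=0)
    return ERPData(
        waveform=wave,
        times=epochs.times.copy(),
        n_trials=counts,
        channel_names=list(epochs.channel_names),
        condition_labels=list(epochs.condition_labels),
    )


def subtract_erp(epochs: EpochedData, erp: ERPData) -> EpochedData:
    """Subtract each cell's ERP from its single trials.

    The trial mean of the output is exactly zero per cell (for the trials
    that entered the ERP).  Axes must match.
    """
    if epochs.samples.shape[3:] != erp.waveform.shape[2:] or not np.allclose(
        epochs.times, erp.times
    ):
        raise ValueError("epochs and ERP axes do not match")
    if epochs.samples.shape[:2] != erp.waveform.shape[:2]:
        raise ValueError("subject/condition cells do not match")
    out = epochs.samples.copy()
    for s in range(out.shape[0]):
        for c in range(out.shape[1]):
            if erp.n_trials[s, c]:
                out[s, c] -= erp.waveform[s, c][None, :, :]
    return replace_samples(epochs, out)


def replace_samples(epochs: EpochedData, samples: np.ndarray) -> EpochedData:
    return EpochedData(
        samples=samples,
        sampling_rate=epochs.sampling_rate,
        times=epochs.times,
        channel_names=epochs.channel_names,
        condition_labels=epochs.condition_labels,
        reaction_times=epochs.reaction_times,
        accuracy=epochs.accuracy,
    )


def response_locked_erp(epochs: EpochedData, window=(-0.5, 1.0)) -> ERPData:
    """ERP re-anchored at the response (t=0 at each trial's reaction time).

    Trials are shifted by the nearest whole sample (no interpolation);
    trials whose shifted window leaves the epoch are dropped from the
    average.
    """
    fs = epochs.sampling_rate
    n_out = int(round((window[1] - window[0]) * fs))
    out_times = window[0] + np.arange(n_out) / fs
    S, C, T, Ch, N = epochs.samples.shape
    wave = np.full((S, C, Ch, n_out), np.nan)
    counts = np.zeros((S, C), dtype=int)
    t0 = epochs.times[0]
    for s in range(S):
        for c in range(C):
            acc = []
            for tr in range(T):
                rt = epochs.reaction_times[s, c, tr]
                if not (epochs.accuracy[s, c, tr] and np.isfinite(rt)):
                    continue
                start = int(round((rt + window[0] - t0) * fs))
                if start < 0 or start + n_out > N:
                    continue
                acc.append(epochs.samples[s, c, tr, :, start : start + n_out])
            counts[s, c] = len(acc)
            if acc:
                wave[s, c] = np.mean(acc, axis=0)
    return ERPData(
        waveform=wave, times=out_times, n_trials=counts,
        channel_names=list(epochs.channel_names),
        condition_labels=list(epochs.condition_labels),
    )


def erp_aperiodic_r2(erp: ERPData, exponent_map, map_times, q: float = 0.05)\
        -> StatMap:
    """Signed marginal R² of ERP amplitude predicting the aperiodic exponent.

    The ERP waveform is resampled (nearest sample) onto the exponent map's
    time axis; the mixed model with subject and condition random intercepts
    is fitted per channel-timepoint.  Points with zero ERP variance are
    flagged missing by the underlying mass-univariate routine.
    """
    exponent_map = np.asarray(exponent_map, dtype=float)
    idx = np.searchsorted(erp.times, map_times)
    idx = np.clip(idx, 0, erp.times.size - 1)
    erp_on_map = erp.waveform[..., idx]
    if erp_on_map.shape != exponent_map.shape:
        raise ValueError("ERP and exponent map shapes do not align")
    return mass_univariate_r2(exponent_map, erp_on_map, q=q)
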
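"""Spectral parameterization: aperiodic power law plus Gaussian peaks.

The model of a neural power spectrum in semi-log space (log10 power over
linear frequency) is the sum of an aperiodic component
``b - chi * log10(f)`` (knee fixed at zero) and Gaussian peaks
``a * exp(-(f - c)^2 / (2 w^2))``.  Fitting proceeds as in the standard
parameterization algorithm:

1. robust aperiodic fit — an initial least-squares line in log-log space,
   then a refit restricted to points not inflated by peaks (flattened value
   at or below a low percentile of the flattened spectrum);
2. iterative peak extraction from the flattened spectrum, with a relative
   stopping threshold (multiples of the flattened SD), width limits, and an
   edge rule that discards candidates whose centre lies within
   ``bw_std_edge`` estimated SDs of either end of the fitted range;
3. a joint bounded least-squares refit of all retained Gaussians;
4. a final aperiodic refit on the peak-removed spectrum.

The edge rule is a deliberate guard against overfitting half-visible peaks,
and it has a documented failure mode: genuine oscillations at the lower
edge of the fitted range (e.g. ~3 Hz on a 3–50 Hz fit) are dropped and
their power is absorbed by the aperiodic component, inflating the exponent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "SpecparamSettings",
    "AperiodicFit",
    "PeakFit",
    "SpectralModel",
    "ParameterizedTFR",
    "robust_aperiodic_fit",
    "extract_peaks",
    "fit_spectrum",
    "reconstruct_periodic",
    "parameterize_tfr",
]


@dataclass(frozen=True)
class SpecparamSettings:
    """Fitting settings (defaults match the standard tool's)."""

    peak_width_limits: tuple = (0.5, 12.0)  # full bandwidth limits, Hz
    max_n_peaks: float = math.inf
    min_peak_height: float = 0.0  # absolute threshold, log10 units
    peak_threshold: float = 2.0  # relative threshold, SDs of flattened spectrum
    bw_std_edge: float = 1.0  # edge-exclusion distance, in peak SDs
    ap_percentile: float = 2.5  # robust-fit percentile of flattened spectrum
    gauss_overlap_thresh: float = 0.75  # overlap-drop distance, in peak SDs
    cf_bound: float = 1.5  # centre-frequency bound, in guess SDs

    @property
    def gauss_std_limits(self) -> tuple:
        lo, hi = self.peak_width_limits
        return lo / 2.0, hi / 2.0


@dataclass
class AperiodicFit:
    """Offset (log10 power) and exponent; slope = -exponent, knee fixed at 0."""

    offset: float
    exponent: float
    fallback: bool = False  # True if the robust refit fell back to the initial fit

    @property
    def slope(self) -> float:
        return -self.exponent

    def evaluate(self, freqs: np.ndarray) -> np.ndarray:
        return self.offset - self.exponent * np.log10(freqs)


@dataclass
class PeakFit:
    """One Gaussian peak: centre (Hz), height (log10 power), SD (Hz)."""

    center: float
    height: float
    sd: float

    @property
    def bandwidth(self) -> float:
        return 2.0 * self.sd

    def evaluate(self, freqs: np.ndarray) -> np.ndarray:
        return self.height * np.exp(-((freqs - self.center) ** 2) / (2 * self.sd**2))


@dataclass
class SpectralModel:
    """Fitted spectrum: aperiodic + peaks, with fit metrics in log space."""

    aperiodic: AperiodicFit
    peaks: list
    r_squared: float
    mean_abs_error: float
    freq_range: tuple
    settings: SpecparamSettings = field(default_factory=SpecparamSettings)

    def predict(self, freqs: np.ndarray) -> np.ndarray:
        return self.aperiodic.evaluate(freqs) + reconstruct_periodic(self, freqs)


def _linear_aperiodic_fit(freqs, log_power):
    """Plain least-squares line in (log10 f, log10 power) space."""
    slope, intercept = np.polyfit(np.log10(freqs), log_power, 1)
    return AperiodicFit(offset=float(intercept), exponent=float(-slope))


def robust_aperiodic_fit(freqs, log_power, percentile: float = 2.5) -> AperiodicFit:
    """Aperiodic fit resistant to peak contamination.

    An initial least-squares line is fitted; the residuals are flattened
    (negatives clipped to zero) and only the points whose flattened value is
    at or below the given percentile of the flattened spectrum are kept for
    the refit.  Because points under the line all clip to zero, the
    percentile threshold is typically zero, so the refit uses the
    peak-free half of the spectrum.  Falls back to the initial fit (with a
    flag) if fewer points than parameters survive masking.
    """
    freqs = np.asarray(freqs, dtype=float)
    log_power = np.asarray(log_power, dtype=float)
    if freqs.size < 5:
        raise ValueError("need at least 5 frequency points")
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be positive")
    initial = _linear_aperiodic_fit(freqs, log_power)
    flat = log_power - initial.evaluate(freqs)
    flat[flat < 0] = 0.0
    thresh = np.percentile(flat, percentile)
    keep = flat <= thresh
    if keep.sum() < 2:
        warnings.warn("robust aperiodic refit under-determined; using initial fit")
        return AperiodicFit(initial.offset, initial.exponent, fallback=True)
    refit = _linear_aperiodic_fit(freqs[keep], log_power[keep])
    return refit


def _estimate_sd_from_half_height(freqs, flat, max_ind, height, limits):
    """Guess a peak SD from the half-height crossings around the maximum."""
    half = 0.5 * height
    le_ind = ri_ind = None
    for j in range(max_ind - 1, -1, -1):
        if flat[j] <= half:
            le_ind = j
            break
    for j in range(max_ind + 1, flat.size):
        if flat[j] <= half:
            ri_ind = j
            break
    dists = [abs(ind - max_ind) for ind in (le_ind, ri_ind) if ind is not None]
    if dists:
        df = freqs[1] - freqs[0]
        fwhm = 2 * min(dists) * df
        guess_sd = fwhm / (2 * np.sqrt(2 * np.log(2)))
    else:
        guess_sd = np.mean(limits)
    return float(np.clip(guess_sd, *limits))


def _gaussian_sum(freqs, *params):
    out = np.zeros_like(freqs)
    for c, a, w in zip(params[0::3], params[1::3], params[2::3]):
        out = out + a * np.exp(-((freqs - c) ** 2) / (2 * w**2))
    return out


def _gaussian_sum_jac(freqs, *params):
    cols = []
    for c, a, w in zip(params[0::3], params[1::3], params[2::3]):
        d = freqs - c
        g = np.exp(-(d**2) / (2 * w**2))
        cols += [a * d / w**2 * g, g, a * d**2 / w**3 * g]
    return np.stack(cols, axis=1)


def extract_peaks(freqs, flattened_log_power,
                  settings: SpecparamSettings | None = None) -> list:
    """Iteratively extract Gaussian peaks from a flattened spectrum.

    Candidates are taken at the running maximum until it falls below
    ``max(peak_threshold * SD(flattened), min_peak_height)``; each fitted
    Gaussian is subtracted before the next search.  Candidates whose centre
    lies within ``bw_std_edge * SD`` of either range edge are subtracted but
    *not* retained.  Retained candidates are finally refit jointly by
    bounded least squares on the original flattened spectrum.
    """
    settings = settings or SpecparamSettings()
    freqs = np.asarray(freqs, dtype=float)
    flat = np.array(flattened_log_power, dtype=float)
    std_limits = settings.gauss_std_limits
    f_lo, f_hi = freqs[0], freqs[-1]

    guesses = []
    flat_iter = flat.copy()
    while len(guesses) < settings.max_n_peaks:
        max_ind = int(np.argmax(flat_iter))
        height = flat_iter[max_ind]
        if height <= max(settings.peak_threshold * np.std(flat_iter),
                         settings.min_peak_height):
            break
        center = freqs[max_ind]
        sd = _estimate_sd_from_half_height(freqs, flat_iter, max_ind, height,
                                           std_limits)
        flat_iter = flat_iter - height * np.exp(
            -((freqs - center) ** 2) / (2 * sd**2)
        )
        edge = settings.bw_std_edge * sd
        if (center - f_lo) > edge and (f_hi - center) > edge:
            guesses.append((center, height, sd))

    if not guesses:
        return []
    guesses = _drop_overlapping(guesses, settings.gauss_overlap_thresh)
    return _refit_peaks(freqs, flat,
                        [PeakFit(c, a, w) for c, a, w in guesses], settings)


def _drop_overlapping(guesses, overlap_thresh):
    """Among guesses whose centres lie within ``overlap_thresh`` summed SDs,
    keep only the taller one — overlapping Gaussians would otherwise split a
    single peak's mass between two fitted components."""
    guesses = sorted(guesses, key=lambda g: g[0])
    drop = set()
    for i in range(len(guesses) - 1):
        c0, a0, w0 = guesses[i]
        c1, a1, w1 = guesses[i + 1]
        if c0 + overlap_thresh * w0 > c1 - overlap_thresh * w1:
            drop.add(i if a0 < a1 else i + 1)
    return [g for i, g in enumerate(guesses) if i not in drop]


def _refit_peaks(freqs, flat, peaks, settings) -> list:
    """Jointly refit Gaussians on a flattened spectrum by bounded least squares."""
    std_limits = settings.gauss_std_limits
    f_lo, f_hi = freqs[0], freqs[-1]
    p0, lo, hi = [], [], []
    for p in peaks:
        p0 += [p.center, p.height, p.sd]
        lo += [max(f_lo, p.center - 2 * settings.cf_bound * p.sd), 0.0,
               std_limits[0]]
        hi += [min(f_hi, p.center + 2 * settings.cf_bound * p.sd), np.inf,
               std_limits[1]]
    p0 = np.clip(p0, lo, hi)
    try:
        popt, _ = curve_fit(_gaussian_sum, freqs, flat, p0=p0,
                            bounds=(lo, hi), jac=_gaussian_sum_jac,
                            maxfev=3000, xtol=1e-9, ftol=1e-9)
    except RuntimeError:
        popt = np.asarray(p0, dtype=float)
    refit = [
        PeakFit(center=float(c), height=float(a), sd=float(w))
        for c, a, w in zip(popt[0::3], popt[1::3], popt[2::3])
    ]
    # re-apply the edge rule: refitting may drift a centre into the
    # exclusion zone, and edge peaks are not retained by design
    edge = settings.bw_std_edge
    refit = [p for p in refit
             if (p.center - f_lo) > edge * p.sd and (f_hi - p.center) > edge * p.sd]
    refit.sort(key=lambda p: p.center)
    return refit


def _joint_polish(freqs, log_power, ap, peaks, settings):
    """Bounded least-squares refinement of aperiodic + peak parameters together."""
    log_f = np.log10(freqs)
    std_limits = settings.gauss_std_limits
    f_lo, f_hi = freqs[0], freqs[-1]

    def model(_, *params):
        return params[0] - params[1] * log_f + _gaussian_sum(freqs, *params[2:])

    def jac(_, *params):
        base = np.stack([np.ones_like(log_f), -log_f], axis=1)
        if len(params) > 2:
            return np.hstack([base, _gaussian_sum_jac(freqs, *params[2:])])
        return base

    p0 = [ap.offset, ap.exponent]
    lo = [-np.inf, -np.inf]
    hi = [np.inf, np.inf]
    for p in peaks:
        p0 += [p.center, p.height, p.sd]
        lo += [max(f_lo, p.center - 2 * settings.cf_bound * p.sd), 0.0,
               std_limits[0]]
        hi += [min(f_hi, p.center + 2 * settings.cf_bound * p.sd), np.inf,
               std_limits[1]]
    p0 = np.clip(p0, lo, hi)
    try:
        popt, _ = curve_fit(model, freqs, log_power, p0=p0, bounds=(lo, hi),
                            jac=jac, maxfev=3000, xtol=1e-10, ftol=1e-10)
    except RuntimeError:
        popt = np.asarray(p0, dtype=float)
    ap_out = AperiodicFit(float(popt[0]), float(popt[1]))
    peaks_out = [
        PeakFit(center=float(c), height=float(a), sd=float(w))
        for c, a, w in zip(popt[2::3], popt[3::3], popt[4::3])
    ]
    # the polish may drift a centre into the edge-exclusion zone; edge
    # peaks are not retained by design
    edge = settings.bw_std_edge
    peaks_out = [p for p in peaks_out
                 if (p.center - f_lo) > edge * p.sd
                 and (f_hi - p.center) > edge * p.sd]
    peaks_out.sort(key=lambda p: p.center)
    if len(peaks_out) < len(peaks):
        # refit the aperiodic line without the dropped peaks
        resid = log_power - reconstruct_periodic(peaks_out, freqs)
        ap_out = _linear_aperiodic_fit(freqs, resid)
    return ap_out, peaks_out


def fit_spectrum(freqs, linear_power,
                 settings: SpecparamSettings | None = None) -> SpectralModel:
    """Fit the full aperiodic + peaks model to a linear-power spectrum."""
    settings = settings or SpecparamSettings()
    freqs = np.asarray(freqs, dtype=float)
    linear_power = np.asarray(linear_power, dtype=float)
    if np.any(~np.isfinite(linear_power)) or np.any(linear_power <= 0):
        raise ValueError("power must be finite and strictly positive")
    log_power = np.log10(linear_power)

    ap = robust_aperiodic_fit(freqs, log_power, settings.ap_percentile)
    flat = log_power - ap.evaluate(freqs)
    peaks = extract_peaks(freqs, flat, settings)

    # final aperiodic refit on the peak-removed spectrum, then a joint
    # polish of all parameters together so the returned model sits at the
    # joint least-squares optimum (exact recovery on in-model spectra)
    peak_model = reconstruct_periodic(peaks, freqs)
    ap_final = _linear_aperiodic_fit(freqs, log_power - peak_model)
    ap_final, peaks = _joint_polish(freqs, log_power, ap_final, peaks, settings)
    ap_final.fallback = ap.fallback
    peak_model = reconstruct_periodic(peaks, freqs)
    model_log = ap_final.evaluate(freqs) + peak_model

    resid = log_power - model_log
    mae = float(np.mean(np.abs(resid)))
    denom = np.sum((log_power - log_power.mean()) ** 2)
    if denom > 0:
        r2 = float(np.corrcoef(log_power, model_log)[0, 1] ** 2)
    else:
        r2 = 1.0 if mae < 1e-12 else 0.0
    return SpectralModel(
        aperiodic=ap_final,
        peaks=peaks,
        r_squared=r2,
        mean_abs_error=mae,
        freq_range=(float(freqs[0]), float(freqs[-1])),
        settings=settings,
    )


def reconstruct_periodic(model_or_peaks, freqs) -> np.ndarray:
    """Sum of fitted Gaussians in log10 units; non-negative by construction."""
    freqs = np.asarray(freqs, dtype=float)
    peaks = getattr(model_or_peaks, "peaks", model_or_peaks)
    out = np.zeros_like(freqs)
    for p in peaks:
        out = out + p.evaluate(freqs)
    return out


@dataclass
class ParameterizedTFR:
    """Per-channel-timepoint spectral parameters of a TFR.

    Maps are defined inside the analysis window only; ``failed`` flags
    fits that raised or fell back, which are left as NaN (never zero-filled,
    which would bias downstream statistics).
    """

    offset: np.ndarray  # (S, C, Ch, T_w)
    exponent: np.ndarray
    periodic: np.ndarray  # (S, C, Ch, F, T_w), log10 units, >= 0
    r_squared: np.ndarray
    mean_abs_error: np.ndarray
    n_peaks: np.ndarray
    failed: np.ndarray  # bool
    times: np.ndarray
    frequencies: np.ndarray
    window: tuple
    settings: SpecparamSettings

    @property
    def slope(self) -> np.ndarray:
        return -self.exponent


def parameterize_tfr(
    tfr,
    settings: SpecparamSettings | None = None,
    window: tuple = (-0.5, 2.0),
    time_step: int = 1,
) -> ParameterizedTFR:
    """Fit the spectral model at every channel x timepoint in the window.

    ``time_step`` subsamples the TFR time axis (1 = every timepoint) for
    workloads where full temporal resolution is not needed.  Timepoints
    where the TFR edge mask marks any frequency invalid are excluded.
    More than 5% failed fits triggers a warning listing the locations.
    """
    settings = settings or SpecparamSettings()
    times = tfr.times
    in_window = (times >= window[0]) & (times <= window[1])
    if tfr.valid is not None:
        in_window &= np.all(tfr.valid, axis=0)
    t_idx = np.flatnonzero(in_window)[::time_step]
    if t_idx.size == 0:
        raise ValueError("no valid timepoints inside the analysis window")

    S, C, Ch, F, _ = tfr.power.shape
    Tw = t_idx.size
    freqs = tfr.frequencies
    offset = np.full((S, C, Ch, Tw), np.nan)
    exponent = np.full_like(offset, np.nan)
    r2 = np.full_like(offset, np.nan)
    mae = np.full_like(offset, np.nan)
    n_peaks = np.full_like(offset, np.nan)
    periodic = np.full((S, C, Ch, F, Tw), np.nan)
    failed = np.zeros((S, C, Ch, Tw), dtype=bool)

    for s in range(S):
        for c in range(C):
            if not np.isfinite(tfr.power[s, c, 0, 0, t_idx[0]]):
                failed[s, c] = True  # missing cell
                continue
            for ch in range(Ch):
                spectra = tfr.power[s, c, ch][:, t_idx]
                for j in range(Tw):
                    try:
                        m = fit_spectrum(freqs, spectra[:, j], settings)
                    except (ValueError, RuntimeError):
                        failed[s, c, ch, j] = True
                        continue
                    offset[s, c, ch, j] = m.aperiodic.offset
                    exponent[s, c, ch, j] = m.aperiodic.exponent
                    r2[s, c, ch, j] = m.r_squared
                    mae[s, c, ch, j] = m.mean_abs_error
                    n_peaks[s, c, ch, j] = len(m.peaks)
                    periodic[s, c, ch, :, j] = reconstruct_periodic(m.peaks, freqs)

    fail_frac = failed.mean()
    if fail_frac > 0.05:
        locs = np.argwhere(failed)
        warnings.warn(
            f"{fail_frac:.1%} of spectral fits failed; first locations "
            f"(subject, condition, channel, time): {locs[:5].tolist()}"
        )
    return ParameterizedTFR(
        offset=offset, exponent=exponent, periodic=periodic,
        r_squared=r2, mean_abs_error=mae, n_peaks=n_peaks, failed=failed,
        times=times[t_idx], frequencies=freqs, window=window, settings=settings,
    )
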
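"""Ground-truth synthetic EEG generation.

Two layers of synthesis are provided:

* direct power spectra in log10 space (aperiodic power law + Gaussian
  peaks), used to characterise the spectral parameterization algorithm, and
* time-domain epoched multi-subject EEG whose 1/f background has a
  *time-varying* exponent, with amplitude-modulated oscillations, additive
  phase-locked transients (ERPs), white sensor noise, and ex-Gaussian
  reaction times.

The time-domain aperiodic generator is a random-phase multisine: a dense
grid of cosines whose per-component amplitude follows the instantaneous
target spectrum ``10**(b(t) - chi(t) * log10(f / pivot))``.  This gives
sample-exact control of the spectrum while the exponent evolves smoothly in
time; for any interval with constant parameters a Welch estimate of the
signal recovers the target log-log slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng

__all__ = [
    "ConditionLabel",
    "ExGaussParams",
    "ExponentEvent",
    "OscillationSpec",
    "ErpTemplate",
    "GroundTruthSpec",
    "EpochedData",
    "simulate_power_spectrum",
    "simulate_aperiodic_timeseries",
    "simulate_epochs",
    "simulate_rts",
    "default_spec",
]

ConditionLabel = tuple[str, str, str]
"""(modality, load, stimulus-type) triple identifying a condition cell."""


def _as_rng(seed) -> Generator:
    if isinstance(seed, Generator):
        return seed
    return default_rng(seed)


# ---------------------------------------------------------------------------
# direct spectra
# ---------------------------------------------------------------------------

def simulate_power_spectrum(aperiodic, peaks, freqs, noise_sd=0.0, seed=None):
    """Evaluate the aperiodic + Gaussian-peaks model in log10-power units.

    Parameters
    ----------
    aperiodic : (b, chi)
        Offset (log10 power) and exponent of the power-law background.
    peaks : sequence of (center_hz, height, sd_hz)
        Gaussian peaks, heights in log10-power units above the background.
    freqs : array
        Strictly increasing, positive frequency grid in Hz.
    noise_sd : float
        SD of independent Gaussian noise added per frequency (log10 units).
    seed : int, Generator, optional
        Source of randomness for the noise; deterministic given a seed.

    Returns
    -------
    ndarray of log10 power per frequency.
    """
    freqs = np.asarray(freqs, dtype=float)
    b, chi = (float(v) for v in aperiodic)
    if freqs.ndim != 1 or freqs.size == 0:
        raise ValueError("freqs must be a non-empty 1-D array")
    if np.any(freqs <= 0):
        raise ValueError("all frequencies must be positive")
    if np.any(np.diff(freqs) <= 0):
        raise ValueError("freqs must be strictly increasing")
    if not (np.isfinite(b) and np.isfinite(chi)):
        raise ValueError("aperiodic parameters must be finite")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    log_power = b - chi * np.log10(freqs)
    for center, height, sd in peaks:
        if not all(np.isfinite([center, height, sd])):
            raise ValueError("peak parameters must be finite")
        if sd <= 0:
            raise ValueError("peak sd must be positive")
        log_power = log_power + height * np.exp(-((freqs - center) ** 2) / (2 * sd**2))
    if noise_sd > 0:
        log_power = log_power + _as_rng(seed).normal(0.0, noise_sd, freqs.size)
    return log_power


# ---------------------------------------------------------------------------
# time-domain aperiodic background
# ---------------------------------------------------------------------------

def _multisine(chi_t, b_t, sampling_rate, phases, freq_grid,
               pivot_hz=1.0, _chunk=48):
    """Random-phase multisine with time-varying 1/f amplitude profile.

    ``chi_t``/``b_t`` have shape (..., n); ``phases`` has shape (..., n_f)
    with matching leading dims.  Returns a real signal of shape (..., n)
    whose one-sided spectral density at time t is
    ``10**(b_t - chi_t * log10(f / pivot_hz))``.
    """
    chi_t = np.asarray(chi_t, dtype=float)
    b_t = np.asarray(b_t, dtype=float)
    n = chi_t.shape[-1]
    t = np.arange(n) / sampling_rate
    df = float(freq_grid[1] - freq_grid[0]) if freq_grid.size > 1 else 1.0
    out = np.zeros(chi_t.shape, dtype=float)
    log_f = np.log10(freq_grid / pivot_hz)
    for start in range(0, freq_grid.size, _chunk):
        f = freq_grid[start : start + _chunk]
        lf = log_f[start : start + _chunk]
        ph = phases[..., start : start + f.size]
        log_psd = b_t[..., None, :] - chi_t[..., None, :] * lf[:, None]
        amp = np.sqrt(2.0 * df * 10.0**log_psd)
        arg = 2 * np.pi * f[:, None] * t[None, :] + ph[..., None]
        out += np.einsum("...fn,...fn->...n", amp, np.cos(arg))
    return out


def simulate_aperiodic_timeseries(
    exponent_timecourse,
    offset_timecourse,
    sampling_rate: float,
    duration: float,
    seed=None,
    freq_resolution: float = 0.5,
    pivot_hz: float = 1.0,
):
    """Real-valued signal whose short-time spectrum tracks a 1/f target.

    ``exponent_timecourse`` and ``offset_timecourse`` may be scalars or
    arrays of length ``round(duration * sampling_rate)``.  For any interval
    where both are constant, the log-log slope of a Welch spectral estimate
    of the output equals ``-exponent`` (up to estimator leakage) and raising
    the offset by 1 multiplies spectral power by 10 at every frequency.
    Deterministic given ``seed``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    n = int(round(duration * sampling_rate))
    chi_t = np.broadcast_to(np.asarray(exponent_timecourse, dtype=float), (n,)).copy()
    b_t = np.broadcast_to(np.asarray(offset_timecourse, dtype=float), (n,)).copy()
    if np.any(chi_t < 0):
        raise ValueError("exponent timecourse must be >= 0 everywhere")
    rng = _as_rng(seed)
    nyq = sampling_rate / 2.0
    freq_grid = np.arange(freq_resolution, nyq, freq_resolution)
    phases = rng.uniform(0, 2 * np.pi, freq_grid.size)
    return _multisine(chi_t, b_t, sampling_rate, phases, freq_grid,
                             pivot_hz=pivot_hz)


# ---------------------------------------------------------------------------
# epoched EEG
# ---------------------------------------------------------------------------

@dataclass
class ExGaussParams:
    """Ex-Gaussian reaction-time model: Normal(mu, sigma^2) + Exp(tau), seconds."""

    mu: float
    sigma: float
    tau: float

    def validate(self) -> None:
        if not (self.mu > 0 and self.sigma > 0 and self.tau > 0):
            raise ValueError("ex-Gaussian parameters must all be positive")


@dataclass
class ExponentEvent:
    """Transient change of the aperiodic exponent.

    ``shape='gaussian'`` is a Gaussian-in-time bump centred at ``latency_s``
    with temporal SD ``width_s``; ``shape='plateau'`` holds the full ``delta``
    between ``latency_s`` and ``latency_s + width_s`` with 0.1-s cosine ramps.
    ``channels`` is a channel-group name or a weight vector in [0, 1];
    ``condition_modulation`` maps condition-label components (e.g. "target")
    to multiplicative factors on ``delta``.
    """

    latency_s: float
    width_s: float
    delta: float
    channels: object = None
    condition_modulation: dict = field(default_factory=dict)
    shape: str = "gaussian"

    def timecourse(self, times: np.ndarray) -> np.ndarray:
        if self.shape == "gaussian":
            return np.exp(-((times - self.latency_s) ** 2) / (2 * self.width_s**2))
        if self.shape == "plateau":
            return _plateau(times, self.latency_s, self.width_s, ramp=0.1)
        raise ValueError(f"unknown event shape {self.shape!r}")


@dataclass
class OscillationSpec:
    """Narrow-band oscillation with optional post-stimulus suppression.

    The amplitude envelope equals ``pre_stimulus_level`` before
    ``suppression_onset_s`` and drops by ``suppression_depth`` (fraction in
    [0, 1]) over the suppression interval, with smooth cosine ramps.  The
    per-trial phase is uniform-random (induced, not phase-locked activity).
    ``condition_modulation`` scales the suppression depth per condition.
    """

    freq_hz: float
    amplitude: float
    channels: object = None
    pre_stimulus_level: float = 1.0
    suppression_onset_s: float = 0.2
    suppression_duration_s: float = 0.8
    suppression_depth: float = 0.0
    condition_modulation: dict = field(default_factory=dict)

    def envelope(self, times: np.ndarray, depth: float) -> np.ndarray:
        g = _plateau(times, self.suppression_onset_s, self.suppression_duration_s,
                     ramp=0.1)
        return self.pre_stimulus_level * (1.0 - depth * g)


@dataclass
class ErpTemplate:
    """Phase-locked transient added identically to every trial."""

    amplitude: float
    latency_s: float
    width_s: float
    channels: object = None

    def waveform(self, times: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(
            -((times - self.latency_s) ** 2) / (2 * self.width_s**2)
        )


def _plateau(t: np.ndarray, onset: float, duration: float, ramp: float = 0.1):
    """Smooth boxcar: 0 before onset, 1 on the plateau, cosine ramps."""
    g = np.zeros_like(t)
    rise = (t >= onset) & (t < onset + ramp)
    g[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - onset) / ramp))
    g[(t >= onset + ramp) & (t <= onset + duration)] = 1.0
    fall = (t > onset + duration) & (t < onset + duration + ramp)
    g[fall] = 0.5 * (1 + np.cos(np.pi * (t[fall] - onset - duration) / ramp))
    return g


@dataclass
class GroundTruthSpec:
    """Full description of a simulated multi-subject EEG study.

    The aperiodic background of every channel follows
    ``log10 PSD(f, t) = b(t) - chi(t) * log10(f / pivot_hz)``; exponent
    events rotate the spectrum around ``pivot_hz``, so a transient exponent
    increase raises power below the pivot and lowers it above — the
    low-frequency signature that baseline-corrected TFRs misattribute to
    oscillations.
    """

    n_subjects: int = 20
    condition_labels: list = field(
        default_factory=lambda: [
            ("visuospatial", "0back", "nontarget"),
            ("visuospatial", "0back", "target"),
            ("visuospatial", "2back", "nontarget"),
            ("visuospatial", "2back", "target"),
            ("verbal", "0back", "nontarget"),
            ("verbal", "0back", "target"),
            ("verbal", "2back", "nontarget"),
            ("verbal", "2back", "target"),
        ]
    )
    trials_per_condition: int = 30
    n_channels: int = 8
    channel_groups: dict = field(default_factory=dict)
    sampling_rate: float = 200.0
    epoch_window: tuple = (-1.5, 2.8)
    aperiodic_offset: float = 0.0
    aperiodic_exponent: float = 1.2
    pivot_hz: float = 25.0
    exponent_events: list = field(default_factory=list)
    oscillations: list = field(default_factory=list)
    erp_template: ErpTemplate | None = None
    subject_sd_offset: float = 0.1
    subject_sd_exponent: float = 0.1
    sensor_noise_sd: float = 0.05
    rt_models: dict = field(default_factory=dict)
    seed: int = 0
    freq_resolution: float = 0.5

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        start, end = self.epoch_window
        if not (start < 0 < end):
            raise ValueError("epoch_window must contain 0 (stimulus onset)")
        if self.aperiodic_exponent < 0:
            raise ValueError("baseline exponent must be >= 0")
        if self.trials_per_condition < 1 or self.n_subjects < 1:
            raise ValueError("counts must be >= 1")
        if len(set(self.condition_labels)) != len(self.condition_labels):
            raise ValueError("condition labels must be unique")
        for osc in self.oscillations:
            if not 0.0 <= osc.suppression_depth <= 1.0:
                raise ValueError("suppression depth must be in [0, 1]")
        for name, w in self.channel_groups.items():
            w = np.asarray(w, dtype=float)
            if w.shape != (self.n_channels,):
                raise ValueError(
                    f"channel group {name!r} has {w.size} weights, "
                    f"expected {self.n_channels}"
                )
            if np.any((w < 0) | (w > 1)):
                raise ValueError(f"channel group {name!r} weights outside [0, 1]")
        for params in self.rt_models.values():
            params.validate()

    # -- helpers ----------------------------------------------------------
    def times(self) -> np.ndarray:
        start, end = self.epoch_window
        n = int(round((end - start) * self.sampling_rate))
        return start + np.arange(n) / self.sampling_rate

    def resolve_channels(self, channels) -> np.ndarray:
        if channels is None:
            return np.ones(self.n_channels)
        if isinstance(channels, str):
            try:
                return np.asarray(self.channel_groups[channels], dtype=float)
            except KeyError:
                raise ValueError(f"unknown channel group {channels!r}") from None
        w = np.asarray(channels, dtype=float)
        if w.shape != (self.n_channels,):
            raise ValueError("channel weight vector has wrong length")
        return w

    def rt_model(self, label: ConditionLabel) -> ExGaussParams:
        return self.rt_models.get(label, ExGaussParams(0.6, 0.08, 0.2))


def _condition_factor(modulation: dict, label: ConditionLabel) -> float:
    """Multiply modulation factors matching the full label or any component."""
    factor = 1.0
    if tuple(label) in modulation:
        factor *= modulation[tuple(label)]
    for part in label:
        if part in modulation:
            factor *= modulation[part]
    return factor


@dataclass
class EpochedData:
    """Single-trial EEG across subjects and conditions.

    ``samples`` has shape (subject, condition, trial, channel, time);
    the time axis is in seconds with the stimulus at 0.
    """

    samples: np.ndarray
    sampling_rate: float
    times: np.ndarray
    channel_names: list
    condition_labels: list
    reaction_times: np.ndarray  # (subject, condition, trial), NaN = missing
    accuracy: np.ndarray  # bool, same shape

    def validate(self) -> None:
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        dt = np.diff(self.times)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0]):
            raise ValueError("time axis must be strictly increasing and uniform")
        rts = self.reaction_times
        if np.any(rts[np.isfinite(rts)] <= 0):
            raise ValueError("reaction times must be positive where present")
        s, c, t, ch, n = self.samples.shape
        if (len(self.channel_names) != ch or len(self.condition_labels) != c
                or self.times.size != n or rts.shape != (s, c, t)):
            raise ValueError("metadata dimensions inconsistent with samples")

    @property
    def n_subjects(self):
        return self.samples.shape[0]

    @property
    def n_conditions(self):
        return self.samples.shape[1]

    @property
    def n_trials(self):
        return self.samples.shape[2]

    @property
    def n_channels(self):
        return self.samples.shape[3]


def simulate_rts(rt_model, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` i.i.d. ex-Gaussian reaction times (seconds)."""
    if isinstance(rt_model, tuple):
        rt_model = ExGaussParams(*rt_model)
    rt_model.validate()
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    return rng.normal(rt_model.mu, rt_model.sigma, n) + rng.exponential(rt_model.tau, n)


def simulate_epochs(spec: GroundTruthSpec) -> EpochedData:
    """Generate epoched EEG according to ``spec``.

    Per-subject aperiodic baselines are drawn once per subject; exponent
    events, oscillation envelopes and the ERP template are deterministic
    given the spec; per-trial randomness (background phases, oscillation
    phases, sensor noise, reaction times) comes from independent substreams
    spawned from ``spec.seed``, so two runs with the same spec are
    bit-identical.
    """
    spec.validate()
    times = spec.times()
    n = times.size
    fs = spec.sampling_rate
    n_cond = len(spec.condition_labels)
    nyq = fs / 2.0
    freq_grid = np.arange(spec.freq_resolution, nyq, spec.freq_resolution)

    samples = np.empty(
        (spec.n_subjects, n_cond, spec.trials_per_condition, spec.n_channels, n)
    )
    rts = np.empty((spec.n_subjects, n_cond, spec.trials_per_condition))
    acc = np.ones_like(rts, dtype=bool)

    event_weights = [spec.resolve_channels(ev.channels) for ev in spec.exponent_events]
    osc_weights = [spec.resolve_channels(o.channels) for o in spec.oscillations]
    erp_wave = None
    if spec.erp_template is not None:
        w = spec.resolve_channels(spec.erp_template.channels)
        erp_wave = w[:, None] * spec.erp_template.waveform(times)[None, :]

    subject_seeds = SeedSequence(spec.seed).spawn(spec.n_subjects)
    for s, subj_seed in enumerate(subject_seeds):
        subj_rng = default_rng(subj_seed)
        b0 = spec.aperiodic_offset + subj_rng.normal(0, spec.subject_sd_offset)
        chi0 = max(
            0.0, spec.aperiodic_exponent + subj_rng.normal(0, spec.subject_sd_exponent)
        )
        for c, label in enumerate(spec.condition_labels):
            # channel x time exponent timecourse for this cell
            chi_t = np.full((spec.n_channels, n), chi0)
            for ev, w in zip(spec.exponent_events, event_weights):
                mod = _condition_factor(ev.condition_modulation, label)
                chi_t += ev.delta * mod * w[:, None] * ev.timecourse(times)[None, :]
            np.clip(chi_t, 0.0, None, out=chi_t)
            b_t = np.full((spec.n_channels, n), b0)

            envs = []
            for osc, w in zip(spec.oscillations, osc_weights):
                depth = np.clip(
                    osc.suppression_depth
                    * _condition_factor(osc.condition_modulation, label),
                    0.0, 1.0,
                )
                envs.append((osc, w, osc.envelope(times, depth)))

            for tr in range(spec.trials_per_condition):
                trial_rng = subj_rng
                phases = trial_rng.uniform(
                    0, 2 * np.pi, (spec.n_channels, freq_grid.size)
                )
                x = _multisine(
                    chi_t, b_t, fs, phases, freq_grid, pivot_hz=spec.pivot_hz
                )
                for osc, w, env in envs:
                    phi = trial_rng.uniform(0, 2 * np.pi)
                    x += (
                        osc.amplitude
                        * w[:, None]
                        * env[None, :]
                        * np.cos(2 * np.pi * osc.freq_hz * times + phi)[None, :]
                    )
                if erp_wave is not None:
                    x += erp_wave
                if spec.sensor_noise_sd > 0:
                    x += trial_rng.normal(0, spec.sensor_noise_sd, x.shape)
                samples[s, c, tr] = x
            rts[s, c] = simulate_rts(
                spec.rt_model(label), spec.trials_per_condition, subj_rng
            )

    data = EpochedData(
        samples=samples,
        sampling_rate=fs,
        times=times,
        channel_names=[f"ch{i:02d}" for i in range(spec.n_channels)],
        condition_labels=list(spec.condition_labels),
        reaction_times=rts,
        accuracy=acc,
    )
    data.validate()
    return data


def _anterior_posterior_groups(n_channels: int) -> dict:
    """Four overlapping channel groups along an anterior-posterior axis."""
    pos = np.linspace(0.0, 1.0, n_channels)
    centers = {"frontal": 0.0, "central": 1 / 3, "parietal": 2 / 3,
               "occipital": 1.0}
    width = 0.25
    return {
        name: np.clip(1.0 - np.abs(pos - c) / (2 * width), 0.0, 1.0)
        for name, c in centers.items()
    }


def default_spec(**overrides) -> GroundTruthSpec:
    """A realistic working-memory-like study specification (8 channels).

    Frontal channels carry an early exponent increase (~0.3 s), parietal
    channels a later one (~0.7 s); posterior channels carry a 10 Hz
    oscillation suppressed post-stimulus, central channels a weaker 20 Hz
    one.  Reaction times are ex-Gaussian, slower under higher load.
    Overriding ``n_channels`` rebuilds the channel groups to match unless
    ``channel_groups`` is also given.
    """
    n_channels = overrides.get("n_channels", 8)
    spec = GroundTruthSpec(
        n_channels=n_channels,
        channel_groups=_anterior_posterior_groups(n_channels),
        exponent_events=[
            ExponentEvent(0.3, 0.15, 0.3, channels="frontal",
                          condition_modulation={"target": 1.2}),
            ExponentEvent(0.7, 0.2, 0.25, channels="parietal",
                          condition_modulation={"nontarget": 1.2}),
        ],
        oscillations=[
            OscillationSpec(10.0, 10.0, channels="occipital",
                            suppression_onset_s=0.2, suppression_duration_s=0.8,
                            suppression_depth=0.6,
                            condition_modulation={"2back": 1.2}),
            OscillationSpec(20.0, 4.0, channels="central",
                            suppression_onset_s=0.2, suppression_duration_s=0.6,
                            suppression_depth=0.4),
        ],
        erp_template=ErpTemplate(2.0, 0.25, 0.08, channels="frontal"),
        rt_models={
            label: ExGaussParams(0.55 if "0back" in label else 0.7, 0.08, 0.2)
            for label in [
                ("visuospatial", "0back", "nontarget"),
                ("visuospatial", "0back", "target"),
                ("visuospatial", "2back", "nontarget"),
                ("visuospatial", "2back", "target"),
                ("verbal", "0back", "nontarget"),
                ("verbal", "0back", "target"),
                ("verbal", "2back", "nontarget"),
                ("verbal", "2back", "target"),
            ]
        },
    )
    for key, value in overrides.items():
        setattr(spec, key, value)
    return spec
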
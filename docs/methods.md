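# Methods

This note documents the models, algorithms and design choices in
`specdyn`, in the order data flows through the pipeline.

## Synthetic ground truth (`specdyn.synth`)

**Aperiodic background.** Every channel's background follows
`log10 PSD(f, t) = b(t) − χ(t)·log10(f / f_pivot)`.  The time-domain
realisation is a random-phase multisine: a dense grid of cosines
(default spacing 0.5 Hz, up to Nyquist) whose per-component amplitude
`sqrt(2·Δf·PSD(f, t))` follows the instantaneous target spectrum.  This
gives sample-exact control of the spectrum while the exponent evolves
smoothly in time; windowed synthesis schemes were rejected because they
quantise the exponent timecourse at the window hop, too coarse for the
0.15–0.6 s exponent events the package simulates.  For any interval with
constant parameters, a Welch estimate of the output recovers the target
log-log slope (bias < 0.05 over seeded realisations; the residual per-bin
scatter comes from leakage interference between neighbouring components
and averages out).

**The pivot frequency** (`pivot_hz`, default 25 Hz) is where the spectrum
rotates when the exponent changes: a transient exponent increase raises
power below the pivot and lowers it above, which is the empirically
observed signature of slope steepening (low-frequency power up,
gamma-range power down).  With the textbook parameterization (pivot at
1 Hz, offset fixed) an exponent increase would *lower* power at every
analysed frequency, which reproduces neither real data nor the
baseline-correction artefact the package demonstrates.

**Exponent events** are Gaussian bumps (latency, temporal SD) or smoothed
plateaus (latency, duration, 0.1 s cosine ramps) added to χ(t), weighted
per channel group and optionally scaled per condition.  **Oscillations**
are sinusoids with per-trial uniform-random phase (induced activity) and a
suppression envelope: amplitude drops by `depth ∈ [0, 1]` between onset and
onset + duration, again with cosine ramps.  **ERP transients** are
Gaussian-envelope deflections added identically to every trial
(phase-locked by construction), so ERP subtraction can be validated against
the evoked/induced distinction.  **Reaction times** are ex-Gaussian
(Normal(μ, σ²) + Exp(τ)) per condition.

**Default study conditions** (`default_spec`): 20 subjects × 8 conditions
(modality × load × stimulus-type) × 30 trials, 8 channels in four
overlapping anterior–posterior groups, 200 Hz sampling, epochs −1.5 to
2.8 s.  The exponent baseline is χ₀ = 1.2 with between-subject SD 0.1;
two exponent events (frontal ~0.3 s, Δχ = 0.3; parietal ~0.7 s,
Δχ = 0.25) mimic the early/late component structure of task data; a 10 Hz
posterior oscillation (amplitude 10, suppression depth 0.6) and a weaker
20 Hz central one provide alpha/beta dynamics; reaction times are slower
under the higher load (μ 0.55 vs 0.70 s).  The alpha amplitude was chosen
analytically so the fitted peak height (~0.4–0.6 log10 units above
background) matches typical posterior alpha.

**Determinism.** One master seed spawns per-subject substreams
(`numpy.random.SeedSequence`); identical specs produce bit-identical data.

**What the generator does not emulate:** electrode geometry and volume
conduction, artifacts (blinks, muscle), non-sinusoidal waveform shape,
knee-type spectra, trial-to-trial amplitude variability of oscillations,
and accuracy/lure structure.  Passing tests therefore demonstrate that the
*analysis chain* behaves correctly on signals with known spectral content,
not that real EEG satisfies the generative assumptions.

## Time-frequency decomposition (`specdyn.tfr`)

Complex Morlet wavelets with temporal SD `n_cycles / (2πf)`, truncated at
±5 SD, normalised to unit energy so the expected squared magnitude of the
response to broadband input approximates the spectral density at the
centre frequency regardless of bandwidth (absolute values therefore differ
from amplitude-normalised conventions — relevant when comparing offsets
across tools).  Multiplicative superlets combine, per frequency, the
Morlet responses with `i × base_cycles` cycles (i = 1..⌈o⌉) by a weighted
geometric mean of magnitudes; the order `o` is linearly interpolated
(default 1 → 20) across the analysed band (default 3–50 Hz, 1 Hz steps).
Fractional orders weight the last wavelet by `(o − ⌊o⌋)/o`, making the
output continuous in `o` and exactly equal to Morlet power at `o = 1`.
Single-trial power is averaged within subject × condition over
correct-response trials, then decimated to 100 Hz by plain subsampling
(the wavelet bandwidth has already smoothed power; no extra anti-alias
filter).  Samples within one wavelet half-length of either epoch edge are
flagged invalid and excluded downstream.

## Baseline correction (`specdyn.baseline`)

Four variants — decibel `10·log10(P/B)`, relative `(P−B)/B`, normalised
`(P−B)/(P+B)`, absolute `P−B` — with `B` the arithmetic time-mean of power
in one of three pre-stimulus windows ((−0.5, −0.2), (−0.3, 0), (−0.5, 0) s),
computed per subject × condition × channel × frequency from that cell's own
trial-averaged power.  Ratio methods require a strictly positive baseline
and report the offending channel/frequency otherwise.

## Spectral parameterization (`specdyn.specparam`)

The algorithm mirrors the standard fixed-mode parameterization:

1. **Robust aperiodic fit** — least-squares line in (log10 f, log10 P);
   residuals clipped below zero; points at or below the 2.5th percentile
   of the clipped residuals kept for a refit (in practice the peak-free
   half of the spectrum).
2. **Iterative peak extraction** — repeat: take the flattened-spectrum
   maximum; stop below `max(2.0 × SD(flattened), min height 0)`; guess the
   Gaussian SD from the nearest half-height crossing (clipped to half the
   0.5–12 Hz bandwidth limits); subtract; *drop* the candidate if its
   centre lies within 1.0 estimated SD of either range edge.  Overlapping
   guesses (centres within 0.75 summed SDs) keep only the taller, so one
   peak's mass is never split across two Gaussians.
3. **Joint refit** — all retained Gaussians refit together by bounded
   least squares (centres within ±3 guess-SDs, heights ≥ 0, SDs within the
   width limits), then a final aperiodic refit on the peak-removed
   spectrum, then a **joint polish** of aperiodic + peak parameters
   together (analytic Jacobian, tolerance 1e-10).  The polish resolves the
   small residual coupling a single alternation pass leaves between the
   aperiodic line and the peaks; on noiseless in-model spectra recovery is
   exact to optimizer tolerance.  Peaks that drift into the edge-exclusion
   zone during refinement are discarded, consistently with step 2.

Reported bandwidth is `2 × SD`.  Fit quality is summarised by R²
(squared correlation of model and observed log-power) and the mean
absolute error in log10 units; the full-model residual mean-absolute value
equals the reported error exactly.  `parameterize_tfr` fits every
channel × timepoint inside the analysis window (default −0.5 to 2 s, edge
mask respected); failed fits are flagged NaN, never zero-filled, and a
warning lists locations when more than 5% fail.

**The edge rule is a documented failure mode, on purpose:** genuine
oscillations at the low edge of the fitted range (≈3 Hz on a 3–50 Hz fit)
are dropped and their power is absorbed by the aperiodic component,
inflating the exponent (validation: detection < 1% at 3 Hz vs 100% at
10 Hz, positive mean exponent bias).  Interpreting exponent maps where
true low-frequency oscillations are plausible requires the rhythmicity
cross-check below.

## Rhythmicity (`specdyn.rhythmicity`)

The phase-autocorrelation function: per evaluated frequency, the analytic
signal comes from 3-cycle Morlet convolution (superlets are unsuitable for
phase because the mixed-width combination distorts phase autocorrelation).
For each lag `l` in 1.0–3.0 cycles (0.1 steps, converted to samples by
rounding, duplicates dropped), the unit phasors
`exp(j(φ_t − φ_{t−l}))` are averaged in a centred window of 2.5 cycles and
the magnitude taken; pACF(t) is the unweighted mean across lags.  The
magnitude is taken after window-averaging per lag (before averaging across
lags), which yields a real index bounded in [0, 1]; the lag grid starts at
1 cycle because a zero lag is identically 1 and lags below a cycle mostly
reflect filter autocorrelation.  Unit normalisation makes the measure
exactly amplitude-invariant.  Timepoints whose window or maximal lag
leaves the valid region are masked.

## Mixed-model statistics (`specdyn.mixedstats`)

Random-intercept linear mixed models fitted by maximum likelihood (not
REML).  The profiled marginal likelihood is optimised over log-variances
(L-BFGS-B); all linear algebra goes through the Woodbury identity, so cost
scales with the number of random-effect levels rather than rows.
Condition comparisons use
`y ~ 1 + modality*nback*stimulus + rt + (1|subject)` with sum-to-zero
(±1) coding so main effects are interpretable under the full interaction
model; degenerate (single-level) factors are dropped with a notice; the
reaction-time covariate is the cell-level ex-Gaussian μ, mean-centred.
Correlation maps use a single fixed predictor with crossed subject and
condition random intercepts.

Satterthwaite denominator degrees of freedom:
`df = 2·g² / (∇g' I⁻¹ ∇g)` with `g(θ) = Var(ĉ'β̂)` differentiated
analytically in the variance parameters and `I` the expected Fisher
information; variance components estimated at (effectively) zero are
treated as fixed, which reduces to the classical residual df in the
no-random-variance limit.  Signed marginal R² is
`σ_f² / (σ_f² + Σ σ_k² + σ_ε²)` with `σ_f²` the variance of the fitted
fixed-effect predictions, signed by the focal coefficient (only
single-focal-predictor models are signed).  Multiplicity: Benjamini–
Yekutieli step-up (valid under arbitrary dependence; delegated to
statsmodels and verified against a brute-force implementation of the
step-up definition), followed by a cluster rule — a significant point
survives only within a run of ≥ 3 consecutive timepoints at its channel or
with ≥ 3 channels simultaneously significant at its timepoint (no spatial
adjacency structure is imposed).  Inference always uses un-averaged maps.

Ex-Gaussian reaction-time fits remove within-cell values with z > 3 or
below 0.2 s, then minimise the exponnorm negative log-likelihood
(Nelder-Mead, moment-based starts); μ is the cell summary, and cells with
fewer than 10 surviving values are flagged missing.

## ERP handling (`specdyn.erp`)

ERPs are arithmetic means over correct trials per subject × condition;
subtraction removes each cell's ERP from its single trials before
decomposition (trial mean exactly zero afterwards), which removes
phase-locked power while preserving induced power.  Response-locked ERPs
shift trials by the nearest whole sample (no interpolation).  The
ERP-vs-exponent control delegates to the correlation-map machinery with
ERP amplitude as the predictor.

## Validation studies and problem sizes (`specdyn.studies`)

All validation runs on synthetic data at desk scale: 200 random spectra
for recovery; a 108-point parameter grid for the edge study; the
misattribution demonstration at 20 subjects × 2 conditions × 30 trials ×
4 channels (exponent scenario) and 8 × 2 × 20 × 4 (alpha scenario), with
spectral parameterization applied to the group-average TFR in the
grand-average illustration convention; 64 channels in a fully crossed
amplitude × exponent design for the rhythmicity contrast (the background
pivots at 10 Hz so exponent differences leave alpha-band power unchanged
by construction); 30 + 30 replicates for the condition-pipeline power and
type-I study, with effects planted at the exponent-map level (subject
intercept SD 0.2, map noise SD 0.1 — map-level simulation is what the
statistics see, and the signal chain upstream is validated separately by
the recovery and misattribution studies); 100 seeds × 1000 draws for
ex-Gaussian recovery.

## Known limitations

* No knee-mode aperiodic fitting; spectra with a visible bend will bias χ.
* Single-trial spectra are never parameterized (trial-averaged only).
* The condition LMM supports two-level factors only (as in the intended
  designs); multi-level factors raise an error.
* pACF and exponent estimates are not fully independent in practice: a
  strong spectral peak leaks slightly into the exponent estimate
  (|Δχ| ≈ 0.02 across a 8:1 amplitude range in the validation study).
* The HDF5 container stores one run per file; there is no incremental
  append.
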
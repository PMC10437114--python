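# Methods

This note documents the statistical model, the defaults and why they were
chosen, the synthetic-data generator's scope, and the numerical decisions
that shape results. Nothing here states an empirical number that the test
suite or `scripts/acceptance.py` does not itself compute.

## Paradigm model

A run is `lead_in + n_cycles × (one block per condition) + lead_out`.
Defaults: four conditions (NMES+LO control, NMES+AO, NMES+AE, NMES+AI),
8 cycles, 15 s task + 20 s rest per block, 30 s lead-in/out → 32 blocks,
1180 s. Within each cycle the condition order is a uniform random
permutation; within each block five 3 s clips are drawn *without
replacement* from the ten-clip library of the matching video type (drawing
with replacement would allow duplicate clips inside one 15 s phase, which
the playback procedure excludes in practice). Task precedes rest within a
block: the stimulation envelope (1 s ramp, 15 s hold, 18 s interval) only
fits the block with the task phase first. The envelope itself is kept as
schedule metadata and not modelled hemodynamically — every condition
includes the stimulation, so it cancels from between-condition contrasts.

Sample alignment is half-open and 0-based: sample *k* belongs to an event
iff `onset ≤ k/fs < end`. This makes boxcar sums exact (8 blocks × 15 s ×
10 Hz = 1200 samples per condition) and is asserted in the tests.

## Optics

OD uses the natural-log convention, `OD = −ln(I/I_ref)`, with
`I_ref` = whole-recording mean per channel × wavelength. The mean
reference makes each OD trace approximately zero-mean; relative to a true
baseline it differs by a per-channel constant (`ln E[e^{−ΔOD}] ≠ E[ΔOD]`),
which the intercept drift regressor absorbs, so first-level inference is
unaffected. When the true emitted level is known (forward simulations) it
can be passed explicitly, making the forward/inverse composition exact to
machine precision.

The Beer–Lambert inversion solves the 2×2 system per sample. Extinction
coefficients ship as a packaged table in 1/(mM·cm) interpolated from the
standard compiled in-vitro hemoglobin spectra; defaults at 769/850 nm.
DPF defaults to 6.0 at both wavelengths (a common adult value; the
acquisition software's value is not public) and source–detector separation
to 3 cm — all configuration, not constants.

Channel quality combines intensity coefficient of variation (default bad
threshold 15%) and the cardiac-band (0.7–1.5 Hz) correlation between the
two wavelengths' band-passed OD (bad below 0.7) — a scalp-coupling-style
index: a coupled channel sees the same cardiac pulsation at both
wavelengths. The original cohort's exclusion rule ("poor signal quality")
is unquantified, so these thresholds are this package's operationalization.

No band-pass filtering precedes the GLM: drift is handled by design
regressors and serial correlation by prewhitening, avoiding interactions
between a filter and the AR model.

## First level: AR-IWLS

Per channel, `y = Xβ + ε` with X = condition boxcars convolved with the
canonical HRF plus Legendre drift polynomials (default order 3 per ~20 min
run). The HRF is a double gamma scaled to unit peak: main lobe mode 6 s
(shape from mode = (a−1)·scale with scale 1.2 s), undershoot mode 16 s,
undershoot ratio 1/6, 32 s support. Coefficients therefore keep μM units.

Estimation alternates until the coefficient vector changes by < 1e-6
relative (max 10 iterations; non-convergence is flagged, never silent):

1. (weighted) least squares for β;
2. AR(p) fit to the raw-scale residuals — one Levinson–Durbin pass over
   the residual autocovariance yields every order's innovation variance;
   p minimizes BIC over 0..max, max = 4·fs (AR memory scales with
   sampling rate; BIC keeps the order small unless the data insist);
3. prewhitening of y and X with `1 − φ₁B − … − φ_pB^p`;
4. Tukey-bisquare weights (c = 4.685) of whitened residuals standardized
   by MAD.

Covariance is `σ²(X_w'WX_w)⁻¹` with `σ² = Σw r² / (Σw − k)` divided by
the bisquare Gaussian-consistency factor `E[w z²]/E[w] ≈ 0.828` — without
it the weighted variance is biased low at the normal model and the t-tests
run anticonservative even on clean data. Degrees of freedom are
`Σw − rank(X)`. With AR order 0 and robust weighting off the estimator
reduces exactly to OLS (asserted to 1e-8).

Each condition is estimated against the implicit rest baseline;
condition−control differencing happens at the group stage, where the
between-subject variance belongs.

The first-level estimator follows the scikit-learn fit/predict protocol
(`ArIwlsGlm`), so it composes with sklearn tooling; the rest of the
pipeline is function-shaped.

## Group level

Per channel, subject condition coefficients enter
`β ~ condition + (1 | subject)` (REML, statsmodels). Contrast estimates
are the fixed-effect differences versus the control; p-values use the
normal approximation — adequate at the double-digit cohort sizes this
design targets, and Satterthwaite df are deliberately out of scope. A
degenerate mixed fit is retried with a derivative-free optimizer (the
default quasi-Newton step can hit a singular profiled information matrix
when a variance component sits on the boundary) and, failing that, falls
back to the paired-difference t-test with a logged warning; in the
balanced complete case the two agree on the point estimate, which the
tests exploit as a cross-check.

FDR: Benjamini–Hochberg within each contrast, across the 20 channels or
across the 6 ROIs. The multiple-testing family is per contrast because
that is how activation tables are reported; the original toolbox's family
is not documented, so this is a stated decision.

ROI aggregation happens on per-subject coefficients *before* the group
model (not on group-level statistics), preserving the between-subject
variance structure for the mixed model. Weights are the montage's printed
sensitivity percentages, column-normalized per ROI; channels with zero
weight in an ROI do not enter its average. The montage's "probability
registration" averaging is operationalized as exactly this weighted mean —
the weights table is the only operational definition available.

## Synthetic data

The generator emulates: per-subject randomized schedules; HbO responses as
amplitude × (boxcar ∗ HRF) with subject amplitudes `Normal(β_true, τ²)`
drawn independently per channel × condition; HbR tied to HbO by a fixed
−1/3 ratio plus independent noise (typical empirical anticorrelation; only
HbO is analyzed); noise = stationary AR(1) (φ = 0.8, innovation SD
0.5 μM) + cardiac 1.1 Hz (0.3 μM) + respiration 0.25 Hz (0.2 μM) + Mayer
0.1 Hz (0.3 μM), random phases + 0.1 μM/min drift + optional motion
spikes. The cohort's true noise magnitudes are unknown; these defaults
produce the serial correlation the prewhitening exists to handle and are
exposed in configuration. Forward optics write SNIRF files that round-trip
through the preprocessing chain.

Not emulated: layered scalp/skull optics, systemic superficial
contamination shared across channels, non-stationary noise, and
task-correlated motion. Passing tests therefore demonstrate correctness of
the estimation chain under a realistic stationary noise model, not
robustness to every artifact of real recordings.

## Problem sizes in tests and the acceptance script

Simulation-based checks use a reduced 2-cycle (8-block, 340 s) schedule at
5 Hz — the estimation problem is the same shape at a quarter the samples —
with 500 replicates for the type-I calibration (AR-IWLS within
[0.03, 0.07] at α = 0.05 while OLS inflates), 500 for the SE-vs-empirical-
SD comparison, and 50 replicate cohorts of 12 subjects (τ = 1 μM, 3.5 μM
effect on two channels) for power and false-flag rates. The demonstration
cohort in the acceptance script is full scale: 66 subjects, complete
1180 s paradigm at 10 Hz, with the published channel contrast effects as
generating truth and everything else at generator defaults.

## Known limitations

- No motion-artifact correction or short-channel regression; the robust
  weights are the only artifact defense.
- HbR/HbT are carried through conversion but not statistically modelled.
- Mixed-model inference is asymptotic (normal); small cohorts (< ~10
  subjects) should interpret borderline p-values cautiously.
- The SNIRF reader covers the continuous-wave amplitude layout this
  package writes, not every variant of the format.
- Montage geometry is metadata; no registration or sensitivity math is
  performed.
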
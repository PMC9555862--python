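# Methods

This note documents the models, estimators, numerical choices and known
limitations of the package. It is written for a reader who wants to know
exactly what is computed and what the synthetic-data tests do and do not
establish.

## Synthetic sessions and the planted geometry

The generator is the pipeline's ground-truth substrate. A session is a set
of trials (condition labels T, I, M, R, P, X), organized in runs of
block-randomized blocks: every block of 12 trials contains each of the 6
conditions exactly twice, mirroring a cue grid in which each condition
appears twice per screen. Trials last 3 s with the cue at 0.5 s
(configurable); spike counts are binned at 10–20 ms.

A target geometry is planted by inverting the distance definition. For a
target squared-distance matrix D over conditions, the double-centered Gram
matrix G = −½·C·(D·N)·C (C the centering matrix, N the unit count) is
eigendecomposed; condition patterns are rows of V·√Λ, embedded into the
N-dimensional unit space by a seeded random orthonormal rotation
(unique up to rotation; the seed fixes it). By construction the pairwise
squared Euclidean distances of the resulting condition-mean rate offsets,
divided by N, reproduce D — which is what the crossnobis estimator
converges to under identity noise whitening. A target whose Gram matrix
has a negative eigenvalue beyond tolerance is rejected with the offending
eigenvalue named. Offsets are shifted per neuron (a constant across
conditions, so distances are unchanged) to keep baseline + offset ≥ 0.

Firing rates are `baseline + Σ_c w_c(t) · μ_c[condition]`, where each
component c has its own embedded geometry and a piecewise-linear onset
ramp w_c (0 before onset, linear rise over `rise_time`, then 1). The ramp
parameterization is the package's choice: within-trial rate envelopes are
not constrained by the data the analysis emulates, so the simplest
monotone envelope was adopted and exposed in the component configuration.
Multiple components are embedded with independent seeds, so their pattern
subspaces are orthogonal in expectation and the measured RDM at any
timepoint is approximately the w²-weighted sum of the component RDMs.
Negative mixed rates are clipped at 0 and counted (`clipped_rate_bins`),
keeping the Poisson model valid while surfacing misconfiguration.

Noise is Poisson per bin by default (counts are spikes). A Gaussian option
produces real-valued counts with known isotropic noise for closed-form
oracle tests (e.g. the geometry round-trip below); it deliberately breaks
the integer-count invariant and is marked as such.

Because movement-specific tuning is absent in the No-Go condition, a
5-finger model RDM is extended to the 6 task conditions by placing X at
the centroid of the embedded finger patterns (`models.with_no_go`).

**What the generator does not emulate:** real spike-train temporal
structure (refractoriness, bursting, autocorrelation), electrode noise
correlations beyond what Poisson rates induce, behavioral variability
(reaction times, errors, eye movements), unit turnover within a session,
and any closed-loop dependence of behavior on decoder feedback. Passing
tests therefore establish estimator correctness and parameter recovery
under the stated noise model, not performance claims about real recordings.

## Crossnobis estimation

Trials are stratified-split into 5 folds (per-condition counts balanced to
within one trial; deterministic given the seed). Per fold, condition-mean
patterns and residuals around those means are computed; the noise
covariance is estimated per fold from the residuals pooled across
conditions and shrunk toward its diagonal with the analytic
Schäfer–Strimmer weight (off-diagonals scaled by 1−λ*, λ* estimated from
the data; a ~1e-10-relative ridge guarantees positive definiteness even
for silent units). For every unordered fold pair the quadratic form uses
the average of the two fold covariances; estimates are averaged over the
10 fold pairs. Averaging ordered pairs instead is algebraically identical
for this symmetrized form. The No-Go condition is dropped before
estimation, leaving 10 unique inter-finger distances.

Vectorization order is fixed everywhere (row-major upper triangle:
T-I, T-M, T-R, T-P, I-M, …), shared by data RDMs and model RDMs and
round-trip tested. Negative estimates are never clipped; only the MDS
embedding floors them at 0, for the embedding alone.

The Poisson symmetrized-KL estimator uses the same fold scheme; per fold
pair, Σ_units ½[(λ_jA−λ_kA)(ln λ_jB−ln λ_kB) + (A↔B)] / N, with rates
floored at 0.01 spikes/s before the log.

Whitening choice: the covariance is pooled across conditions within each
fold (residuals around per-condition means). An explicit matrix or
identity can be passed instead (`noise=` argument), which the oracle tests
use; whitening pooled differently is then a caller-side choice.

## Model RDMs

- **Somatotopy**: fingers at integer positions 1..5 on a 1-D cortical
  sheet, unit-norm Gaussian kernels of width `kernel_sd` (default 1.0
  finger-spacing; the width is a free parameter, exposed in config).
  Closed form d²(i,j) = 2 − 2·exp(−(i−j)²/(4·sd²)), verified against
  numerical integration.
- **Unstructured**: all 10 distances equal (max-scaled to 1). This is the
  task-optimal null — the task statistics carry no between-finger
  correlation — and the baseline against which cosine similarities are
  interpreted, since its centered vector is zero.
- **Usage / muscle / able-bodied**: consumed as 5×5 CSV fixtures. The
  shipped files are hand-constructed synthetic stand-ins (filenames say
  so): the usage and muscle matrices are deliberately near-duplicates
  (their real counterparts are nearly collinear), and the able-bodied
  matrix is thumb-distinct with a neighbor gradient, the structure real
  imaging RDMs show.
- Normalization: `max_scaled` for display conventions, `l2` before NNLS
  decomposition so coefficient magnitudes are comparable; both idempotent.

## WUC, whitening, ceilings and tests

WUC is the whitened cosine defined in the README. The whitening matrix V
is the covariance of the 10 RDM entries across independent estimates
(sessions), shrunk toward its diagonal like the noise covariance. With a
single RDM available, a structured fallback is used: V = 0.5·I +
0.25·A·Aᵀ with A the pair×condition incidence matrix (diagonal 1, 0.25
between pairs sharing a condition, 0 otherwise) — a heuristic encoding of
shared-data covariance, positive definite by construction, and logged when
used. Whitened Pearson is WUC on mean-centered vectors; it is undefined
for the unstructured model (centered zero vector), which the analysis
driver skips explicitly.

The noise ceiling is the leave-one-session-out mean similarity of each
session RDM with the mean of the others (the "lower" ceiling). The
bootstrap model contrast resamples sessions with replacement, compares the
bootstrap-mean RDM with both models, and applies a two-tailed one-sample
t-test to the bootstrap distribution of fit differences. The typicality
test takes sim(target, population mean) as the statistic and builds the
null by exchanging the target with a random population member; p is the
+1-corrected fraction of permuted statistics ≤ observed. The exchange
statistic is this package's reconstruction of a "permutation shuffle
test"; other statistics are possible.

MDS is classical (Torgerson) scaling per session; alignment is
Generalized Procrustes with rotation/reflection/translation but no
scaling, so inter-point distances are preserved (isometry is tested).

## NNLS dynamics

RDM movies use a 200-ms window sliding in 10-ms steps by default (the
window is a modeling constant; the step is free — the analysis drivers use
50 ms to keep runtimes small). Windows near trial edges are truncated and
rates renormalized by the covered length. Each timepoint's RDM is
decomposed by NNLS onto the ℓ2-normalized model basis; start time is the
first timepoint with coefficient strictly above 0.2 (never-crossing yields
NaN, and NaN pairs are dropped from timing tests with a logged count).
The 0.2 threshold is meaningful when peak coefficients are near 1 (≈25%
of peak); the synthetic study dataset's planted amplitudes are scaled to
put measured RDM norms in that regime. Onset lags are tested with the
two-sided Wilcoxon signed-rank across sessions, computed on per-session
coefficient curves (computing them on bootstrap-mean curves is the
documented alternative). Bootstrap bands on the coefficient time courses
are the SD of NNLS coefficients of bootstrap-mean movies (sessions
resampled with replacement), i.e. a bootstrap SEM.

VIF: each model is regressed on the others with zero-intercept OLS
(unconstrained) or NNLS, and VIF = 1/(1 − R²) with uncentered R². The
zero-intercept, uncentered convention matches the zero-intercept NNLS
decomposition the VIF is diagnosing and keeps R² in [0, 1), hence VIF ≥ 1;
R² within 1e-10 of 1 reports an infinite sentinel. Subset selection fits
each candidate subset by NNLS to the mean training RDM in a
leave-one-session-out loop, scores the reconstruction against the held-out
RDM by WUC, bootstraps sessions for the SE of the best subset's mean fit,
and picks the smallest subset within one SE of the best (ties: fewer
models, then lexicographic). Subsets containing members with VIF > 5 are
flagged, not excluded.

## Stability statistics

Distances from per-(session, run) RDMs are fit by OLS with one-hot finger
pair effects (their mean is the grand-mean distance β0), plus centered
session- and run-index regressors (centering is numerical only;
coefficients are per index step). Trend t-tests use df = number of RDMs —
deliberately conservative, because the 10 entries of an RDM covary and
must not be counted as independent observations. Cohen's f² compares the
full model against the finger-pair-only baseline:
f² = (R²_full − R²_base)/(1 − R²_full). The subset variant restricts the
table to named pairs (e.g. the high-confusion middle-ring and ring-pinky
pairs) with a one-tailed test for an increase.

Bayes factors are Jeffreys–Zellner–Siow: the two-sided BF10 integrates the
non-central-t likelihood over a Cauchy(0, √2/2) effect-size prior (the
cited default "medium" scale) by quadrature, cross-checked in tests
against the equivalent g-integral form and against pingouin. One-sided
BFs sample the posterior of the two-sided test (inverse-CDF sampling on a
dense grid; 10⁶ samples by default) and multiply by the directional
posterior mass over the prior odds (½). BF < 1/3 is reported as
substantial support for the null.

The session × model interaction test fits value ~ session + model +
session:model on per-session model fits of two models, one-tailed on the
interaction with df = n_sessions − 2. The design behind this test is a
reconstruction; its df convention is conservative for the same
shared-data reason as above.

## Numerical conventions and edge cases

- Diagonal LDA: pooled per-feature variances floored at 1e-6 (spikes/s)²;
  uniform priors (conditions are block-balanced); arg-max ties resolve to
  the lowest class index; features with session-mean rate < 1 Hz excluded
  (boundary inclusive: exactly 1 Hz is kept). The low-rate mask is fixed
  once per session, not refit per LOO fold.
- Threshold crossings: 1-ms refractory lockout after each detected event
  (prevents double-counting one waveform at 30 kHz sampling); an all-zero
  trace has RMS 0 and returns no events.
- Gap statistic: 20 uniform reference draws over the feature bounding box,
  within-cluster dispersion W_k = Σ_r Σ_{i∈r} ‖x_i − centroid_r‖², and the
  one-standard-error selection rule (smallest k with Gap(k) ≥ Gap(k+1) −
  s_{k+1}). Reference count and k-medoids restarts are config-exposed.
- L-ratio: "noise" events are all same-electrode events outside the
  cluster; χ² degrees of freedom equal the feature dimension; a singular
  cluster covariance is ridged with a logged shrinkage.
- Window selection ties resolve to the earliest candidate window.
- Seeds: every stochastic routine takes an explicit seed or Generator;
  identical inputs and seeds reproduce outputs bit-for-bit.

## Problem sizes

The test suite and drivers use deliberately scaled-down problem sizes
chosen to keep the statistical checks well-powered: null-calibration runs
use 150–500 simulated datasets of 20–50 units; the geometry round-trip
uses 200 trials/condition with Gaussian noise and identity whitening; the
dynamics-recovery studies use 10 sessions of 48–96 units and 144 trials
with a 50-ms sliding step. The synthetic study dataset keeps the
experiment's session count (10) and unit count (~96) but fewer trials per
session (144 vs ~400).

## Known limitations

- Crossnobis whitening uses fold-level shrinkage covariances estimated
  from limited trials; with strong Poisson rate-dependence of the noise,
  measured distances are attenuated relative to the planted
  (identity-noise) target. Geometry recovery is therefore tested with the
  Gaussian/identity oracle path, and rank-order agreement with the planted
  structure on the Poisson path.
- Highly collinear model bases make NNLS onsets noisy; the analysis
  dataset needs ~96 units for stable start-time ordering. This mirrors the
  real multicollinearity problem the VIF screen exists for.
- The bootstrap-t model contrast treats bootstrap draws as samples, which
  is anticonservative; it is implemented as specified and its p-values
  should be read accordingly.
- Trend t-statistics inherit correlation between RDM entries; the
  conservative df mitigates but does not remove the resulting dispersion,
  so single-realization trend p-values near 0.05 should not be
  over-read (the drivers' Bayes factors exist for exactly this reason).
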
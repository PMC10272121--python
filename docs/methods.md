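# Methods

## Problem setting

`dynconn` implements a seed-based dynamic functional-connectivity pipeline
for predicting a psychological trait (rumination-like questionnaire scores)
from resting-state-like multivariate time series. The working hypothesis of
the method is that the *temporal variability* of the correlation between a
seed region and each other region — not its average strength — carries
trait-relevant information. The pipeline estimates a time-varying
correlation path per (seed, target) edge, summarizes each edge by the
temporal variance of that path, fits sparse linear models from those
per-edge variances to trait scores, and screens the model family through a
multi-cohort selection cascade with a virtual-lesion refinement step.

## Dynamic conditional correlation (DCC) estimation

Each edge is estimated pairwise by the standard two-stage quasi-ML DCC
procedure:

1. **Variance stage.** Each series gets a univariate GARCH(1,1) fit with a
   constant mean (the series is demeaned; no autoregressive prewhitening by
   default): sigma^2_t = omega + alpha eps^2_{t-1} + beta sigma^2_{t-1},
   sigma^2_1 initialized at the sample variance. Gaussian
   quasi-log-likelihood is maximized with omega > 0, alpha, beta >= 0 and
   alpha + beta <= 0.999 enforced by a smooth log/logistic
   reparameterization. The optimizer works on the variance-standardized
   series, which makes the fit exactly invariant to positive rescaling of
   the input. Standardized residuals z_t = (x_t - mu)/sigma_t feed stage 2.
2. **Correlation stage.** For residual pair (z1, z2) with sample
   correlation Sbar, the recursion
   Q_t = (1 - t1 - t2) Sbar + t1 z_{t-1} z_{t-1}' + t2 Q_{t-1}, Q_1 = Sbar,
   rho_t = q12 / sqrt(q11 q22), is driven by (t1, t2) >= 0, t1 + t2 <=
   0.999, chosen to maximize the correlation-stage quasi-likelihood.

Both stages use a deterministic Nelder–Mead in the transformed space with
fixed starting values ((omega, alpha, beta) = (0.1 var(x), 0.05, 0.90);
(t1, t2) = (0.05, 0.90)), function tolerance 1e-6 *relative to the
objective magnitude*, and at most 500 iterations. The relative tolerance
matters: log-likelihoods here have magnitude of a few hundred, and an
absolute span test would mislabel fits that crawl along the alpha = 0
boundary as non-converged. Non-convergence is flagged, never raised, so a
single bad edge cannot kill a whole-brain map; flagged edges are dropped
table-wide from feature tables (the Lasso stage has no missing-data
handling).

Per-edge summaries are the temporal mean of rho_t (which plays the role of
static connectivity) and the temporal variance with the population (1/T)
convention on the raw correlation scale. A Fisher-z variance option exists
but is off by default. Estimation is pairwise per edge rather than one
joint high-dimensional model — a joint fit over hundreds of regions is
computationally infeasible and the features are per-edge anyway; stage-1
fits are shared across edges that reuse a series.

Known caveat: band-pass-filtered BOLD violates the i.i.d.-innovation
assumption of the GARCH stage. The generator's optional AR(1) smoothing
exists to probe this; the estimator itself makes no correction.

## Synthetic cohort generator

No public raw data accompany the method, so the pipeline is validated on a
generator with full ground truth. Per subject i with latent trait
u_i ~ N(0,1):

* each seed emits unit-variance innovations (optionally GARCH(1,1)-scaled
  with (omega, alpha, beta) = (0.1, 0.1, 0.8), optionally AR(1)-smoothed);
* target j follows rho_t = clip(rho_bar + gamma_ij sin(2 pi t / period +
  phi_ij), ±0.95), with target_t = rho_t seed_std_t + sqrt(1 - rho_t^2) e_t
  — so the instantaneous correlation equals rho_t by construction;
* on the five signal edges, gamma_ij = max(0, amp_base + amp_slope u_i +
  eta_ij) with eta_ij ~ N(0, amp_jitter_sd); everywhere else gamma = 0, so
  non-signal edges have true temporal variance exactly 0;
* the observed score is offset + multiplier·u_i + N(0, trait_noise_sd),
  plus two nuisance scores built identically from independent latents.

The per-edge amplitude perturbation eta_ij is deliberate: with amplitudes
*exactly* shared across signal edges, the five signal features are
collinear in truth and an L1 selector has no reason to keep more than a
couple of them; the perturbation gives each edge conditionally independent
information, which is both more realistic and necessary for support
recovery to be a meaningful target.

Default study conditions (frozen after a power calibration targeting
per-edge feature–trait correlation >= 0.8, the regime this package treats
as "high SNR"): 60 subjects x 400 timepoints, 1 seed x 100 targets, signal
support {0, 20, 40, 60, 80}, baseline correlation 0 (symmetric clipping
headroom), amp_base 0.6, amp_slope 0.4, amp_jitter_sd 0.2, modulation
period T/2 (two complete cycles, so the pre-clip sinusoid variance is
exactly gamma^2/2 for any phase; faster modulation is badly attenuated by
the DCC recursion's ~20-sample memory), trait scale (17, 4) with noise sd
0.5 — questionnaire-like scores spanning roughly 7–28.

What the generator does *not* emulate: hemodynamics, spatial structure,
motion or scanner artifacts, site effects, temporal autocorrelation (unless
the AR(1) flag is set), or regime-switching dynamics. Passing tests
therefore show that the estimation and selection machinery recovers known
structure of this kind — not that the pipeline's assumptions hold for real
BOLD data.

## Sparse trait models

Features are z-scored inside every training fit (L1 penalties are
scale-sensitive; fold-internal standardization prevents leakage). The L1
penalty is not tuned: the path is computed on a 100-point log grid from the
smallest penalty that zeroes all coefficients down to 1e-4 of it, and the
selected point is the smallest penalty whose active set does not exceed the
training sample size — "as many features as subjects". Depending on the
realization this constraint either binds (an interior, genuinely
regularized point) or does not (the path bottom, near interpolation); in
the latter case cross-validated performance is intrinsically noisy across
cohort draws. This is a property of the rule, preserved deliberately.

Leave-one-participant-out cross-validation refits the *entire* procedure —
standardization, path, penalty selection — without the held-out subject.
Applying a fitted model to new data ("pattern expression") always uses the
training-cohort standardization, never the new cohort's. Performance is
Pearson r between predicted and observed scores (scale-insensitive, which
matters when questionnaire scales differ across cohorts); constant
predictions are an error at evaluation and are recorded as non-significant
by the cascade.

## Inference

* **Permutation test:** one-sided, shuffling the pairing of existing
  predictions with outcomes (predictions are not recomputed per
  permutation); p = (1 + #{r_null >= r_obs}) / (n_perm + 1), so p is never
  0. Default 10,000 permutations; the benchmark protocol uses 1,000.
* **Multiplicity:** Benjamini–Hochberg step-up at q = 0.05 across the seed
  x outcome family.
* **Cascade:** stage 1 = LOOCV + permutation + BH-FDR on the training
  cohort; stage 2 = fixed-model application to the validation cohort at
  uncorrected p < 0.05; stage 3 = report on the test cohort with a
  percentile-bootstrap 95% CI (10,000 paired resamples by default;
  degenerate resamples redrawn). The CI method is a package choice — a
  percentile bootstrap over subjects — because no canonical method is
  implied by correlation reporting alone. Validation/test cohorts can be
  supplied lazily and are only materialized if an earlier stage has
  survivors.
* **Outliers:** a single-pass |v - mean| > 3 sd(v) rule (sample sd), only
  applied to prediction scatter when explicitly requested; reported
  alongside, never silently substituted.

## Virtual lesioning

A lesion zeroes one nonzero weight of the fixed model — no refit, which for
a linear model equals holding that feature at its training mean — and
delta_corr = r_full - r_reduced is measured per evaluation cohort. Features
with strictly positive delta on *every* cohort form the important set
(exact-zero or undefined deltas exclude); the refined model copies retained
weights, intercept and standardization unchanged. Correlation-based
evaluation is intercept-invariant, so keeping the intercept cannot change
any reported r. Delta values are not additive and are used only through
their signs and ranks.

## Benchmark problem sizes

The reference protocol (tests and the acceptance script) uses: GARCH
recovery at T = 8000; constant-correlation recovery at T = 4000; variance
rank agreement over 25 edges at T = 1000 with amplitudes {0, 0.1, 0.2, 0.3,
0.4}; end-to-end recovery over replicated train/validation/test cohorts of
60/40/40 subjects (the multi-cohort design at reduced sample sizes; 20
replicates in the test suite, 12 in the acceptance script), with 1,000
permutations per test; and permutation calibration over 500 null
replicates of 1,000 permutations each. These sizes are the
package's chosen benchmark scale; the generator itself has no such limits.

## Known limitations

* Pairwise DCC ignores cross-edge dependence; joint modeling is out of
  scope.
* The max-features rule can sit near interpolation (see above); its LOOCV r
  has heavy replicate-to-replicate scatter even at high SNR, and a model
  with mediocre cross-validated r can still generalize well as a fixed
  pattern.
* The Korean 19-item scale's three factors are taken from the published
  item assignments; the original 22-item three-factor table ships from the
  published factor structure of the English scale and is external to this
  package's own data.
* RRS scoring assumes no reverse-scored items; other questionnaires (BDI,
  CES-D, STAI) enter only as manifest columns.
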
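# Methods

## Model and estimand

Subjects enter disease-free with a baseline biomarker X (higher values
assumed to carry higher risk; negate X otherwise) and are followed for an
event at latent time Z, observed as T = min(Z, C) with event indicator
δ = 1{T = Z}; censoring C is assumed independent of Z (completely at
random). Disease status is defined by a fixed horizon τ: "diseased" means
Z ≤ τ. Sensitivity and specificity of the rule X > c are the
cumulative-case / dynamic-control probabilities SE(c) = P(X > c | Z ≤ τ),
SP(c) = P(X ≤ c | Z > τ).

The sample splits into three observable groups: disease-free (T > τ),
diseased (T ≤ τ, δ = 1) and censored-before-τ (T ≤ τ, δ = 0), whose status
is unknown. The estimator splits the sample at c, computes Kaplan-Meier
survival at τ in each marker group (S_lo in X ≤ c, S_hi in X > c) and
fills an expected 2×2 table with (1 − S)·n and S·n per group; SE and SP
are row proportions of that table. No diagnostic for the
censoring-independence assumption is provided. The package deliberately
implements only this expected-events form; direct inverse-probability
weighting and indirect nearest-neighbour estimators are algebraically
equivalent or near-equivalent alternatives and are out of scope, as are
covariate adjustment, competing risks and left truncation.

## Cut-point search

Candidates are the sorted distinct observed marker values with the maximum
removed: because classification is X ≤ c vs X > c, any c between
consecutive order statistics acts exactly like the lower one, so this grid
is exhaustive and keeps ĉ on the marker's own scale. Three objectives are
supported — Youden J = SE + SP − 1 and concordance CZ = SE·SP (maximized),
corner distance ER = √((1−SE)² + (1−SP)²) (minimized). Ties, including
numerical ties within a relative 1e-9 (plateaus of the empirical objective
can differ only by rounding noise in the survival products), are broken by
the smallest candidate, which makes results deterministic and invariant to
record order. Candidates where the expected diseased or disease-free total
is zero are skipped and counted; if every candidate is inadmissible a
typed error is raised rather than returning NaN, because the expected
2×2 table is undefined there. No minimum stratum size is imposed beyond
non-emptiness: small strata legitimately propagate wide uncertainty, which
the bootstrap then exposes.

Implementation note: all candidates are evaluated in one pass. Subjects
are sorted by marker; cumulative at-risk and death counts over the
distinct event times ≤ τ give, for every prefix (= every candidate's low
group) and its complement, the full product-limit estimate at τ as a row
product. This is O(N·J) for J distinct event times and is what makes the
1000-replicate simulation study and the bootstrap loops practical on one
CPU. A scalar implementation (`km_survival_at`, `se_sp_at_cutpoint`)
follows the textbook formulas; tests assert the two routes agree to 1e-12
and that the Kaplan-Meier step matches lifelines. Kaplan-Meier conventions:
right-continuous step function; censorings tied with events at the same
time remain in the risk set at that time; beyond the largest observed time
in a stratum the last value is carried forward (relevant when a small
stratum's follow-up ends before τ). Comparisons T ≤ τ are exact on stored
values — no tolerance.

## Theoretical optima

Under the homoscedastic normal scenario (diseased N(μ, 1) vs disease-free
N(0, 1)) SE(c) = 1 − Φ(c − μ), SP(c) = Φ(c); all three objectives peak at
the density-crossing point c = μ/2, returned in closed form. Under the
gamma scenario (diseased G(shape 2.5, scale β) vs disease-free G(1.5, 1))
the optima differ by objective and are found numerically: a 4001-point
grid over (0, q_0.9999 of the wider law) brackets the optimum and a
bounded scalar minimization refines it (default tolerance 1e-8). The grid
stage matters because for β < 1 the Youden objective has a secondary
shoulder near the origin; the crossing-point condition
f_diseased(c) = f_disease-free(c) is asserted in tests. The gamma laws are
parameterized as (shape, scale); with β = 3.82 this reproduces the
reference true cut-points (Youden 3.42, concordance 3.38, corner ≈ 3.235).

## Bootstrap

`bootstrap_cutpoint` draws n_boot case resamples with replacement,
re-estimates ĉ on each, and reports the replicate SD and the percentile
interval using nearest-order-statistic (type-1) quantiles — the basic
percentile method without interpolation assumptions. Failed replicates
(degenerate resamples) are dropped and counted rather than redrawn, since
redrawing would condition the resampling distribution on success; if more
than half fail the whole result is refused as unstable. The default
n_boot = 200 matches the simulation-study setting; for real data the CLI
defaults to 999 replicates, as small replicate counts can leave coverage
below nominal. Bootstrapping the objective value itself (known to be
optimistically biased at the selected cut-point) is noted as future work.

The operating-point ellipse fixes ĉ and bootstraps (logit FPF, logit TPF)
jointly — the two estimators are correlated under censoring because
censored subjects contribute to both — using multinomial weight resampling
so the two stratum Kaplan-Meier estimates for all replicates are computed
as matrix products. The region is the χ²(2 df) contour of the estimated
logit-scale covariance, mapped back through the inverse logit, so the
boundary always stays inside (0, 1)². Replicates hitting the FPF/TPF
boundary (logit undefined) are dropped; a point estimate on the boundary
raises an error instead of producing a degenerate region. The covariance
is estimated by bootstrap rather than closed-form delta-method algebra;
the elliptic logit-space geometry is retained.

## Simulation engine

Event times are exponential with rate 2 (so P(Z ≤ τ) = 1 − e^{−2τ}); the
marker is drawn conditionally on Z ≤ τ; censoring is uniform on [0, b].
The horizon τ ∈ {0.35, 0.20, 0.14, 0.11, 0.08} sets disease fractions of
50/33/25/20/15% (the percentages are rounded values of 1 − e^{−2τ}), and b
controls the fraction censored before τ: at 50% disease, b = 2, 1, 0.66
give 12/25/38%; at the other disease fractions b = 0.67, 0.50, 0.40, 0.29
give 25%. The reference grid crosses 4 accuracy levels
(μ ∈ {0.51, 1.05, 1.68, 2.56} or β ∈ {0.79, 1.22, 1.97, 3.82}, i.e.
J = 0.2…0.8) with sample sizes 50–400 (50% disease, three censoring
levels), the four (N, disease-fraction) pairs (100, 15%), (150, 33%),
(200, 25%), (250, 20%) at 25% censoring, and the gamma block at 50%
disease / 25% censoring — 80 scenarios.

Per scenario × replicate, a counter-based seed stream keyed by
(master seed, scenario index, replicate index) makes every cell
independently reproducible. `bias` is the mean of ĉ − c against the
method-specific true cut-point — the plain mean error, reported under
that name — and `mse` the mean squared error, with a Monte-Carlo standard
error attached; replicates where estimation fails are dropped and counted.

What the generator does *not* emulate: markers measured with error,
non-monotone marker-risk relationships, informative censoring, covariates,
and discrete/heavily tied markers. Passing simulation tests therefore
demonstrate correctness of the estimators under the stated sampling model,
not robustness to those real-data features.

## Problem sizes used in the test suite

Deterministic and analytic checks run at full precision. Monte-Carlo
checks use: 1000 replicates for the MSE-vs-N monotonicity slice; 250
replicates (within 5 Monte-Carlo SEs) for the N = 400 table-parity cells;
200 replicates × 300 datasets for bootstrap-CI coverage (N = 100, J = 0.6,
25% censoring, interval expected to cover the true cut-point 90–99% of
the time); 200 bootstrap replicates × 500 datasets for ellipse coverage
(N = 200, expected 95% ± 3); and N = 4000 × 200 replicates for the
consistency (bias → 0) check. These sizes were chosen so each stochastic
assertion has at least ~2–5 Monte-Carlo SEs of slack around its expected
value while the whole suite stays in the minutes range.

## Known limitations

* The estimated SE/SP at the *selected* cut-point are optimistically
  biased in small samples (selection bias of the maximum); the package
  reports them as-is and provides the bootstrap/ellipse machinery to
  quantify uncertainty rather than attempting a bias correction.
* Objectives are unweighted; prevalence- or utility-weighted variants and
  predictive-value-based cut-points are not implemented.
* One horizon per call; time-dependent ROC surfaces over multiple τ are
  out of scope, as are smoothed ROC curves and AUC estimation.
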
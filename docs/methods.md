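# Methods

## Statistical model and procedures

### Nonparametric AUC and its variance

For a fixed scoring rule tested on `N0` actually-negative scores `X_i` and
`N1` actually-positive scores `Y_j`, the AUC estimate is the two-sample
Mann-Whitney statistic `Â = (N0 N1)⁻¹ Σ_ij ψ(X_i, Y_j)` with
`ψ = 1 / 0.5 / 0` according as `x < y / x = y / x > y`.  Ties count half
everywhere, including in file-loaded scores; the simulated continuous
scores tie with probability zero.  The implementation uses midranks
(O(n log n)), which is algebraically — and in floating point exactly —
equal to literal pair counting; the test suite asserts this equality on
random tied instances.

`Â` is a generalized two-sample U-statistic; its variance decomposes into
three Hoeffding components,

    Var(Â) = (N0−1)/(N0 N1) ξ01 + (N1−1)/(N0 N1) ξ10 + 1/(N0 N1) ξ11,

where `ξ01` is the covariance of two kernels sharing a positive subject
(distinct negatives), `ξ10` the mirror image, and `ξ11` the kernel
variance.  Two estimators are provided:

* **delong** — structural components: per-subject kernel averages `v01[i]`,
  `v10[j]`, with ddof-1 sample (co)variances divided by the respective
  class size.  This estimates the two first-order components and drops the
  second-order `ξ11` term; it is the classical estimator and is not
  exactly unbiased.
* **ustat** — each kernel-product expectation is replaced by its average
  over index tuples with all required indices distinct, and `A²` by the
  four-index U-statistic average over `i ≠ i′, j ≠ j′`.  Each piece is
  exactly unbiased, so the plugged-in variance is unbiased as well.  The
  O(N0 N1) reduced form (row/column-sum identities with inclusion-
  exclusion for the all-distinct term) is verified against a literal
  O(N0² N1²) index-tuple enumeration in the tests, and its unbiasedness is
  verified against the brute-force Monte Carlo variance of `Â` over
  replicate test draws.

The cross-model covariance on a common test set uses the same structure
with the kernel products taken across models; the two-model z test is
`z = (Â1−Â2)/SE`, `SE² = V̂1 + V̂2 − 2Ĉ`, two-sided normal reference.
`SE²` at or below a relative floor of `1e−12 · (V̂1+V̂2)` (identical score
columns, or cancellation in the unbiased estimator) yields the degenerate
result `p = 1` with `z` undefined and a flag: with no usable estimate of
the variability of the difference, the data offer no evidence of one.
Although the unbiased estimator of a single AUC variance may in principle
go negative, exhaustive enumeration over tiny discrete score samples found
no negative value; the clamp matters in practice only for `SE²`.

### Exact F test of the ideal AUC

For two-class multivariate normal biomarkers with common covariance, the
ideal AUC of the best linear model is `Φ(√D²/√2)` in the squared
Mahalanobis distance `D²`, a strictly increasing mapping, so equality of
nested ideal AUCs is equality of Mahalanobis distances.  Rao's statistic
(see README for the formula) refers the relative growth of the sample
distance to `F(q, N0+N1−p−q−1)` and is exact at any sample size.  Choices:

* Pooled within-class covariance uses denominator `N0+N1−2`, matching the
  `(N0+N1−2)` factor inside the statistic's constant `c`; the type I error
  calibration of the Monte Carlo study confirms the pairing.
* The mapping is `Φ(√D²/√2)` in the *squared* distance: it is the unique
  form consistent with both panel ideal AUCs (0.8413 at `D² = 2.00`,
  0.8613 at `D² = 2.36`).
* Singularity guard: a reciprocal condition number of the pooled
  covariance below `1e−12` raises an error rather than falling back to a
  pseudo-inverse, since the test presumes a proper Mahalanobis distance.
* `p = 0` (no existing biomarkers) is supported with `D̂²(0) = 0`, reducing
  to a one-sample separation F test.
* The p-value is one-sided (upper tail): added variables cannot decrease
  the sample distance, so the test is one-sided by construction.

### Nested logistic LR and Wald tests

Plain Newton-Raphson maximum likelihood with an intercept always included
(the simulated designs have unequal class sizes; an interceptless fit
would confound prevalence with discrimination).  Convergence when the
maximum absolute score falls below `1e−8` or the relative log-likelihood
change below `1e−10`, capped at 100 iterations, with step-halving to keep
the likelihood monotone.  Fits with any `|coefficient| > 15` are flagged
as separated; nonconverged or separated fits keep their achieved statistics
and are *counted, not discarded* in Monte Carlo runs — discarding would
bias rejection fractions.  LR statistics that come out a hair negative
from convergence tolerance are clamped at 0.  For `q = 1` the Wald test is
reported as `z = ŵ/SE` with a two-sided normal p-value (identical to the
`χ²(1)` form, asserted to 1e−12 in the tests); for `q > 1` the block
quadratic form against `χ²(q)`.

## Synthetic data generators (the study conditions)

* **16-biomarker Gaussian panel**: negative-class mean 0, identity
  covariance; positive-class mean
  `[0.7, 0.6, 0.6, 0.5, 0.5, 0.3, 0.3, 0.2, 0.2, 0.1, 0.1, 0.1, 0, 0, 0, ·]`
  with the 16th entry 0 (null) or 0.6 (alternative).  The profile mixes
  strong, weak and useless markers around a medium-performance model
  (15-marker ideal AUC 0.8413) and includes deliberately useless existing
  markers.  It emulates idealized biomarker data: real panels have
  correlated, non-Gaussian, unequal-variance markers, so passing tests
  certify the statistical machinery under its stated assumptions, not
  robustness to their violation (the F test in particular *requires*
  the common-covariance Gaussian model).
* **Bivariate binormal scores** for two fixed models: per-class covariance
  `[[1, ρ], [ρ, 1]]`, class means `[0,0]` and `[μ,μ]`, so both models share
  the true AUC `Φ(μ/√2)` and every rejection is a type I error.  Boundary
  correlations `|ρ| = 1` are generated by direct transform rather than a
  Cholesky factor.
* **Monte Carlo protocol**: 20,000 trials by default (MC SE ≈ 0.0015 for a
  fraction near 0.05), all three added-value tests sharing the drawn data
  within a trial; one seeded `numpy` generator per experiment with draws in
  a fixed order, so reruns are bit-identical from `(config, seed)`.
  Reported summaries carry `mc_se = sqrt(f(1−f)/n_trials)` and
  flagged-trial counts.
* **Antler learning curves**: logistic models on the 15 informative panel
  markers at total training sizes 60–480 split equally between classes
  (the natural reading of a per-trial "training sample size"; it is
  configurable), 1,000 repetitions, AUC estimated by resubstitution and on
  fresh test sets of 60 and 10,000 subjects per class.  The ideal
  reference is the linear-discriminant optimum 0.8413, which the logistic
  model attains asymptotically under the equal-covariance Gaussian panel.
  At size 60 (30 per class, 15 predictors) a fraction of fits separate;
  they are flagged and retained.

## Numerical and scale choices

* The unbiasedness study of the U-statistic variance uses unit-variance
  binormal scores with shift `μ = 1.0` (AUC ≈ 0.76) at designs (10,10) and
  (30,15): a mid-range AUC keeps all three variance components active.
* Stochastic test-suite checks run at 5,000 trials and accept within three
  binomial standard errors of the 20,000-trial reference values; the
  acceptance script runs the full 20,000-trial protocols.  Exactness of
  the F test is checked distributionally: 5,000 null `U` values against
  `F(1, N0+N1−3)` by a Kolmogorov-Smirnov test at the 1% level.
* Rejection counting uses `p ≤ α`, equivalent almost surely to the strict
  inequality for continuous statistics while keeping `α = 1` a level-1
  test despite the `p = 1` atom created by the LR zero-clamp.  Degenerate
  AUC comparisons never reject and are flagged.

## Known limitations

* The F test's equivalence between ideal-AUC and Mahalanobis hypotheses
  holds only under the common-covariance multivariate normal model; no
  unequal-covariance or non-nested variant is provided.
* No bootstrap or cross-validation variance estimation, no partial AUC or
  ROC confidence bands, and no penalized/exact logistic regression.
* The correlated-AUC tests address fixed models on an independent test
  set; they are silent about (and invalid for) resubstitution estimates or
  models retrained per draw.
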
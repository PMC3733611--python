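"""Seeded Monte Carlo experiments for the added-value testing methods.

Three study designs are implemented:

* **added-value** -- type I error / power of the LR, Wald and exact F tests
  when one new biomarker is tested on top of 15 existing ones, with
  training data drawn from a 16-biomarker two-class Gaussian panel
  (identity covariance; the positive-class mean profile mixes strong,
  weak and useless biomarkers).  Under the null profile the new (16th)
  biomarker has zero mean difference; under the alternative it has 0.6.
* **auc-comparison** -- null behaviour of the correlated-AUC z test
  (DeLong and unbiased U-statistic variances) for two *fixed* models whose
  paired test scores follow a bivariate binormal model with per-class
  correlation ``rho`` and common mean shift ``mu``.
* **antler** -- learning curves of a logistic model on the 15 informative
  panel biomarkers, contrasting the resubstitution AUC estimate with
  small- and large-test-set estimates against the ideal AUC, whose
  characteristic mean +/- SD envelope resembles a pair of antlers.

Every experiment is a pure function of its configuration and seed; rerunning
with the same seed reproduces results bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .auc_nonparametric import PairedScoreSample, ScoreSample, compare_auc, estimate_auc
from .ideal_auc_ftest import (
    GaussianClassSpec,
    NestedModelSpec,
    TwoClassData,
    ideal_auc_f_test,
    mahalanobis_to_auc,
)
from .logistic_nested_tests import fit_logistic, lr_test, wald_test

__all__ = [
    "PANEL_MEAN_POS_NULL",
    "PANEL_MEAN_POS_ALT",
    "biomarker_panel_spec",
    "BinormalPairSpec",
    "binormal_auc",
    "ExperimentConfig",
    "MCSummary",
    "LearningCurveResult",
    "generate_two_class_gaussian",
    "generate_paired_binormal_scores",
    "run_added_value_experiment",
    "run_auc_comparison_experiment",
    "run_learning_curve",
]

# Positive-class mean profile of the 16-biomarker simulation panel
# (negative-class mean 0, identity covariance).  The first 12 biomarkers
# carry signal of varying strength, 13-15 are useless, and the 16th is the
# candidate "new" biomarker: useless under the null profile, mean 0.6 under
# the alternative.
PANEL_MEAN_POS_NULL = np.array(
    [0.7, 0.6, 0.6, 0.5, 0.5, 0.3, 0.3, 0.2, 0.2, 0.1, 0.1, 0.1, 0.0, 0.0, 0.0, 0.0]
)
PANEL_MEAN_POS_ALT = np.array(
    [0.7, 0.6, 0.6, 0.5, 0.5, 0.3, 0.3, 0.2, 0.2, 0.1, 0.1, 0.1, 0.0, 0.0, 0.0, 0.6]
)


def biomarker_panel_spec(scenario: str = "null") -> GaussianClassSpec:
    """Two-class Gaussian population of the 16-biomarker simulation panel.

    ``scenario`` is ``"null"`` (the 16th biomarker is useless; ideal AUC of
    the full linear discriminant 0.8413, same as the 15-marker one) or
    ``"alternative"`` (16th mean difference 0.6; full-model ideal AUC
    0.8613).
    """
    if scenario == "null":
        mean_pos = PANEL_MEAN_POS_NULL
    elif scenario == "alternative":
        mean_pos = PANEL_MEAN_POS_ALT
    else:
        raise ValueError(f"scenario must be 'null' or 'alternative', got {scenario!r}")
    return GaussianClassSpec(mean_neg=np.zeros(16), mean_pos=mean_pos, cov=np.eye(16))


@dataclass(frozen=True)
class BinormalPairSpec:
    """Bivariate binormal test-score model for two fixed classifiers.

    Within each class the paired scores have unit variances and correlation
    ``rho``; class means are ``[0, 0]`` (negative) and ``[mu, mu]``
    (positive), so both models share the binormal AUC ``Phi(mu / sqrt 2)``.
    """

    rho: float = 0.0
    mu: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.rho) or abs(self.rho) > 1.0:
            raise ValueError("rho must lie in [-1, 1]")
        if not np.isfinite(self.mu):
            raise ValueError("mu must be finite")


def binormal_auc(mu: float) -> float:
    """Population AUC of a unit-variance binormal score model with shift mu."""
    from scipy.stats import norm

    return float(norm.cdf(mu / np.sqrt(2.0)))


@dataclass(frozen=True)
class ExperimentConfig:
    """Monte Carlo experiment configuration.

    ``tests`` selects which statistics are evaluated per trial: any of
    ``"LR"``, ``"Wald"``, ``"F"`` for the added-value experiment, or
    ``"delong"``, ``"ustat"`` for the fixed-model AUC comparison.
    """

    n0: int
    n1: int
    n_trials: int = 20_000
    alpha: float = 0.05
    seed: int = 0
    scenario: str = "null"
    tests: tuple[str, ...] = ("LR", "Wald", "F")

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be at least 1")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")


def _mc_se(fraction: float, n_trials: int) -> float:
    return float(np.sqrt(fraction * (1.0 - fraction) / n_trials))


@dataclass(frozen=True)
class MCSummary:
    """Rejection fractions of one Monte Carlo experiment.

    ``rejection_fraction[test]`` is the observed type I error (null
    scenario) or power (alternative scenario) at level ``alpha``;
    ``mc_se[test] = sqrt(f (1 - f) / n_trials)``; ``flagged_trials[test]``
    counts trials whose result carried a warning (nonconvergence,
    separation, degenerate comparison).
    """

    rejection_fraction: Mapping[str, float]
    mc_se: Mapping[str, float]
    n_trials: int
    alpha: float
    seed: int
    flagged_trials: Mapping[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class LearningCurveResult:
    """Mean +/- SD learning curves of three AUC estimators.

    Estimators: ``resubstitution`` (AUC on the training data),
    ``small_test`` and ``large_test`` (AUC on independently drawn test sets
    of the stated per-class sizes).  ``ideal_auc`` is the infinite-data AUC
    of the model family.
    """

    train_sizes: tuple[int, ...]
    means: Mapping[str, np.ndarray]
    sds: Mapping[str, np.ndarray]
    ideal_auc: float
    n_reps: int
    seed: int
    flagged_fits: tuple[int, ...] = ()


def generate_two_class_gaussian(
    spec: GaussianClassSpec, n0: int, n1: int, rng: np.random.Generator
) -> TwoClassData:
    """Draw ``n0`` negative and ``n1`` positive subjects from the population."""
    try:
        chol = np.linalg.cholesky(spec.cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance matrix must be positive definite") from exc
    neg = rng.standard_normal((n0, spec.d)) @ chol.T + spec.mean_neg
    pos = rng.standard_normal((n1, spec.d)) @ chol.T + spec.mean_pos
    return TwoClassData(neg_matrix=neg, pos_matrix=pos)


def generate_paired_binormal_scores(
    spec: BinormalPairSpec, n0: int, n1: int, rng: np.random.Generator
) -> PairedScoreSample:
    """Draw paired test scores of two fixed models for a common test sample."""
    rho = spec.rho
    z_neg = rng.standard_normal((n0, 2))
    z_pos = rng.standard_normal((n1, 2))
    # direct transform handles |rho| = 1 where a Cholesky factor degenerates
    mix = np.sqrt(1.0 - rho * rho)
    neg1 = z_neg[:, 0]
    neg2 = rho * z_neg[:, 0] + mix * z_neg[:, 1]
    pos1 = z_pos[:, 0] + spec.mu
    pos2 = rho * z_pos[:, 0] + mix * z_pos[:, 1] + spec.mu
    return PairedScoreSample(
        neg_scores_1=neg1, neg_scores_2=neg2, pos_scores_1=pos1, pos_scores_2=pos2
    )


_ADDED_VALUE_TESTS = ("LR", "Wald", "F")


def run_added_value_experiment(
    config: ExperimentConfig,
    spec: NestedModelSpec | None = None,
    population: GaussianClassSpec | None = None,
) -> MCSummary:
    """Type I error / power of the LR, Wald and F tests of one new biomarker.

    Per trial one training sample is drawn from the 16-biomarker panel
    (scenario taken from ``config``) and shared by all requested tests, so
    their errors are correlated within a trial but each marginal rejection
    fraction is unaffected.  Trials whose fits fail to converge or separate
    are kept with their achieved p-values and counted in
    ``flagged_trials``.
    """
    tests = tuple(t for t in config.tests if t in _ADDED_VALUE_TESTS)
    if not tests:
        raise ValueError(f"no added-value tests among {config.tests!r}")
    if spec is None:
        spec = NestedModelSpec(existing_idx=tuple(range(15)), new_idx=(15,))
    if population is None:
        population = biomarker_panel_spec(config.scenario)
    rng = np.random.default_rng(config.seed)
    rejections = {t: 0 for t in tests}
    flagged = {t: 0 for t in tests}
    for _ in range(config.n_trials):
        data = generate_two_class_gaussian(population, config.n0, config.n1, rng)
        for test in tests:
            if test == "F":
                result = ideal_auc_f_test(data, spec)
                p_value, warn = result.p_value, ()
            elif test == "LR":
                res = lr_test(data, spec)
                p_value, warn = res.p_value, res.warnings
            else:
                res = wald_test(data, spec)
                p_value, warn = res.p_value, res.warnings
            # "reject at level alpha" is p <= alpha: equivalent to a strict
            # inequality for continuous statistics, and keeps the degenerate
            # level alpha = 1 a level-1 test despite the p = 1 atom that the
            # LR zero-clamp introduces
            if p_value <= config.alpha:
                rejections[test] += 1
            if warn:
                flagged[test] += 1
    fractions = {t: rejections[t] / config.n_trials for t in tests}
    return MCSummary(
        rejection_fraction=fractions,
        mc_se={t: _mc_se(f, config.n_trials) for t, f in fractions.items()},
        n_trials=config.n_trials,
        alpha=config.alpha,
        seed=config.seed,
        flagged_trials=flagged,
    )


def run_auc_comparison_experiment(
    config: ExperimentConfig, spec: BinormalPairSpec
) -> MCSummary:
    """Null rejection rate of the correlated-AUC z test for two fixed models.

    Only test scores are drawn per trial (the models are fixed); both
    models share the same population AUC, so every rejection is a type I
    error.  Degenerate comparisons (nonpositive variance of the AUC
    difference) are counted as non-rejections and flagged.
    """
    methods = tuple(t for t in config.tests if t in ("delong", "ustat"))
    if not methods:
        methods = ("delong", "ustat")
    rng = np.random.default_rng(config.seed)
    rejections = {m: 0 for m in methods}
    flagged = {m: 0 for m in methods}
    for _ in range(config.n_trials):
        paired = generate_paired_binormal_scores(spec, config.n0, config.n1, rng)
        for method in methods:
            result = compare_auc(paired, method=method)
            # degenerate comparisons never reject (p is set to 1 by rule)
            if not result.degenerate and result.p_value <= config.alpha:
                rejections[method] += 1
            if result.degenerate:
                flagged[method] += 1
    fractions = {m: rejections[m] / config.n_trials for m in methods}
    return MCSummary(
        rejection_fraction=fractions,
        mc_se={m: _mc_se(f, config.n_trials) for m, f in fractions.items()},
        n_trials=config.n_trials,
        alpha=config.alpha,
        seed=config.seed,
        flagged_trials=flagged,
    )


def _model_auc(fit_coefficients: np.ndarray, data: TwoClassData) -> float:
    scores_neg = data.neg_matrix @ fit_coefficients[1:] + fit_coefficients[0]
    scores_pos = data.pos_matrix @ fit_coefficients[1:] + fit_coefficients[0]
    return estimate_auc(ScoreSample(neg_scores=scores_neg, pos_scores=scores_pos))


def run_learning_curve(
    config: ExperimentConfig,
    train_sizes: Sequence[int] = (60, 120, 240, 360, 480),
    small_test_per_class: int = 60,
    large_test_per_class: int = 10_000,
    n_reps: int = 1_000,
    n_biomarkers: int = 15,
) -> LearningCurveResult:
    """Learning curves of a logistic model on the informative panel biomarkers.

    ``train_sizes`` are total training sizes split equally between classes.
    Per repetition and size, a fresh logistic model is trained and its AUC
    estimated by resubstitution and on independently drawn small and large
    test sets; means and SDs are taken over repetitions.  The ideal AUC
    reference is the linear-discriminant optimum on the selected
    biomarkers, which the logistic model attains in the infinite-data limit
    under the equal-covariance Gaussian panel.
    """
    population = biomarker_panel_spec(config.scenario)
    idx = np.arange(n_biomarkers)
    sub_population = GaussianClassSpec(
        mean_neg=population.mean_neg[idx],
        mean_pos=population.mean_pos[idx],
        cov=population.cov[np.ix_(idx, idx)],
    )
    ideal = mahalanobis_to_auc(sub_population.mahalanobis_sq())
    rng = np.random.default_rng(config.seed)
    sizes = tuple(int(s) for s in train_sizes)
    estimators = ("resubstitution", "small_test", "large_test")
    values = {e: np.empty((len(sizes), n_reps)) for e in estimators}
    flagged = [0] * len(sizes)
    for k, size in enumerate(sizes):
        n_per_class = size // 2
        for rep in range(n_reps):
            train = generate_two_class_gaussian(sub_population, n_per_class, n_per_class, rng)
            features = np.vstack([train.neg_matrix, train.pos_matrix])
            labels = np.concatenate([np.zeros(train.n0), np.ones(train.n1)])
            fit = fit_logistic(features, labels)
            if not fit.converged or fit.separation:
                flagged[k] += 1
            small = generate_two_class_gaussian(
                sub_population, small_test_per_class, small_test_per_class, rng
            )
            large = generate_two_class_gaussian(
                sub_population, large_test_per_class, large_test_per_class, rng
            )
            values["resubstitution"][k, rep] = _model_auc(fit.coefficients, train)
            values["small_test"][k, rep] = _model_auc(fit.coefficients, small)
            values["large_test"][k, rep] = _model_auc(fit.coefficients, large)
    return LearningCurveResult(
        train_sizes=sizes,
        means={e: values[e].mean(axis=1) for e in estimators},
        sds={e: values[e].std(axis=1, ddof=1) for e in estimators},
        ideal_auc=ideal,
        n_reps=n_reps,
        seed=config.seed,
        flagged_fits=tuple(flagged),
    )
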
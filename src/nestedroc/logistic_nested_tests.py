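"""Nested logistic regression and the asymptotic LR and Wald tests.

The added value of ``q`` new biomarkers over ``p`` existing ones can be
judged by testing whether their weight coefficients in the full logistic
model are all zero.  Two classical asymptotic tests are provided:

* likelihood ratio: ``2 (l_full - l_partial)`` referred to chi-square(q);
* Wald: for ``q = 1`` the coefficient-to-standard-error ratio referred to
  the standard normal (two-sided), and for ``q > 1`` the quadratic form of
  the new-coefficient block against its estimated covariance, referred to
  chi-square(q).

Both are exact only asymptotically; their finite-sample type I error is
inflated at small training sizes, which the Monte Carlo harness in
:mod:`nestedroc.simulation_experiments` quantifies.

The maximum-likelihood fit is a plain Newton-Raphson iteration on the
log-likelihood with an intercept always included, a step-halving safeguard,
and flags for nonconvergence and (quasi-)separation.  It is deliberately
lightweight so that tens of thousands of Monte Carlo fits stay cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats
from scipy.special import expit

from .ideal_auc_ftest import NestedModelSpec, TwoClassData

__all__ = ["LogisticFit", "TestResult", "fit_logistic", "lr_test", "wald_test"]

# |coefficient| beyond this is treated as evidence of (quasi-)separation
_SEPARATION_COEF = 15.0
_MAX_ITER = 100
_GRAD_TOL = 1e-8
_LL_REL_TOL = 1e-10


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic fit (intercept first in ``coefficients``)."""

    coefficients: np.ndarray
    log_likelihood: float
    coef_cov: np.ndarray
    converged: bool
    n_iter: int
    separation: bool = False


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    test_name: Literal["LR", "Wald", "F"]
    warnings: tuple[str, ...] = ()


def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    # y*eta - log(1 + exp(eta)), computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(features: np.ndarray, labels: np.ndarray) -> LogisticFit:
    """Newton-Raphson maximum-likelihood logistic regression with intercept.

    Convergence when the maximum absolute score (gradient) drops below 1e-8
    or the relative log-likelihood change below 1e-10, capped at 100
    iterations.  Fits that run away (any |coefficient| > 15) are flagged as
    separated; nonconverged fits keep their achieved coefficients and
    likelihood so Monte Carlo loops stay total.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels, dtype=float).ravel()
    if x.shape[0] != y.size:
        raise ValueError("features and labels disagree on the number of subjects")
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0.0, 1.0))):
        raise ValueError("labels must be coded 0/1")
    if classes.size < 2:
        raise ValueError("labels contain a single class; both classes are required")

    design = np.column_stack([np.ones(x.shape[0]), x])
    n, k = design.shape
    beta = np.zeros(k)
    eta = design @ beta
    ll = _log_likelihood(eta, y)

    converged = False
    n_iter = 0
    hessian = np.eye(k)
    for n_iter in range(1, _MAX_ITER + 1):
        mu = expit(eta)
        grad = design.T @ (y - mu)
        w = mu * (1.0 - mu)
        hessian = design.T @ (design * w[:, np.newaxis])
        if np.max(np.abs(grad)) < _GRAD_TOL:
            converged = True
            break
        try:
            step = np.linalg.solve(hessian, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(hessian + 1e-8 * np.eye(k), grad)
        # step-halving keeps the likelihood monotone
        new_ll = -np.inf
        for _ in range(30):
            candidate = beta + step
            eta_new = design @ candidate
            new_ll = _log_likelihood(eta_new, y)
            if new_ll >= ll - 1e-12:
                break
            step *= 0.5
        beta, eta = beta + step, design @ (beta + step)
        if new_ll - ll <= _LL_REL_TOL * max(1.0, abs(ll)) and new_ll >= ll:
            ll = new_ll
            mu = expit(eta)
            grad = design.T @ (y - mu)
            w = mu * (1.0 - mu)
            hessian = design.T @ (design * w[:, np.newaxis])
            converged = True
            break
        ll = new_ll

    try:
        cov = np.linalg.inv(hessian)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hessian)
    separation = bool(np.max(np.abs(beta)) > _SEPARATION_COEF)
    return LogisticFit(
        coefficients=beta,
        log_likelihood=float(_log_likelihood(design @ beta, y)),
        coef_cov=cov,
        converged=converged,
        n_iter=n_iter,
        separation=separation,
    )


def _stack(data: TwoClassData, idx: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
    sel = np.asarray(idx, dtype=int)
    features = np.vstack([data.neg_matrix[:, sel], data.pos_matrix[:, sel]])
    labels = np.concatenate([np.zeros(data.n0), np.ones(data.n1)])
    return features, labels


def _fit_flags(*fits: LogisticFit) -> tuple[str, ...]:
    flags = []
    if any(not f.converged for f in fits):
        flags.append("nonconvergence")
    if any(f.separation for f in fits):
        flags.append("separation")
    return tuple(flags)


def lr_test(data: TwoClassData, spec: NestedModelSpec) -> TestResult:
    """Likelihood ratio test for the q new biomarkers in the full model.

    Twice the log-likelihood difference of the nested fits, referred to
    chi-square(q); tiny negative statistics from convergence tolerance are
    clamped at zero.
    """
    x_partial, labels = _stack(data, spec.existing_idx)
    x_full, _ = _stack(data, spec.existing_idx + spec.new_idx)
    fit_partial = fit_logistic(x_partial, labels) if spec.p > 0 else _intercept_fit(labels)
    fit_full = fit_logistic(x_full, labels)
    statistic = max(2.0 * (fit_full.log_likelihood - fit_partial.log_likelihood), 0.0)
    p_value = float(stats.chi2.sf(statistic, spec.q))
    return TestResult(
        statistic=statistic, df=spec.q, p_value=p_value, test_name="LR",
        warnings=_fit_flags(fit_partial, fit_full),
    )


def _intercept_fit(labels: np.ndarray) -> LogisticFit:
    """Closed-form intercept-only fit: intercept = logit(prevalence)."""
    y = np.asarray(labels, dtype=float).ravel()
    prev = y.mean()
    if prev in (0.0, 1.0):
        raise ValueError("labels contain a single class; both classes are required")
    n = y.size
    intercept = math.log(prev / (1.0 - prev))
    ll = n * (prev * math.log(prev) + (1 - prev) * math.log(1 - prev))
    return LogisticFit(
        coefficients=np.array([intercept]),
        log_likelihood=float(ll),
        coef_cov=np.array([[1.0 / (n * prev * (1 - prev))]]),
        converged=True,
        n_iter=0,
    )


def wald_test(data: TwoClassData, spec: NestedModelSpec) -> TestResult:
    """Wald test of the new-biomarker coefficients in the full logistic model.

    For ``q = 1`` the statistic reported is ``z = w_hat / SE`` with a
    two-sided normal p-value; for ``q > 1`` the block quadratic form is
    referred to chi-square(q).  A singular covariance block yields a
    degenerate result (statistic 0, p 1) with a warning.
    """
    x_full, labels = _stack(data, spec.existing_idx + spec.new_idx)
    fit = fit_logistic(x_full, labels)
    # +1 offsets the intercept column of the design matrix
    new_slice = np.arange(spec.p + 1, spec.p + spec.q + 1)
    coef_new = fit.coefficients[new_slice]
    cov_new = fit.coef_cov[np.ix_(new_slice, new_slice)]
    flags = _fit_flags(fit)
    if spec.q == 1:
        se = math.sqrt(max(cov_new[0, 0], 0.0))
        if se == 0.0:
            return TestResult(0.0, 1, 1.0, "Wald", flags + ("degenerate",))
        z = float(coef_new[0] / se)
        p_value = float(2.0 * stats.norm.sf(abs(z)))
        return TestResult(statistic=z, df=1, p_value=p_value, test_name="Wald", warnings=flags)
    try:
        statistic = float(coef_new @ np.linalg.solve(cov_new, coef_new))
    except np.linalg.LinAlgError:
        return TestResult(0.0, spec.q, 1.0, "Wald", flags + ("degenerate",))
    p_value = float(stats.chi2.sf(statistic, spec.q))
    return TestResult(statistic=statistic, df=spec.q, p_value=p_value, test_name="Wald", warnings=flags)
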
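"""Nonparametric AUC estimation and comparison of correlated AUCs.

The area under the ROC curve of a fixed scoring rule, estimated on an
independent test set of ``N0`` actually-negative scores ``X_i`` and ``N1``
actually-positive scores ``Y_j``, is the two-sample Mann-Whitney statistic

    Ahat = (1 / N0 N1) sum_ij psi(X_i, Y_j),

with the tie-aware kernel ``psi(x, y) = 1`` if ``x < y``, ``0.5`` if
``x == y`` and ``0`` otherwise.  Two variance estimators for ``Ahat`` (and
the covariance of two AUCs measured on a common test set) are provided:

* ``delong`` -- the classical structural-components estimator of DeLong,
  DeLong and Clarke-Pearson, which estimates the first-order Hoeffding
  variance components from per-subject averages of the kernel; and
* ``ustat`` -- the fully unbiased U-statistic estimator, which estimates all
  three Hoeffding components (including the second-order one the structural
  components method drops) by averaging kernel products over index tuples
  with the required indices distinct.

``compare_auc`` turns either estimator into the familiar two-sided z test
for the difference of the AUCs of two fixed models scored on a common
test set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

__all__ = [
    "ScoreSample",
    "PairedScoreSample",
    "AUCEstimate",
    "AUCComparisonResult",
    "kernel_psi",
    "estimate_auc",
    "structural_components",
    "delong_variance",
    "ustat_variance",
    "auc_estimate",
    "compare_auc",
]

VarianceMethod = Literal["delong", "ustat"]


def _as_finite_1d(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError(f"{name} must contain at least one score")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite scores")
    return arr


@dataclass(frozen=True)
class ScoreSample:
    """Test scores of one model: ``neg_scores`` (X_i) and ``pos_scores`` (Y_j)."""

    neg_scores: np.ndarray
    pos_scores: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "neg_scores", _as_finite_1d(self.neg_scores, "neg_scores"))
        object.__setattr__(self, "pos_scores", _as_finite_1d(self.pos_scores, "pos_scores"))

    @property
    def n0(self) -> int:
        return self.neg_scores.size

    @property
    def n1(self) -> int:
        return self.pos_scores.size


@dataclass(frozen=True)
class PairedScoreSample:
    """Scores of two models on a common test set (row-aligned within class)."""

    neg_scores_1: np.ndarray
    neg_scores_2: np.ndarray
    pos_scores_1: np.ndarray
    pos_scores_2: np.ndarray

    def __post_init__(self) -> None:
        for name in ("neg_scores_1", "neg_scores_2", "pos_scores_1", "pos_scores_2"):
            object.__setattr__(self, name, _as_finite_1d(getattr(self, name), name))
        if self.neg_scores_1.size != self.neg_scores_2.size:
            raise ValueError("negative-class score vectors must have equal length")
        if self.pos_scores_1.size != self.pos_scores_2.size:
            raise ValueError("positive-class score vectors must have equal length")

    @property
    def n0(self) -> int:
        return self.neg_scores_1.size

    @property
    def n1(self) -> int:
        return self.pos_scores_1.size

    def model(self, which: int) -> ScoreSample:
        if which == 1:
            return ScoreSample(self.neg_scores_1, self.pos_scores_1)
        if which == 2:
            return ScoreSample(self.neg_scores_2, self.pos_scores_2)
        raise ValueError("model index must be 1 or 2")


@dataclass(frozen=True)
class AUCEstimate:
    """AUC point estimate with a variance estimate and its components.

    ``variance`` is clamped at zero; ``raw_variance`` keeps the signed value
    (the unbiased U-statistic estimator can be negative in tiny samples).
    """

    auc: float
    variance: float
    method: VarianceMethod
    raw_variance: float
    components: dict = field(default_factory=dict)
    clamped: bool = False


@dataclass(frozen=True)
class AUCComparisonResult:
    """Two-sided z test of the difference of two correlated AUCs."""

    auc_1: float
    auc_2: float
    diff: float
    se_diff: float
    z: float
    p_value: float
    method: VarianceMethod
    degenerate: bool = False


def kernel_psi(x: float, y: float) -> float:
    """Tie-aware ranking kernel: 1 if x < y, 0.5 if tied, 0 if x > y."""
    if not (math.isfinite(x) and math.isfinite(y)):
        raise ValueError("kernel_psi requires finite inputs")
    if x < y:
        return 1.0
    if x == y:
        return 0.5
    return 0.0


def _psi_matrix(neg: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """N0 x N1 matrix of psi(X_i, Y_j) via broadcasting."""
    return 0.5 * (np.sign(pos[np.newaxis, :] - neg[:, np.newaxis]) + 1.0)


def estimate_auc(sample: ScoreSample) -> float:
    """Mann-Whitney AUC estimate, ties counted half.

    Computed from midranks in O(n log n); identical (including in floating
    point) to averaging ``kernel_psi`` over all N0*N1 pairs, since midranks
    encode the same half-integer pair counts.
    """
    neg, pos = sample.neg_scores, sample.pos_scores
    ranks = stats.rankdata(np.concatenate([neg, pos]), method="average")
    pos_rank_sum = ranks[neg.size:].sum()
    n0, n1 = neg.size, pos.size
    return float((pos_rank_sum - n1 * (n1 + 1) / 2.0) / (n0 * n1))


def structural_components(sample: ScoreSample) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject kernel averages (Sen's structural components).

    Returns ``(v01, v10)`` where ``v01[i]`` averages ``psi(X_i, Y_j)`` over
    positives and ``v10[j]`` averages over negatives; both vectors have mean
    equal to the AUC estimate.
    """
    if sample.n0 < 2 or sample.n1 < 2:
        raise ValueError("structural components require at least 2 subjects per class")
    psi = _psi_matrix(sample.neg_scores, sample.pos_scores)
    return psi.mean(axis=1), psi.mean(axis=0)


def delong_variance(sample: ScoreSample) -> float:
    """Structural-components variance estimate of the AUC (DeLong et al.).

    ``S01 / N0 + S10 / N1`` with ``S01``, ``S10`` the ddof-1 sample variances
    of the negative- and positive-subject components; always nonnegative.
    """
    v01, v10 = structural_components(sample)
    return float(v01.var(ddof=1) / v01.size + v10.var(ddof=1) / v10.size)


def _ustat_sums(p1: np.ndarray, p2: np.ndarray) -> tuple[float, float, float, float]:
    """Unbiased U-statistic averages of kernel products for two psi matrices.

    Returns (t01, t10, t11, ta2): estimates of E[psi1(Xi,Yj) psi2(Xi',Yj)]
    over i != i', E[psi1(Xi,Yj) psi2(Xi,Yj')] over j != j', E[psi1 psi2] on a
    common pair, and E[psi1] E[psi2] (distinct subjects everywhere).  With
    p1 is p2 these are the single-model second moments.
    """
    n0, n1 = p1.shape
    prod = p1 * p2
    sum_prod = prod.sum()
    r1, r2 = p1.sum(axis=1), p2.sum(axis=1)
    c1, c2 = p1.sum(axis=0), p2.sum(axis=0)
    s1, s2 = r1.sum(), r2.sum()
    # sum over same-j, distinct-i index pairs (and the row analogue)
    same_j = float(c1 @ c2 - sum_prod)
    same_i = float(r1 @ r2 - sum_prod)
    # all four indices distinct, by inclusion-exclusion on coincident indices
    distinct = float(s1 * s2 - r1 @ r2 - c1 @ c2 + sum_prod)
    t01 = same_j / (n0 * (n0 - 1) * n1)
    t10 = same_i / (n0 * n1 * (n1 - 1))
    t11 = float(sum_prod) / (n0 * n1)
    ta2 = distinct / (n0 * (n0 - 1) * n1 * (n1 - 1))
    return t01, t10, t11, ta2


def ustat_variance(sample: ScoreSample) -> tuple[float, float, float, float]:
    """Unbiased U-statistic variance estimate of the AUC.

    Estimates the three Hoeffding components ``xi01``, ``xi10``, ``xi11``
    (kernel-product expectations minus AUC^2, each formed over index tuples
    with all required indices distinct so the estimate is exactly unbiased)
    and plugs them into

        Var(Ahat) = (N0-1)/(N0 N1) xi01 + (N1-1)/(N0 N1) xi10
                    + 1/(N0 N1) xi11.

    Returns ``(variance, xi01, xi10, xi11)``; the variance may be negative
    in very small samples.
    """
    if sample.n0 < 2 or sample.n1 < 2:
        raise ValueError("unbiased variance estimation requires at least 2 subjects per class")
    psi = _psi_matrix(sample.neg_scores, sample.pos_scores)
    t01, t10, t11, ta2 = _ustat_sums(psi, psi)
    xi01, xi10, xi11 = t01 - ta2, t10 - ta2, t11 - ta2
    n0, n1 = psi.shape
    variance = ((n0 - 1) * xi01 + (n1 - 1) * xi10 + xi11) / (n0 * n1)
    return float(variance), float(xi01), float(xi10), float(xi11)


def auc_estimate(sample: ScoreSample, method: VarianceMethod = "delong") -> AUCEstimate:
    """AUC with its variance estimate packaged as an :class:`AUCEstimate`."""
    auc = estimate_auc(sample)
    if method == "delong":
        v01, v10 = structural_components(sample)
        raw = float(v01.var(ddof=1) / v01.size + v10.var(ddof=1) / v10.size)
        components = {"v01": v01, "v10": v10}
    elif method == "ustat":
        raw, xi01, xi10, xi11 = ustat_variance(sample)
        components = {"xi01": xi01, "xi10": xi10, "xi11": xi11}
    else:
        raise ValueError(f"unknown variance method {method!r}")
    clamped = raw < 0.0
    return AUCEstimate(
        auc=auc,
        variance=max(raw, 0.0),
        method=method,
        raw_variance=raw,
        components=components,
        clamped=clamped,
    )


def _delong_covariance(paired: PairedScoreSample) -> float:
    psi1 = _psi_matrix(paired.neg_scores_1, paired.pos_scores_1)
    psi2 = _psi_matrix(paired.neg_scores_2, paired.pos_scores_2)
    v01_1, v10_1 = psi1.mean(axis=1), psi1.mean(axis=0)
    v01_2, v10_2 = psi2.mean(axis=1), psi2.mean(axis=0)
    s01 = float(np.cov(v01_1, v01_2, ddof=1)[0, 1])
    s10 = float(np.cov(v10_1, v10_2, ddof=1)[0, 1])
    return s01 / paired.n0 + s10 / paired.n1


def _ustat_covariance(paired: PairedScoreSample) -> float:
    psi1 = _psi_matrix(paired.neg_scores_1, paired.pos_scores_1)
    psi2 = _psi_matrix(paired.neg_scores_2, paired.pos_scores_2)
    t01, t10, t11, ta1a2 = _ustat_sums(psi1, psi2)
    n0, n1 = psi1.shape
    xi01, xi10, xi11 = t01 - ta1a2, t10 - ta1a2, t11 - ta1a2
    return ((n0 - 1) * xi01 + (n1 - 1) * xi10 + xi11) / (n0 * n1)


def compare_auc(paired: PairedScoreSample, method: VarianceMethod = "delong") -> AUCComparisonResult:
    """Two-sided z test for equality of two correlated AUCs.

    ``z = (A1 - A2) / SE`` with ``SE^2 = Var(A1) + Var(A2) - 2 Cov(A1, A2)``,
    all three terms estimated by the chosen method on the shared test set.
    A nonpositive ``SE^2`` (possible for the unbiased estimator in tiny
    samples, or for identical score columns) yields the degenerate result
    ``p = 1`` with ``z`` undefined.
    """
    if paired.n0 < 2 or paired.n1 < 2:
        raise ValueError("AUC comparison requires at least 2 subjects per class")
    sample1, sample2 = paired.model(1), paired.model(2)
    auc1, auc2 = estimate_auc(sample1), estimate_auc(sample2)
    if method == "delong":
        var1 = delong_variance(sample1)
        var2 = delong_variance(sample2)
        cov = _delong_covariance(paired)
    elif method == "ustat":
        var1 = ustat_variance(sample1)[0]
        var2 = ustat_variance(sample2)[0]
        cov = _ustat_covariance(paired)
    else:
        raise ValueError(f"unknown variance method {method!r}")
    se_sq = var1 + var2 - 2.0 * cov
    diff = auc1 - auc2
    # relative floor catches exact degeneracy (e.g. identical columns) that
    # floating-point cancellation leaves as a tiny positive residue
    if se_sq <= 1e-12 * (var1 + var2):
        return AUCComparisonResult(
            auc_1=auc1, auc_2=auc2, diff=diff, se_diff=0.0,
            z=float("nan"), p_value=1.0, method=method, degenerate=True,
        )
    se = math.sqrt(se_sq)
    z = diff / se
    p = 2.0 * stats.norm.sf(abs(z))
    return AUCComparisonResult(
        auc_1=auc1, auc_2=auc2, diff=diff, se_diff=se,
        z=z, p_value=float(min(p, 1.0)), method=method,
    )
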
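"""Exact F test of the ideal AUC of nested linear discriminant functions.

For two-class multivariate Gaussian data with common covariance ``V`` and
mean vectors ``mu1`` (positive) and ``mu2`` (negative), the best linear
classifier is Fisher's linear discriminant, and its ideal (infinite-data)
AUC is a monotone function of the squared Mahalanobis distance
``D2 = (mu1 - mu2)' V^-1 (mu1 - mu2)``:

    A = Phi( sqrt(D2) / sqrt(2) ).

Equality of the ideal AUCs of a partial model on ``p`` biomarkers and a
full model adding ``q`` more is therefore equivalent to equality of the two
Mahalanobis distances, which Rao's F test decides exactly at any sample
size: with sample distances ``D2_p`` and ``D2_pq`` computed from a training
sample of ``N0 + N1`` subjects,

    U = (N0 + N1 - p - q - 1) / q
        * ( (1 + c * D2_pq) / (1 + c * D2_p) - 1 ),
    c = N0 N1 / ((N0 + N1)(N0 + N1 - 2)),

follows F(q, N0 + N1 - p - q - 1) under the null hypothesis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TwoClassData",
    "NestedModelSpec",
    "GaussianClassSpec",
    "RaoTestResult",
    "sample_mahalanobis_sq",
    "rao_f_statistic",
    "ideal_auc_f_test",
    "mahalanobis_to_auc",
    "auc_to_mahalanobis",
]

# reciprocal-condition threshold below which the pooled covariance is
# treated as singular rather than silently pseudo-inverted
_RCOND_MIN = 1e-12


class SingularCovarianceError(np.linalg.LinAlgError):
    """Pooled within-class covariance is singular or numerically so."""


@dataclass(frozen=True)
class TwoClassData:
    """Biomarker matrices for the two classes (rows = subjects)."""

    neg_matrix: np.ndarray
    pos_matrix: np.ndarray

    def __post_init__(self) -> None:
        neg = np.atleast_2d(np.asarray(self.neg_matrix, dtype=float))
        pos = np.atleast_2d(np.asarray(self.pos_matrix, dtype=float))
        if neg.shape[1] != pos.shape[1]:
            raise ValueError("classes must share the same biomarker columns")
        if not (np.all(np.isfinite(neg)) and np.all(np.isfinite(pos))):
            raise ValueError("biomarker data contain non-finite values")
        object.__setattr__(self, "neg_matrix", neg)
        object.__setattr__(self, "pos_matrix", pos)

    @property
    def n0(self) -> int:
        return self.neg_matrix.shape[0]

    @property
    def n1(self) -> int:
        return self.pos_matrix.shape[0]

    @property
    def d(self) -> int:
        return self.neg_matrix.shape[1]


@dataclass(frozen=True)
class NestedModelSpec:
    """Column index sets of the p existing and q new biomarkers (disjoint)."""

    existing_idx: tuple[int, ...]
    new_idx: tuple[int, ...]

    def __post_init__(self) -> None:
        existing = tuple(int(i) for i in self.existing_idx)
        new = tuple(int(i) for i in self.new_idx)
        if len(new) < 1:
            raise ValueError("at least one new biomarker is required")
        if set(existing) & set(new):
            raise ValueError("existing and new biomarker index sets must be disjoint")
        if len(set(existing)) != len(existing) or len(set(new)) != len(new):
            raise ValueError("index sets must not contain duplicates")
        object.__setattr__(self, "existing_idx", existing)
        object.__setattr__(self, "new_idx", new)

    @property
    def p(self) -> int:
        return len(self.existing_idx)

    @property
    def q(self) -> int:
        return len(self.new_idx)


@dataclass(frozen=True)
class GaussianClassSpec:
    """Two-class multivariate normal population: means and common covariance."""

    mean_neg: np.ndarray
    mean_pos: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        mean_neg = np.asarray(self.mean_neg, dtype=float).ravel()
        mean_pos = np.asarray(self.mean_pos, dtype=float).ravel()
        cov = np.asarray(self.cov, dtype=float)
        d = mean_neg.size
        if mean_pos.size != d or cov.shape != (d, d):
            raise ValueError("mean vectors and covariance have inconsistent dimensions")
        if not np.allclose(cov, cov.T):
            raise ValueError("covariance matrix must be symmetric")
        object.__setattr__(self, "mean_neg", mean_neg)
        object.__setattr__(self, "mean_pos", mean_pos)
        object.__setattr__(self, "cov", cov)

    @property
    def d(self) -> int:
        return self.mean_neg.size

    def mahalanobis_sq(self, idx: Sequence[int] | None = None) -> float:
        """Population squared Mahalanobis distance, optionally on a subset."""
        sel = np.arange(self.d) if idx is None else np.asarray(idx, dtype=int)
        if sel.size == 0:
            return 0.0
        delta = (self.mean_pos - self.mean_neg)[sel]
        cov = self.cov[np.ix_(sel, sel)]
        return float(delta @ np.linalg.solve(cov, delta))

    def ideal_auc(self, idx: Sequence[int] | None = None) -> float:
        """Ideal AUC of the linear discriminant on the selected biomarkers."""
        return mahalanobis_to_auc(self.mahalanobis_sq(idx))


@dataclass(frozen=True)
class RaoTestResult:
    """Rao F test outcome for added value of q biomarkers over p."""

    u_stat: float
    df1: int
    df2: int
    p_value: float
    d2_partial: float
    d2_full: float


def pooled_covariance(data: TwoClassData, idx: Sequence[int] | None = None) -> np.ndarray:
    """Pooled within-class covariance with denominator N0 + N1 - 2."""
    sel = slice(None) if idx is None else np.asarray(idx, dtype=int)
    neg = data.neg_matrix[:, sel]
    pos = data.pos_matrix[:, sel]
    n0, n1 = neg.shape[0], pos.shape[0]
    if n0 + n1 - 2 < 1:
        raise ValueError("pooled covariance requires N0 + N1 >= 3")
    neg_c = neg - neg.mean(axis=0)
    pos_c = pos - pos.mean(axis=0)
    return (neg_c.T @ neg_c + pos_c.T @ pos_c) / (n0 + n1 - 2)


def sample_mahalanobis_sq(data: TwoClassData, idx: Sequence[int]) -> float:
    """Sample squared Mahalanobis distance between class means on ``idx``.

    ``D2 = (m1 - m0)' S^-1 (m1 - m0)`` with ``S`` the pooled within-class
    covariance (denominator ``N0 + N1 - 2``).  The empty index set returns 0.
    Raises :class:`SingularCovarianceError` when the reciprocal condition
    number of ``S`` falls below 1e-12.
    """
    sel = np.asarray(idx, dtype=int)
    if sel.size == 0:
        return 0.0
    if data.n0 + data.n1 - 2 <= sel.size:
        raise ValueError("sample Mahalanobis distance requires N0 + N1 - 2 > |idx|")
    s = pooled_covariance(data, sel)
    sing = np.linalg.svd(s, compute_uv=False)
    if sing[-1] <= _RCOND_MIN * sing[0] or sing[0] == 0.0:
        raise SingularCovarianceError(
            "pooled covariance is numerically singular on the selected biomarkers"
        )
    delta = data.pos_matrix[:, sel].mean(axis=0) - data.neg_matrix[:, sel].mean(axis=0)
    return float(delta @ np.linalg.solve(s, delta))


def rao_f_statistic(
    d2_partial: float,
    d2_full: float,
    n0: int,
    n1: int,
    p: int,
    q: int,
) -> RaoTestResult:
    """Rao's exact F statistic for additional discriminant variables.

    The one-sided upper-tail p-value is taken from F(q, N0+N1-p-q-1); the
    test is one-sided by construction since added variables can only
    increase the sample Mahalanobis distance.
    """
    if d2_partial < 0 or d2_full < d2_partial:
        raise ValueError("expected 0 <= d2_partial <= d2_full")
    if q < 1:
        raise ValueError("q must be at least 1")
    df1 = q
    df2 = n0 + n1 - p - q - 1
    if df2 < 1:
        raise ValueError(
            f"invalid design: residual degrees of freedom {df2} < 1 "
            f"(N0={n0}, N1={n1}, p={p}, q={q})"
        )
    c = n0 * n1 / ((n0 + n1) * (n0 + n1 - 2))
    u = (df2 / q) * ((1.0 + c * d2_full) / (1.0 + c * d2_partial) - 1.0)
    p_value = float(stats.f.sf(u, df1, df2))
    return RaoTestResult(
        u_stat=float(u), df1=df1, df2=df2, p_value=p_value,
        d2_partial=float(d2_partial), d2_full=float(d2_full),
    )


def ideal_auc_f_test(data: TwoClassData, spec: NestedModelSpec) -> RaoTestResult:
    """Exact F test that q new biomarkers add ideal-AUC value to p existing ones.

    Computes the sample Mahalanobis distances of the partial (existing) and
    full (existing + new) biomarker sets from the training data and refers
    Rao's U statistic to F(q, N0+N1-p-q-1).
    """
    full_idx = spec.existing_idx + spec.new_idx
    d2_partial = sample_mahalanobis_sq(data, spec.existing_idx)
    d2_full = sample_mahalanobis_sq(data, full_idx)
    return rao_f_statistic(d2_partial, d2_full, data.n0, data.n1, spec.p, spec.q)


def mahalanobis_to_auc(d2: float) -> float:
    """Ideal AUC of the linear discriminant: ``Phi(sqrt(D2) / sqrt(2))``.

    ``D2`` is the squared Mahalanobis distance between the class
    distributions; the mapping is strictly increasing with range [0.5, 1).
    """
    if d2 < 0:
        raise ValueError("squared Mahalanobis distance must be nonnegative")
    return float(stats.norm.cdf(math.sqrt(d2) / math.sqrt(2.0)))


def auc_to_mahalanobis(auc: float) -> float:
    """Inverse of :func:`mahalanobis_to_auc` on [0.5, 1)."""
    if not 0.5 <= auc < 1.0:
        raise ValueError("ideal AUC of an LDF lies in [0.5, 1)")
    return float(2.0 * stats.norm.ppf(auc) ** 2)
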
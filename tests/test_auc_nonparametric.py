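"""Unit and property tests for nonparametric AUC estimation and comparison."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nestedroc import (
    PairedScoreSample,
    ScoreSample,
    auc_estimate,
    compare_auc,
    delong_variance,
    estimate_auc,
    kernel_psi,
    structural_components,
    ustat_variance,
)

from _oracles import brute_auc, brute_structural_components, brute_ustat_variance

score_vectors = st.lists(
    st.floats(min_value=-50, max_value=50, allow_nan=False).map(lambda v: round(v, 1)),
    min_size=2,
    max_size=20,
)


@pytest.mark.parametrize(
    "x, y, expected",
    [(1, 2, 1.0), (2, 2, 0.5), (3, 2, 0.0), (-1.5, -1.5, 0.5), (0.0, -0.1, 0.0)],
)
def test_kernel_orders_scores_with_half_ties(x, y, expected):
    assert kernel_psi(x, y) == expected


def test_kernel_rejects_non_finite():
    with pytest.raises(ValueError):
        kernel_psi(np.nan, 1.0)
    with pytest.raises(ValueError):
        kernel_psi(0.0, np.inf)


@pytest.mark.parametrize(
    "neg, pos, expected",
    [
        ([1, 2, 3], [2.5, 3.5], 5 / 6),
        ([0], [1], 1.0),
        ([1, 2], [1, 2], 0.5),
    ],
)
def test_auc_on_hand_computed_fixtures(neg, pos, expected):
    assert estimate_auc(ScoreSample(neg, pos)) == pytest.approx(expected, abs=1e-12)


def test_auc_rejects_empty_class_and_non_finite():
    with pytest.raises(ValueError):
        ScoreSample([], [1.0])
    with pytest.raises(ValueError):
        ScoreSample([1.0, np.nan], [1.0])


def test_rank_based_auc_equals_pair_counting(rng):
    """The midrank formula must reproduce literal pair counting exactly,
    including with ties induced by rounding."""
    for _ in range(50):
        n0, n1 = rng.integers(1, 30, size=2)
        neg = np.round(rng.normal(size=n0), 1)
        pos = np.round(rng.normal(0.5, size=n1), 1)
        assert estimate_auc(ScoreSample(neg, pos)) == brute_auc(neg, pos)


@given(neg=score_vectors, pos=score_vectors)
def test_auc_invariant_under_monotone_transform(neg, pos):
    base = estimate_auc(ScoreSample(neg, pos))
    transform = lambda v: np.exp(0.3 * np.asarray(v)) + 5.0  # strictly increasing
    assert estimate_auc(ScoreSample(transform(neg), transform(pos))) == pytest.approx(
        base, abs=1e-12
    )


@given(neg=score_vectors, pos=score_vectors)
def test_auc_class_swap_symmetry(neg, pos):
    forward = estimate_auc(ScoreSample(neg, pos))
    reverse = estimate_auc(ScoreSample(pos, neg))
    assert forward + reverse == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize(
    "neg, pos, v01, v10",
    [
        ([1, 3], [2, 4], [1.0, 0.5], [0.5, 1.0]),
        ([1, 2], [3, 4], [1.0, 1.0], [1.0, 1.0]),
    ],
)
def test_structural_components_on_fixtures(neg, pos, v01, v10):
    got01, got10 = structural_components(ScoreSample(neg, pos))
    np.testing.assert_allclose(got01, v01)
    np.testing.assert_allclose(got10, v10)


def test_structural_components_average_to_auc(rng):
    for _ in range(20):
        sample = ScoreSample(rng.normal(size=8), rng.normal(0.4, size=11))
        v01, v10 = structural_components(sample)
        auc = estimate_auc(sample)
        assert v01.mean() == pytest.approx(auc, abs=1e-12)
        assert v10.mean() == pytest.approx(auc, abs=1e-12)
        oracle01, oracle10 = brute_structural_components(
            sample.neg_scores, sample.pos_scores
        )
        np.testing.assert_allclose(v01, oracle01, atol=1e-12)
        np.testing.assert_allclose(v10, oracle10, atol=1e-12)


def test_structural_components_require_two_per_class():
    with pytest.raises(ValueError):
        structural_components(ScoreSample([1.0], [2.0, 3.0]))


def test_delong_variance_hand_computed_fixture():
    assert delong_variance(ScoreSample([1, 3], [2, 4])) == pytest.approx(0.125)


def test_delong_variance_zero_under_perfect_separation():
    assert delong_variance(ScoreSample([1, 2], [3, 4])) == 0.0


def test_delong_variance_nonnegative(rng):
    for _ in range(50):
        n0, n1 = rng.integers(2, 15, size=2)
        sample = ScoreSample(
            np.round(rng.normal(size=n0), 1), np.round(rng.normal(size=n1), 1)
        )
        assert delong_variance(sample) >= 0.0


def test_ustat_variance_zero_under_perfect_separation():
    variance, xi01, xi10, xi11 = ustat_variance(ScoreSample([1, 2], [3, 4]))
    assert variance == 0.0 and xi01 == 0.0 and xi10 == 0.0 and xi11 == 0.0


def test_ustat_variance_matches_brute_force_enumeration(rng):
    """Optimized O(N0 N1) reduction vs literal index-tuple loops, tiny sizes."""
    for _ in range(25):
        n0, n1 = rng.integers(2, 9, size=2)
        neg = np.round(rng.normal(size=n0), 1)
        pos = np.round(rng.normal(0.3, size=n1), 1)
        got = ustat_variance(ScoreSample(neg, pos))
        expected = brute_ustat_variance(neg, pos)
        np.testing.assert_allclose(got, expected, atol=1e-12)


def test_ustat_variance_requires_two_per_class():
    with pytest.raises(ValueError):
        ustat_variance(ScoreSample([1.0], [2.0, 3.0]))


def test_auc_estimate_variance_clamp_consistency(rng):
    """Reported variance is max(raw, 0) and the clamp flag mirrors the sign;
    in practice the single-sample unbiased estimator stays nonnegative."""
    for _ in range(200):
        sample = ScoreSample(rng.normal(size=2), rng.normal(2.0, size=3))
        est = auc_estimate(sample, method="ustat")
        assert est.variance == max(est.raw_variance, 0.0)
        assert est.clamped == (est.raw_variance < 0.0)
        assert est.variance >= 0.0


def test_compare_identical_models_is_degenerate():
    neg, pos = [1.0, 3.0, 2.0], [2.5, 4.0, 3.5]
    paired = PairedScoreSample(neg, neg, pos, pos)
    for method in ("delong", "ustat"):
        result = compare_auc(paired, method=method)
        assert result.diff == 0.0
        assert result.p_value == 1.0
        assert result.degenerate


def test_compare_auc_consistent_fields(rng):
    paired = PairedScoreSample(
        rng.normal(size=30),
        rng.normal(size=30),
        rng.normal(0.8, size=40),
        rng.normal(0.8, size=40),
    )
    for method in ("delong", "ustat"):
        result = compare_auc(paired, method=method)
        assert result.diff == pytest.approx(result.auc_1 - result.auc_2)
        assert 0.0 <= result.p_value <= 1.0
        assert result.z == pytest.approx(result.diff / result.se_diff)


def test_independent_models_have_near_zero_covariance(rng):
    """With independent score columns the estimated covariance term averages
    to ~0, so the paired SE^2 averages to the sum of the two variances."""
    from nestedroc.auc_nonparametric import _delong_covariance, _ustat_covariance

    n_rep = 3000
    cov_dl = np.empty(n_rep)
    cov_us = np.empty(n_rep)
    for k in range(n_rep):
        paired = PairedScoreSample(
            rng.normal(size=15),
            rng.normal(size=15),
            rng.normal(0.5, size=15),
            rng.normal(0.5, size=15),
        )
        cov_dl[k] = _delong_covariance(paired)
        cov_us[k] = _ustat_covariance(paired)
    for values in (cov_dl, cov_us):
        se = values.std(ddof=1) / np.sqrt(n_rep)
        assert abs(values.mean()) < 4 * se + 1e-6


def test_paired_sample_requires_aligned_lengths():
    with pytest.raises(ValueError):
        PairedScoreSample([1, 2], [1, 2, 3], [4, 5], [4, 5])
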
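"""Independent brute-force oracles used to validate the optimized estimators.

Everything here is written as literal loops over index tuples, directly from
the defining expectations, and stays deliberately independent of the library
code paths it checks (only the scalar kernel is shared).
"""

import numpy as np

from nestedroc import kernel_psi


def brute_auc(neg, pos) -> float:
    """AUC by literal pair counting."""
    total = 0.0
    for x in neg:
        for y in pos:
            total += kernel_psi(x, y)
    return total / (len(neg) * len(pos))


def brute_structural_components(neg, pos):
    v01 = [np.mean([kernel_psi(x, y) for y in pos]) for x in neg]
    v10 = [np.mean([kernel_psi(x, y) for x in neg]) for y in pos]
    return np.array(v01), np.array(v10)


def brute_ustat_variance(neg, pos):
    """Unbiased U-statistic variance by literal enumeration of index tuples.

    Each expectation is replaced by the average of the kernel product over
    the tuples with the required indices distinct; the squared-AUC term is
    the four-index U-statistic average (i != i', j != j').
    """
    n0, n1 = len(neg), len(pos)
    psi = np.array([[kernel_psi(x, y) for y in pos] for x in neg])

    s01 = 0.0  # shared positive subject, distinct negatives
    for j in range(n1):
        for i in range(n0):
            for i2 in range(n0):
                if i != i2:
                    s01 += psi[i, j] * psi[i2, j]
    t01 = s01 / (n0 * (n0 - 1) * n1)

    s10 = 0.0  # shared negative subject, distinct positives
    for i in range(n0):
        for j in range(n1):
            for j2 in range(n1):
                if j != j2:
                    s10 += psi[i, j] * psi[i, j2]
    t10 = s10 / (n0 * n1 * (n1 - 1))

    t11 = float(np.mean(psi * psi))

    sa2 = 0.0  # all four indices distinct
    for i in range(n0):
        for i2 in range(n0):
            for j in range(n1):
                for j2 in range(n1):
                    if i != i2 and j != j2:
                        sa2 += psi[i, j] * psi[i2, j2]
    ta2 = sa2 / (n0 * (n0 - 1) * n1 * (n1 - 1))

    xi01, xi10, xi11 = t01 - ta2, t10 - ta2, t11 - ta2
    variance = ((n0 - 1) * xi01 + (n1 - 1) * xi10 + xi11) / (n0 * n1)
    return variance, xi01, xi10, xi11


def brute_mahalanobis_sq(neg, pos):
    """Sample Mahalanobis distance via an explicit matrix inverse."""
    neg = np.asarray(neg, dtype=float)
    pos = np.asarray(pos, dtype=float)
    n0, n1 = neg.shape[0], pos.shape[0]
    scatter = np.zeros((neg.shape[1],) * 2)
    for row in neg:
        d = row - neg.mean(axis=0)
        scatter += np.outer(d, d)
    for row in pos:
        d = row - pos.mean(axis=0)
        scatter += np.outer(d, d)
    pooled = scatter / (n0 + n1 - 2)
    delta = pos.mean(axis=0) - neg.mean(axis=0)
    return float(delta @ np.linalg.inv(pooled) @ delta)
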
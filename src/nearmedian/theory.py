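"""Closed-form theory of the adjacency-sampling construction.

For k random genomes the first sampling stage takes ``theta * n``
adjacencies from each input in turn; an adjacency of a later genome is
usable only if both of its ends are still free, which happens with
probability ``(1 - (k-1) * theta)^2`` for the last genome processed.
Requiring at least ``theta * n`` such adjacencies, in expectation, pins
the maximal sampling fraction ``theta*(k)`` as the root of a quadratic,
and the constructed genome's normalized score is bounded by
``k * (1 - theta*)``, which approaches the random-genome median score
``k - 1`` as k grows.

When all k genomes share a fraction ``psi`` of their adjacencies (and,
for k = 3, pairs share extra fractions ``omega[i,j]``), the shared
adjacencies are included outright and the same argument yields the
generalized ``theta*`` and bounds below.

The number of two-free-end adjacencies available in the last genome is
binomially distributed with success probability ``(1 - 2*theta)^2`` (for
k = 3), so the probability that stage 1 succeeds has both an exact
binomial-tail form and a normal approximation with continuity
correction.  The approximation exhibits a sharp phase change at
``theta = theta*``: the success probability tends to 1 below it and to 0
above it as n grows.
"""

from __future__ import annotations

import math

import pandas as pd
from scipy.stats import binom, norm

TABLE1_N = (5, 10, 50, 100, 500, 1000, 2000, 10000)
TABLE1_THETA = (0.10, 0.20, 0.24, 0.25, 0.26, 0.30, 1 / 3)
TABLE2_K = (3, 4, 5, 10, 50, 100, 500, 1000, 2000, 10000)
TABLE3_K = (3, 4, 5, 10, 50, 100, 500, 1000, 2000, 10000)
TABLE3_PSI = 0.625


def _check_k(k: int) -> None:
    if int(k) != k or k < 3:
        raise ValueError(f"k must be an integer >= 3, got {k}")


def _check_frac(name: str, x: float) -> None:
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {x}")


def theta_max(k: int) -> float:
    """Maximal sampling fraction theta*(k) for k random genomes.

    The positive root below 1/(k-1) of ``(1 - (k-1)*theta)^2 = theta``:
    ``theta* = (2k - 1 - sqrt(4k - 3)) / (2 (k-1)^2)``.  Equals 1/4 at
    k = 3 and decreases in k.
    """
    _check_k(k)
    return (2 * k - 1 - math.sqrt(4 * k - 3)) / (2 * (k - 1) ** 2)


def score_bound(k: int) -> float:
    """Score bound ``k * (1 - theta*(k))`` of the stage-1 construction.

    Exceeds the random-genome median score ``k - 1``, with the gap
    vanishing as k grows.
    """
    return k * (1 - theta_max(k))


def theta_max_shared(k: int, psi: float) -> float:
    """theta*(k, psi) when all k genomes share a fraction psi of adjacencies."""
    _check_k(k)
    _check_frac("psi", psi)
    return (
        2 * k + 2 * psi - 2 * k * psi - 1 - math.sqrt(4 * (k + psi - k * psi) - 3)
    ) / (2 * (k - 1) ** 2)


def score_bound_shared(k: int, psi: float) -> float:
    """Score bound ``k * (1 - (theta*(k, psi) + psi))`` under all-k sharing."""
    return k * (1 - (theta_max_shared(k, psi) + psi))


def median_score_shared(k: int, psi: float) -> float:
    """Expected normalized median score ``(k-1) * (1-psi)`` under all-k sharing."""
    _check_k(k)
    _check_frac("psi", psi)
    return k * (1 - (psi + (1 - psi) / k))


def theta_max_general(psi: float = 0.0, omega_sum: float = 0.0) -> float:
    """theta* for k = 3 with all-shared fraction psi plus pairwise extras.

    Only the total shared fraction ``s = psi + sum omega[i,j]`` matters:
    ``theta* = (5 - 4s - sqrt(9 - 8s)) / 8``, which coincides with
    ``theta_max_shared(3, s)``.
    """
    s = psi + omega_sum
    _check_frac("psi + omega_sum", s)
    return (5 - 4 * s - math.sqrt(9 - 8 * s)) / 8


def score_bound_general(psi: float = 0.0, omega_sum: float = 0.0) -> float:
    """Score bound ``3 * (1 - (theta* + psi + sum omega))`` for k = 3."""
    s = psi + omega_sum
    return 3 * (1 - (theta_max_general(psi, omega_sum) + s))


def _p_two_free(theta: float) -> float:
    return (1 - 2 * theta) ** 2


def _check_theta(theta: float) -> None:
    if not 0.0 <= theta <= 1 / 3 + 1e-12:
        raise ValueError(f"theta must lie in [0, 1/3], got {theta}")


def success_prob_exact(n: int, theta: float) -> float:
    """Exact binomial tail P(X >= theta*n) of the two-free-end count.

    X ~ Binomial(n, (1 - 2*theta)^2); the required count is
    ``ceil(theta * n)`` since counts are integers.
    """
    _check_theta(theta)
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    m = math.ceil(theta * n - 1e-9)
    if m <= 0:
        return 1.0
    return float(binom.sf(m - 1, n, _p_two_free(theta)))


def success_prob_normal(n: int, theta: float) -> float:
    """Normal approximation with continuity correction to the stage-1 success tail.

    ``1 - Phi(Z)`` with ``Z = (theta*n + 0.5 - n*p) / sqrt(n*p*(1-p))``,
    ``p = (1 - 2*theta)^2``.  The required count ``m = theta*n`` is used
    real-valued (not rounded) and the correction enters as +0.5.
    """
    _check_theta(theta)
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    p = _p_two_free(theta)
    var = n * p * (1 - p)
    if var <= 0.0:
        return 1.0 if theta * n <= n * p else 0.0
    z = (theta * n + 0.5 - n * p) / math.sqrt(var)
    return float(norm.sf(z))


def table1(n_values=TABLE1_N, theta_values=TABLE1_THETA) -> pd.DataFrame:
    """Stage-1 success probabilities (normal approximation) on an (n, theta) grid."""
    data = {
        round(theta, 3): [success_prob_normal(n, theta) for n in n_values]
        for theta in theta_values
    }
    df = pd.DataFrame(data, index=pd.Index(n_values, name="n"))
    df.columns.name = "theta"
    return df


def table2(k_values=TABLE2_K) -> pd.DataFrame:
    """Score bound of the construction vs. the median score k-1, over k."""
    rows = [
        {"k_minus_1": k - 1, "score_bound": score_bound(k), "median_score": k - 1.0}
        for k in k_values
    ]
    return pd.DataFrame(rows, index=pd.Index(k_values, name="k"))


def table3(k_values=TABLE3_K, psi: float = TABLE3_PSI) -> pd.DataFrame:
    """Shared-adjacency score bound, true-median value, and their difference, over k."""
    rows = []
    for k in k_values:
        bound = score_bound_shared(k, psi)
        med = median_score_shared(k, psi)
        rows.append(
            {"score_bound": bound, "median_score": med, "difference": bound - med}
        )
    return pd.DataFrame(rows, index=pd.Index(k_values, name="k"))
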
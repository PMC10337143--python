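"""Permutation-pooled p-values and Storey q-values.

The tests in this package produce one observed statistic per feature and a
large pool of permutation statistics shared by all features (the same
permutation draw is applied to every feature, preserving cross-feature
correlation in the null).  Significance follows the pooled-permutation
scheme: the two-sided empirical p-value of each observed statistic against
the absolute values of the pooled null, with an add-one correction so that
p > 0 and p is super-uniform under the null; q-values multiply the
Benjamini-Hochberg adjustment by a Storey estimate of the null proportion
pi0.
"""

from __future__ import annotations

import numpy as np

__all__ = ["pooled_pvalues", "estimate_pi0", "qvalue_from_null"]


def pooled_pvalues(observed: np.ndarray, null: np.ndarray) -> np.ndarray:
    """Two-sided empirical p: (1 + #{|null| >= |obs|}) / (1 + #null)."""
    null = np.asarray(null).ravel()
    if null.size == 0:
        raise ValueError("empty null pool")
    anull = np.sort(np.abs(null))
    aobs = np.abs(np.asarray(observed, dtype=float))
    # count of null values >= each observed value
    geq = anull.size - np.searchsorted(anull, aobs, side="left")
    return (1.0 + geq) / (1.0 + anull.size)


def estimate_pi0(
    pvalues: np.ndarray,
    lambdas: np.ndarray | None = None,
    degree: int = 3,
) -> float:
    """Storey's smoother estimate of the null proportion pi0.

    ``pi0(lambda) = #{p > lambda} / (N (1 - lambda))`` is evaluated on the
    grid 0.05..0.95 (step 0.05), a degree-3 polynomial is fit, and the
    smoothed value at the largest lambda is clipped to [1/N, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    if n == 0:
        raise ValueError("no p-values")
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_l = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
    if np.allclose(pi0_l, pi0_l[0]):
        pi0 = pi0_l[0]
    else:
        coef = np.polyfit(lambdas, pi0_l, deg=degree)
        pi0 = float(np.polyval(coef, lambdas[-1]))
    return float(np.clip(pi0, 1.0 / n, 1.0))


def qvalue_from_null(
    observed: np.ndarray, null: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """p- and q-values for observed statistics against a pooled null.

    q_i = pi0 * min_{j: p_j >= p_i} (p_j * N / rank_j), i.e. the BH step-up
    adjustment scaled by the estimated null proportion, monotone
    nondecreasing in p.
    """
    p = pooled_pvalues(observed, null)
    pi0 = estimate_pi0(p)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1] * pi0
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return p, q
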
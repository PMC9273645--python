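"""Multiple-testing corrections: Storey q-values, Benjamini-Hochberg,
Bonferroni.

The Storey q-value estimates the positive false-discovery rate. The null
proportion pi0 is estimated from the p-value histogram on a lambda grid,
smoothed with a cubic fit and evaluated at the largest lambda, following
the standard smoother approach; q-values are then pi0-scaled step-up
values made monotone in p.
"""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

DEFAULT_LAMBDAS = np.round(np.arange(0.0, 0.96, 0.05), 2)


def _smoothing_spline(x: np.ndarray, y: np.ndarray, df: float = 3.0) -> np.ndarray:
    """Natural cubic smoothing spline fitted values with a target effective
    degrees of freedom (trace of the smoother matrix), Green & Silverman
    formulation. The penalty is found by bisection on log10(alpha)."""
    n = len(x)
    h = np.diff(x)
    q = np.zeros((n, n - 2))
    r = np.zeros((n - 2, n - 2))
    for j in range(1, n - 1):
        q[j - 1, j - 1] = 1.0 / h[j - 1]
        q[j, j - 1] = -1.0 / h[j - 1] - 1.0 / h[j]
        q[j + 1, j - 1] = 1.0 / h[j]
        r[j - 1, j - 1] = (h[j - 1] + h[j]) / 3.0
        if j < n - 2:
            r[j - 1, j] = r[j, j - 1] = h[j] / 6.0
    penalty = q @ np.linalg.solve(r, q.T)

    def smoother(log_alpha: float):
        inv = np.linalg.inv(np.eye(n) + 10.0**log_alpha * penalty)
        return inv @ y, np.trace(inv)

    lo, hi = -10.0, 10.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        _, trace = smoother(mid)
        if trace > df:
            lo = mid
        else:
            hi = mid
    fitted, _ = smoother(0.5 * (lo + hi))
    return fitted


def estimate_pi0(p, lambdas=DEFAULT_LAMBDAS) -> float:
    """Estimate the proportion of true null hypotheses.

    pi0(lambda) = #{p > lambda} / (m * (1 - lambda)) on the grid; a natural
    cubic smoothing spline with 3 effective degrees of freedom is fit to
    pi0(lambda) and evaluated at max(lambda); the result is clipped to
    (0, 1].
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return 1.0
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.size < 4:
        # not enough grid points to smooth; use the largest lambda directly
        lam = lambdas.max()
        pi0 = (p > lam).sum() / (p.size * (1 - lam))
        return float(np.clip(pi0, np.finfo(float).tiny, 1.0))
    pi0_grid = np.array(
        [(p > lam).sum() / (p.size * (1.0 - lam)) for lam in lambdas]
    )
    fitted = _smoothing_spline(lambdas, pi0_grid, df=3.0)
    return float(np.clip(fitted[-1], np.finfo(float).tiny, 1.0))


def storey_qvalues(p, lambdas=DEFAULT_LAMBDAS, pi0: float | None = None):
    """Storey q-values for a family of p-values.

    Returns (q, pi0). q is monotone nondecreasing when the p-values are
    sorted, and every q lies in (0, 1].
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.array([]), 1.0
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p, lambdas)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    # enforce monotonicity from the largest p down
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q, float(pi0)


def bh_qvalues(p) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.array([])
    return multipletests(p, method="fdr_bh")[1]


def bonferroni(p, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values; ``m`` overrides the family size."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.array([])
    if m is None:
        m = p.size
    return np.minimum(1.0, m * p)
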
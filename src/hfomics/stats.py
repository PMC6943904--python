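"""Shared statistical primitives.

Small, well-specified building blocks used across the pipeline: Welch's
two-sample t-test (vectorised over genes), Benjamini-Hochberg step-up
adjustment, Spearman rank correlation with an exact permutation p-value for
small samples, and Pearson correlation with a t-approximation p-value.

These are implemented directly (rather than calling a monolithic routine)
because the pipeline applies them to thousands of genes at once and because
the small-sample Spearman null is computed exactly by permutation, which the
usual large-sample approximations do not provide.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
from scipy import special, stats

__all__ = [
    "welch_ttest",
    "benjamini_hochberg",
    "spearman",
    "pearson",
    "EXACT_SPEARMAN_MAX_N",
]

#: largest sample size for which the Spearman permutation null is enumerated
EXACT_SPEARMAN_MAX_N = 9


def welch_ttest(a: np.ndarray, b: np.ndarray, axis: int = -1):
    """Welch's unequal-variance two-sample t-test.

    Parameters
    ----------
    a, b
        Arrays of observations; the test is applied along ``axis`` and
        broadcast over the remaining dimensions (e.g. genes x samples).

    Returns
    -------
    t : ndarray
        Welch t statistic.
    p : ndarray
        Two-sided p-value from the t distribution with Welch-Satterthwaite
        degrees of freedom.  Pairs of groups with zero pooled variance
        (both groups constant) get ``t = 0`` and ``p = 1``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.shape[axis], b.shape[axis]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    ma = a.mean(axis=axis)
    mb = b.mean(axis=axis)
    va = a.var(axis=axis, ddof=1)
    vb = b.var(axis=axis, ddof=1)
    se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    degenerate = se2 == 0
    t = np.where(degenerate, 0.0, t)
    df = np.where(degenerate, 1.0, df)
    p = 2.0 * special.stdtr(df, -np.abs(t))
    p = np.where(degenerate, 1.0, p)
    if np.ndim(t) == 0:
        return float(t), float(p)
    return t, p


def benjamini_hochberg(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Input order is preserved; adjusted values are clipped to 1 and are
    monotone in the ranks of the raw p-values (cumulative-minimum
    enforcement of the step-up rule).
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d array of p-values")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho: float) -> float:
    """Two-sided permutation p for Spearman rho by full enumeration.

    Enumerates all n! orderings of one rank vector (feasible for n <= 9),
    honouring ties through the average ranks themselves.
    """
    n = rx.size
    perm = np.array(list(permutations(range(n))), dtype=np.intp)
    ry_perm = ry[perm]  # (n!, n)
    cx = rx - rx.mean()
    cy = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((cx**2).sum() * (cy**2).sum(axis=1))
    rho_null = (cy @ cx) / denom
    return float(np.mean(np.abs(rho_null) >= np.abs(rho) - 1e-12))


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Average ranks are used for ties.  The p-value comes from the exact
    permutation null for n <= 9 and from the usual t-approximation
    ``t = rho * sqrt((n-2) / (1-rho^2))`` for larger n.

    Raises
    ------
    ValueError
        If either input is constant (rho undefined) or lengths differ.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: Spearman rho undefined")
    rx, ry = _rank(x), _rank(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_SPEARMAN_MAX_N:
        p = _exact_spearman_p(rx, ry, rho)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * special.stdtr(n - 2, -abs(t)))
    return rho, p


def pearson(x, y) -> tuple[float, float]:
    """Pearson correlation with a two-sided t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: Pearson r undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = float(2.0 * special.stdtr(n - 2, -abs(t)))
    return r, p
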
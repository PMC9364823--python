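"""Rank statistics underlying the overexpression screens.

The Mann-Whitney U test is the workhorse of every differential screen in
this package (one-vs-rest marker detection, ligand/receptor overexpression,
post- vs pre-irradiation upregulation).  Single-cell expression vectors are
heavily tied (zero-inflated), so the implementation is explicit about tie
handling on both the exact and the asymptotic path:

* both groups of size <= ``exact_max`` (default 8): exact permutation
  enumeration of all C(n1+n2, n1) group assignments of the pooled values;
* otherwise: normal approximation with the standard tie-corrected variance
  and a 0.5 continuity correction;
* an all-tied input has zero permutation variance and is reported as p = 1.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy.stats import rankdata

EXACT_MAX = 8

_ALTERNATIVES = ("greater", "less", "two-sided")


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for group *x*: number of (x, y) pairs with x > y, ties counting 1/2."""
    xc = np.asarray(x, dtype=float)[:, None]
    yc = np.asarray(y, dtype=float)[None, :]
    return float((xc > yc).sum() + 0.5 * (xc == yc).sum())


def _exact_p(x: np.ndarray, y: np.ndarray, alternative: str) -> tuple[float, float]:
    pooled = np.concatenate([x, y]).astype(float)
    n = pooled.size
    n1 = x.size
    u_obs = _u_statistic(x, y)
    idx = np.arange(n)
    us = np.empty(math.comb(n, n1))
    for i, chosen in enumerate(combinations(idx, n1)):
        mask = np.zeros(n, dtype=bool)
        mask[list(chosen)] = True
        us[i] = _u_statistic(pooled[mask], pooled[~mask])
    eps = 1e-12
    p_ge = float(np.mean(us >= u_obs - eps))
    p_le = float(np.mean(us <= u_obs + eps))
    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_ge, p_le))
    return u_obs, p


def tie_term(pooled: np.ndarray) -> float:
    """Sum of t^3 - t over groups of tied values in the pooled sample."""
    _, counts = np.unique(np.asarray(pooled, dtype=float), return_counts=True)
    return float((counts.astype(float) ** 3 - counts).sum())


def normal_p_from_u(
    u: float, n1: int, n2: int, ties: float, alternative: str
) -> float:
    """Tie-corrected, continuity-corrected normal-approximation p-value.

    ``ties`` is the ``tie_term`` of the pooled sample of size n1 + n2.
    """
    n = n1 + n2
    mu = n1 * n2 / 2.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - ties / (n * (n - 1)))
    if sigma2 <= 0:  # every pooled value identical
        return 1.0
    sd = math.sqrt(sigma2)
    from scipy.stats import norm

    def sf(z):
        return float(norm.sf(z))

    p_greater = sf((u - mu - 0.5) / sd)
    p_less = sf((mu - u - 0.5) / sd)
    if alternative == "greater":
        return min(1.0, p_greater)
    if alternative == "less":
        return min(1.0, p_less)
    return min(1.0, 2.0 * min(p_greater, p_less))


def mann_whitney_u(
    x, y, alternative: str = "two-sided", exact_max: int = EXACT_MAX
) -> tuple[float, float]:
    """Mann-Whitney U test of ``x`` against ``y``.

    Returns ``(u, p)`` where ``u`` is the U statistic of the first group.
    ``alternative='greater'`` tests whether values in ``x`` are
    stochastically greater than values in ``y``.
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if x.size <= exact_max and y.size <= exact_max:
        return _exact_p(x, y, alternative)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = float(ranks[: x.size].sum())
    u = r1 - x.size * (x.size + 1) / 2.0
    p = normal_p_from_u(u, x.size, y.size, tie_term(pooled), alternative)
    return u, p


def bonferroni(p, m: int):
    """Bonferroni adjustment min(1, p * m); never decreases p."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, np.asarray(p, dtype=float) * m)
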
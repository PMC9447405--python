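"""Validation statistics for comparing two quantification routes.

Spearman's rank correlation is the primary agreement statistic: on
tie-free data it is computed exactly from the classic rank-difference
formula

    r = 1 - 6 * sum(d_i^2) / (N * (N^2 - 1))

where ``d_i`` is the rank difference of pair ``i`` and ``N`` the number
of pairs.  When ties are present (zeros from empty spots tie routinely)
the statistic is instead the Pearson correlation of average-rank vectors,
which reduces to the formula above in the tie-free case.  Ordinary least
squares regression (slope, intercept, R^2) and a two-group comparison
(Mann-Whitney U by default, Welch's t as an option) round out the suite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "RegressionResult",
    "spearman",
    "linear_regression",
    "compare_groups",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p_value: float
    method: str  # "eq1" (tie-free rank-difference formula) or "rank_pearson"

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"correlation {self.r} outside [-1, 1]")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if not -1e-12 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared {self.r_squared} outside [0, 1]")


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64).ravel()
    if np.isnan(arr).any():
        raise ValueError(f"{name} contains missing values")
    return arr


def _spearman_p_t_approx(r: float, n: int) -> float:
    """Two-sided p from the t-approximation on n - 2 degrees of freedom."""
    if abs(r) >= 1.0:
        return 0.0  # perfect monotone association; p = 0 by convention
    if n < 3:
        return float("nan")
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), df=n - 2))


def _spearman_p_exact(rx: np.ndarray, ry: np.ndarray, r_obs: float) -> float:
    """Exact permutation p-value: fraction of permutations with |r| >= |r_obs|.

    Enumerates all N! pairings of the rank vectors; practical for N <= 10.
    """
    n = rx.size
    count = 0
    total = 0
    sx = np.std(rx) * np.sqrt(n)
    sy = np.std(ry) * np.sqrt(n)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    for perm in itertools.permutations(range(n)):
        r_perm = float(rxc @ ryc[list(perm)]) / (sx * sy)
        if abs(r_perm) >= abs(r_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman(x, y, p_method: str = "t") -> CorrelationResult:
    """Spearman rank correlation with a two-sided significance test.

    Parameters
    ----------
    x, y : array-like
        Paired observations of equal length, N >= 2, no missing values.
    p_method : {"t", "exact"}
        "t" uses the t-approximation on N - 2 degrees of freedom.
        "exact" enumerates the permutation distribution (N <= 10 only).
    """
    xa = _as_1d(x, "x")
    ya = _as_1d(y, "y")
    if xa.size != ya.size:
        raise ValueError(f"length mismatch: {xa.size} vs {ya.size}")
    n = xa.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    rx = sps.rankdata(xa, method="average")
    ry = sps.rankdata(ya, method="average")
    tie_free = np.unique(xa).size == n and np.unique(ya).size == n
    if tie_free:
        d = rx - ry
        r = 1.0 - 6.0 * float(d @ d) / (n * (n * n - 1))
        method = "eq1"
    else:
        sx, sy = np.std(rx), np.std(ry)
        if sx == 0 or sy == 0:  # a constant vector has no rank ordering
            raise ValueError("cannot rank-correlate a constant vector")
        r = float(np.corrcoef(rx, ry)[0, 1])
        method = "rank_pearson"
    r = float(np.clip(r, -1.0, 1.0))
    if p_method == "t":
        p = _spearman_p_t_approx(r, n)
    elif p_method == "exact":
        if n > 10:
            raise ValueError("exact permutation p-value supported for N <= 10 only")
        p = _spearman_p_exact(rx, ry, r)
    else:
        raise ValueError(f"p_method must be 't' or 'exact', got {p_method!r}")
    return CorrelationResult(r=r, n=n, p_value=p, method=method)


def linear_regression(x, y) -> RegressionResult:
    """Ordinary least squares fit of y on x with R^2 = 1 - SS_res/SS_tot."""
    xa = _as_1d(x, "x")
    ya = _as_1d(y, "y")
    if xa.size != ya.size:
        raise ValueError(f"length mismatch: {xa.size} vs {ya.size}")
    if xa.size < 2:
        raise ValueError("need at least 2 pairs")
    if np.all(xa == xa[0]):
        raise ValueError("x is constant; slope is undefined")
    fit = sps.linregress(xa, ya)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def compare_groups(a, b, test: str = "mannwhitney") -> float:
    """Two-sided p-value comparing two independent groups.

    The default is the Mann-Whitney U test: the exact (enumerated) null
    distribution when both groups are small (<= 8) and tie-free, the
    normal approximation with tie correction otherwise.  ``test="welch"``
    selects Welch's unequal-variance t-test instead.
    """
    aa = _as_1d(a, "a")
    ba = _as_1d(b, "b")
    if aa.size == 0 or ba.size == 0:
        raise ValueError("both groups must be non-empty")
    if test == "mannwhitney":
        res = sps.mannwhitneyu(aa, ba, alternative="two-sided", method="auto")
    elif test == "welch":
        res = sps.ttest_ind(aa, ba, equal_var=False)
    else:
        raise ValueError(f"test must be 'mannwhitney' or 'welch', got {test!r}")
    return min(1.0, float(res.pvalue))
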
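"""Robust slope fitting and permutation slope tests.

These are the statistical primitives behind both the ground-truth
progression criteria and the PoPLR benchmark: an ordinary least-squares
slope with residual-based outlier removal, a two-sided t-test on the
slope, and a one-sided (deterioration) permutation test that shuffles the
observed values over the fixed visit times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np
from scipy import stats

#: Series lengths up to this many points are tested against every ordering.
EXHAUSTIVE_MAX_N = 7
#: Random permutations drawn for longer series.
DEFAULT_N_PERM = 5000
#: Minimum series length at which residual outlier removal is attempted.
OUTLIER_MIN_N = 5


@dataclass(frozen=True)
class SlopeFit:
    """Result of a robust slope fit plus its null tests."""

    slope: float
    intercept: float
    p_t: float            # two-sided t-test p for slope = 0
    p_perm: float         # one-sided permutation p (deterioration)
    n_used: int
    outlier_indices: tuple[int, ...]


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    xm = x.mean()
    ym = y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0.0:
        raise ValueError("constant dates: slope undefined")
    slope = float(((x - xm) * (y - ym)).sum() / sxx)
    return slope, ym - slope * xm


def remove_outliers(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Indices kept after the median +/- 1.5 IQR residual rule.

    Residuals come from an initial least-squares fit; points whose residual
    falls outside median(res) +/- 1.5*IQR(res) are dropped.  Applied only to
    series of length >= 5 (shorter series are returned intact).  When the
    IQR degenerates to zero, any point whose residual differs from the
    median is treated as an outlier, but never more than floor(n/3) points
    (those furthest from the median go first) so the refit stays defined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < OUTLIER_MIN_N:
        return np.arange(n)
    slope, intercept = _ols(x, y)
    res = y - (intercept + slope * x)
    med = float(np.median(res))
    q1, q3 = np.percentile(res, [25, 75])
    iqr = float(q3 - q1)
    dev = np.abs(res - med)
    if iqr == 0.0:
        bad = np.flatnonzero(dev > 1e-12)
        max_remove = n // 3
        if len(bad) > max_remove:
            # keep the least deviant of the offenders
            order = bad[np.argsort(dev[bad], kind="stable")[::-1]]
            bad = np.sort(order[:max_remove])
        keep = np.setdiff1d(np.arange(n), bad)
    else:
        lo, hi = med - 1.5 * iqr, med + 1.5 * iqr
        keep = np.flatnonzero((res >= lo) & (res <= hi))
    if len(keep) < 3:  # never degrade below a fittable series
        return np.arange(n)
    return keep


@lru_cache(maxsize=256)
def _exhaustive_coef_matrix(x_key: tuple[float, ...]) -> np.ndarray:
    """All-orderings slope coefficient matrix for fixed visit times.

    Row k holds the centred/normalised x coefficients re-ordered by the
    k-th permutation, so that (matrix @ y) yields every permuted slope in
    one product.  Cached per distinct visit-time vector.
    """
    x = np.asarray(x_key, dtype=float)
    c = (x - x.mean()) / ((x - x.mean()) ** 2).sum()
    perms = np.array(list(permutations(range(len(x)))), dtype=np.intp)
    # permuting y by pi gives slope = sum_i c_i y_pi(i) = sum_j c_{pi^-1(j)} y_j
    inv = np.empty_like(perms)
    rows = np.arange(perms.shape[0])[:, None]
    inv[rows, perms] = np.arange(perms.shape[1])[None, :]
    return c[inv]


def permutation_slope_p(x, y, n_perm: int = DEFAULT_N_PERM,
                        rng: np.random.Generator | None = None) -> float:
    """One-sided permutation p that the regression slope is zero.

    Tests deterioration: p = (1 + #{permuted slopes <= observed}) /
    (1 + #permutations).  All n! orderings are enumerated when n! <=
    max(n_perm, 7!); otherwise ``n_perm`` random shuffles are drawn from
    ``rng``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 points")
    obs, _ = _ols(x, y)
    if n <= EXHAUSTIVE_MAX_N:
        coef = _exhaustive_coef_matrix(tuple(x))
        slopes = coef @ y
        return float((1 + (slopes <= obs + 1e-12).sum()) / (1 + len(slopes)))
    if rng is None:
        rng = np.random.default_rng()
    c = (x - x.mean()) / ((x - x.mean()) ** 2).sum()
    # argsort of uniforms = uniform random permutations, all at once
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    slopes = y[order] @ c
    return float((1 + (slopes <= obs + 1e-12).sum()) / (1 + n_perm))


def slope_t_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided p for the regression-slope t statistic."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        return 1.0
    res = stats.linregress(x, y)
    return 1.0 if math.isnan(res.pvalue) else float(res.pvalue)


def fit_slope(x, y, n_perm: int = DEFAULT_N_PERM,
              rng: np.random.Generator | None = None,
              outlier_removal: bool = True) -> SlopeFit:
    """Outlier-removed OLS slope with t-test and permutation p-values.

    The permutation test is run on the outlier-removed points (over their
    own visit times).  Constant series get p_t = p_perm = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = remove_outliers(x, y) if outlier_removal else np.arange(len(y))
    xk, yk = x[keep], y[keep]
    slope, intercept = _ols(xk, yk)
    if np.ptp(yk) == 0.0:
        p_t = p_perm = 1.0
    else:
        p_t = slope_t_p(xk, yk)
        p_perm = permutation_slope_p(xk, yk, n_perm=n_perm, rng=rng)
    out = tuple(sorted(set(range(len(y))) - set(keep.tolist())))
    return SlopeFit(slope=slope, intercept=intercept, p_t=p_t, p_perm=p_perm,
                    n_used=len(keep), outlier_indices=out)
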
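"""Gradient models and the near-/off-trail rank test.

Community C is modelled against stand basal area with a logarithmic model
(y = a + b·ln x), community S against elevation with a cubic polynomial,
and stand structure against elevation with linear or quadratic models.
Fit quality is the explained-variance pseudo-R² = 1 − SS_res/SS_tot on
the response scale, with a p-value from the F test of the fitted model
against the intercept-only model. Near- vs off-trail R scores are
compared with a two-sided Wilcoxon–Mann–Whitney test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

FAMILIES = {"linear": 2, "poly2": 3, "poly3": 4, "log_x": 2}


@dataclass(frozen=True)
class GradientFit:
    family: str
    coefficients: tuple[float, ...]  # ascending order: intercept first
    pseudo_r2: float
    p_value: float
    n: int


def _design(x: np.ndarray, family: str) -> np.ndarray:
    if family == "linear":
        cols = [np.ones_like(x), x]
    elif family == "poly2":
        cols = [np.ones_like(x), x, x ** 2]
    elif family == "poly3":
        cols = [np.ones_like(x), x, x ** 2, x ** 3]
    elif family == "log_x":
        if np.any(x <= 0):
            raise ValueError("log_x family requires all x > 0")
        cols = [np.ones_like(x), np.log(x)]
    else:
        raise ValueError(f"unknown family {family!r}; choose from {sorted(FAMILIES)}")
    return np.column_stack(cols)


def fit_gradient(x, y, family: str) -> GradientFit:
    """Least-squares fit of y on the design implied by ``family``.

    Coefficients are returned in ascending order (intercept first; for
    log_x the pair (a, b) of y = a + b·ln x).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    k = FAMILIES.get(family)
    if k is None:
        raise ValueError(f"unknown family {family!r}; choose from {sorted(FAMILIES)}")
    n = x.size
    if n <= k:
        raise ValueError(f"need more than {k} points for family {family}")
    X = _design(x, family)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    # a numerically constant response: SS_tot at rounding-noise level
    const_floor = 100 * n * (np.finfo(float).eps * max(1.0, abs(float(y.mean())))) ** 2
    if ss_tot <= const_floor:
        pseudo_r2 = 0.0
        p = 1.0
    else:
        pseudo_r2 = 1.0 - ss_res / ss_tot
        df_model = k - 1
        df_resid = n - k
        if ss_res <= 0:
            p = 0.0
        else:
            f = ((ss_tot - ss_res) / df_model) / (ss_res / df_resid)
            p = float(stats.f.sf(f, df_model, df_resid))
    return GradientFit(family, tuple(float(b) for b in beta), pseudo_r2, p, n)


@dataclass(frozen=True)
class RankTestResult:
    statistic: float  # Mann–Whitney U of group 1
    p_value: float  # two-sided
    method: str  # 'exact' | 'normal_approx'


def rank_test(group1, group2) -> RankTestResult:
    """Two-sided Wilcoxon–Mann–Whitney test.

    Exact enumeration when n1 + n2 ≤ 12 and there are no ties; otherwise
    the normal approximation with tie and continuity corrections.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([g1, g2])
    has_ties = np.unique(pooled).size < pooled.size
    if g1.size + g2.size <= 12 and not has_ties:
        method = "exact"
        res = stats.mannwhitneyu(g1, g2, alternative="two-sided", method="exact")
    else:
        method = "normal_approx"
        res = stats.mannwhitneyu(g1, g2, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
    return RankTestResult(float(res.statistic), float(res.pvalue), method)
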
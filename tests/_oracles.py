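"""Naive brute-force reference implementations used only as test oracles.

Deliberately written as plain triple loops / textbook formulas,
independent of the vectorised library code they check.
"""

import math

import numpy as np
from scipy.stats import t as t_dist


def count_below_pct(values: np.ndarray, mask: np.ndarray, threshold: float) -> float:
    """Triple-loop strict-threshold percentage within a boolean mask."""
    n_below = 0
    n_total = 0
    nx, ny, nz = values.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if mask[i, j, k]:
                    n_total += 1
                    if values[i, j, k] < threshold:
                        n_below += 1
    return 100.0 * n_below / n_total


def pearson_r(x, y) -> float:
    """Textbook product-moment formula."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    sxx = sum((xi - mx) ** 2 for xi in x)
    syy = sum((yi - my) ** 2 for yi in y)
    return sxy / math.sqrt(sxx * syy)


def pearson_p_two_sided(r: float, n: int) -> float:
    """t-transform p-value for H0: rho = 0."""
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    return 2.0 * t_dist.sf(abs(t), df=n - 2)


def fisher_ci(r: float, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Fisher z confidence interval for the correlation."""
    from scipy.stats import norm

    z = math.atanh(r)
    se = 1.0 / math.sqrt(n - 3)
    crit = norm.ppf(0.5 + confidence / 2.0)
    return math.tanh(z - crit * se), math.tanh(z + crit * se)


def ols(x, y) -> tuple[float, float, float, float]:
    """Normal-equation OLS: (slope, intercept, slope_se, p_slope)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((xi - mx) ** 2 for xi in x)
    sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    slope = sxy / sxx
    intercept = my - slope * mx
    ss_res = sum((yi - (intercept + slope * xi)) ** 2 for xi, yi in zip(x, y))
    if n > 2 and ss_res > 0:
        se = math.sqrt(ss_res / (n - 2) / sxx)
        t = slope / se
        p = 2.0 * t_dist.sf(abs(t), df=n - 2)
    else:
        se, p = 0.0, 0.0
    return slope, intercept, se, p
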
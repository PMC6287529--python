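"""Ordinary least-squares line fitting with exact closed-form slope inference.

This is the statistical engine of the linear hook detector: it fits
``y = b0 + b1*x + eps`` and reports the slope's standard error, a
one-sided lower-tail p-value (evidence of a *negative* slope) and the
symmetric two-sided confidence interval at level 1 - alpha.  With the
default ``alpha = 0.0025`` the interval spans the 0.125% and 99.875%
quantiles, i.e. a 99.75% CI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["LinearTailFit", "ols_line", "DegenerateDesignError"]


class DegenerateDesignError(ValueError):
    """All x values identical: the slope is not identifiable."""


# Residual variance below this fraction of the response scale is treated as an
# exact line; a slope smaller than _SLOPE_TOL times the response scale is then
# treated as zero rather than as sign evidence, so float noise on a constant
# series cannot masquerade as a perfect negative line.
_ZERO_RSS_REL = 1e-24
_SLOPE_TOL = 1e-12


@dataclass(frozen=True)
class LinearTailFit:
    """OLS estimates and slope inference for one fitted segment.

    ``p_one_sided`` is P(T <= t) for t = slope/se with df = n_points - 2:
    small values are evidence that the true slope is negative.  For
    n_points = 2 (zero degrees of freedom) the slope is exact but se, p
    and CI are NaN (undefined).
    """

    intercept: float
    slope: float
    slope_se: float
    p_one_sided: float
    ci_low: float
    ci_high: float
    n_points: int
    start_cycle: float
    alpha: float

    @property
    def defined(self) -> bool:
        """True when se/p/CI exist (df >= 1)."""
        return not np.isnan(self.p_one_sided)


def ols_line(x, y, alpha: float = 0.0025) -> LinearTailFit:
    """Fit a straight line by ordinary least squares and test the slope.

    Parameters
    ----------
    x, y : array-like, equal length m >= 2
        Predictor (cycles) and response (fluorescence).
    alpha : float in (0, 1)
        Two-sided CI level is 1 - alpha; default 0.0025 gives the 99.75%
        interval with bounds at the 0.125% and 99.875% quantiles.

    Notes
    -----
    Zero-residual data (a perfect line) has se = 0; by convention the
    p-value is then 0 for a genuinely negative slope and 1 otherwise, and
    the CI collapses to [slope, slope].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    m = x.size
    if m < 2:
        raise ValueError("need at least two points")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")

    xbar = x.mean()
    ybar = y.mean()
    dx = x - xbar
    sxx = float(dx @ dx)
    if sxx == 0.0:
        raise DegenerateDesignError("all x values identical")
    slope = float(dx @ (y - ybar)) / sxx
    intercept = ybar - slope * xbar

    resid = y - (intercept + slope * x)
    rss = float(resid @ resid)
    df = m - 2

    if df == 0:
        nan = float("nan")
        return LinearTailFit(intercept, slope, nan, nan, nan, nan, m, float(x[0]), alpha)

    y_scale = max(1.0, float(np.mean(y * y)))
    if rss <= _ZERO_RSS_REL * y_scale * m:
        # perfect line: maximal evidence if the slope is truly negative
        negative = slope < -_SLOPE_TOL * max(1.0, abs(ybar))
        p = 0.0 if negative else 1.0
        return LinearTailFit(intercept, slope, 0.0, p, slope, slope, m, float(x[0]), alpha)

    sigma2 = rss / df
    se = float(np.sqrt(sigma2 / sxx))
    t_stat = slope / se
    p = float(stats.t.cdf(t_stat, df))
    half = float(stats.t.ppf(1.0 - alpha / 2.0, df)) * se
    return LinearTailFit(intercept, slope, se, p, slope - half, slope + half,
                         m, float(x[0]), alpha)
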
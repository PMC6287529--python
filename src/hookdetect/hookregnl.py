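"""Nonlinear hook detector based on a six-parameter log-logistic model.

The model

    y = c + k*x + (d - c) / (1 + exp(b*(log x - log e)))**f

describes a qPCR amplification curve with baseline ``c``, plateau ``d``,
sigmoidal slope ``b`` (negative for a rising curve), inflection location
``e`` (exact when the asymmetry ``f`` equals 1) and a linear drift ``k``
superimposed over the whole run.  A negative ``k`` captures the
cycle-to-cycle fluorescence loss of a hook effect; the detector fits the
model after trimming the first baseline cycles and calls a hook when the
99.75% confidence interval of k lies entirely below zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .calls import (HookCall, STATUS_FIT_FAILED, STATUS_INSUFFICIENT_TAIL,
                    STATUS_NEGATIVE_REACTION, STATUS_OK)
from .curve import AmplificationCurve
from .hookreg import (DEFAULT_SNR_MIN, DegenerateCurveError, is_negative_reaction,
                      normalize_curve)

__all__ = ["SigmoidFit", "l6_model", "fit_l6", "hookregnl_call",
           "InsufficientDataError"]

METHOD = "hookregNL"

DEFAULT_TRIM = 5
DEFAULT_ALPHA = 0.0025
_N_PARAMS = 6
_MAX_NFEV = 1000

# Floor on the residual sd (relative to the fluorescence scale) entering the
# covariance: a numerically perfect fit would otherwise shrink the CI of k to
# the optimizer's round-off, turning machine noise into a sign-definite slope.
_SIGMA_FLOOR_REL = 1e-8


class InsufficientDataError(ValueError):
    """Fewer points than the six-parameter fit can support."""


@dataclass(frozen=True)
class SigmoidFit:
    """Estimates of the six log-logistic parameters with inference on k.

    ``k_se`` is the Jacobian-based asymptotic standard error;
    ``k_ci_low``/``k_ci_high`` bound the (1 - alpha) CI using the
    t-distribution with m - 6 degrees of freedom.  ``converged`` is False
    when the optimizer failed or the covariance was singular, in which
    case the CI bounds are NaN.
    """

    b: float
    c: float
    d: float
    e: float
    f: float
    k: float
    k_se: float
    k_ci_low: float
    k_ci_high: float
    converged: bool
    rss: float
    n_points: int
    alpha: float


def l6_model(x, b, c, d, e, f, k):
    """Evaluate the six-parameter log-logistic model at cycles ``x``.

    Requires x > 0, e > 0, f > 0 (the sigmoid lives on log-cycle scale).
    Computed via a softplus so extreme ``b`` cannot overflow.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("cycles must be positive (log-logistic model)")
    if e <= 0 or f <= 0:
        raise ValueError("parameters e and f must be positive")
    z = b * (np.log(x) - np.log(e))
    # (1 + exp(z))**(-f) == exp(-f * softplus(z)), stable for any z
    sig = np.exp(-f * np.logaddexp(0.0, z))
    return c + k * x + (d - c) * sig


def _initial_guesses(x: np.ndarray, y: np.ndarray):
    c0 = float(y.min())
    d0 = float(y.max())
    gains = np.diff(y)
    e0 = float(x[int(np.argmax(gains)) + 1]) if gains.size else float(x[x.size // 2])
    e0 = min(max(e0, float(x[0])), float(x[-1]))
    for b0 in (-10.0, -5.0, -20.0):
        yield np.array([b0, c0, d0, e0, 1.0, 0.0])


def fit_l6(curve: AmplificationCurve, trim: int = DEFAULT_TRIM,
           alpha: float = DEFAULT_ALPHA, normalize: bool = True) -> SigmoidFit:
    """Fit the six-parameter model to a curve by trust-region least squares.

    The first ``trim`` cycles are removed before fitting to keep a
    sloping baseline from leaking into the drift term k.  The curve is
    normalized (99th-percentile scaling, as in the linear detector) so
    that k is in comparable units across wells; pass ``normalize=False``
    for data already on a common scale.

    Raises :class:`InsufficientDataError` when fewer than 12 points
    remain after trimming (six parameters need at least six residual
    degrees of freedom).
    """
    if normalize:
        curve = normalize_curve(curve)
    x = np.asarray(curve.cycles[trim:], dtype=float)
    y = np.asarray(curve.fluorescence[trim:], dtype=float)
    m = x.size
    if m < 2 * _N_PARAMS:
        raise InsufficientDataError(
            f"curve {curve.well_id!r}: {m} points after trimming {trim}; need >= {2 * _N_PARAMS}")
    if np.any(x <= 0):
        raise ValueError("cycles must be positive")

    lower = np.array([-np.inf, -np.inf, -np.inf, float(x[0]), 1e-3, -np.inf])
    upper = np.array([np.inf, np.inf, np.inf, float(x[-1]), 1e3, np.inf])

    def resid(theta):
        b, c, d, e, f, k = theta
        return l6_model(x, b, c, d, e, f, k) - y

    best = None
    for theta0 in _initial_guesses(x, y):
        theta0[3] = min(max(theta0[3], lower[3]), upper[3])
        try:
            res = optimize.least_squares(resid, theta0, bounds=(lower, upper),
                                         method="trf", max_nfev=_MAX_NFEV,
                                         ftol=1e-10, xtol=1e-10, gtol=1e-10)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
        if res.success and res.cost < 1e-12 * max(1.0, float(y @ y)):
            break  # essentially exact fit; no need for restarts

    nan = float("nan")
    if best is None or not best.success or not np.all(np.isfinite(best.x)):
        return SigmoidFit(nan, nan, nan, nan, nan, nan, nan, nan, nan,
                          converged=False, rss=nan, n_points=m, alpha=alpha)

    b, c, d, e, f, k = (float(v) for v in best.x)
    rss = float(2.0 * best.cost)
    df = m - _N_PARAMS

    jac = best.jac
    jtj = jac.T @ jac
    try:
        cov_unscaled = np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        return SigmoidFit(b, c, d, e, f, k, nan, nan, nan,
                          converged=False, rss=rss, n_points=m, alpha=alpha)
    scale = max(1.0, float(np.max(np.abs(y))))
    sigma = max(np.sqrt(rss / df), _SIGMA_FLOOR_REL * scale)
    k_se = float(sigma * np.sqrt(cov_unscaled[5, 5]))
    if not np.isfinite(k_se):
        return SigmoidFit(b, c, d, e, f, k, nan, nan, nan,
                          converged=False, rss=rss, n_points=m, alpha=alpha)
    half = float(stats.t.ppf(1.0 - alpha / 2.0, df)) * k_se
    return SigmoidFit(b, c, d, e, f, k, k_se, k - half, k + half,
                      converged=True, rss=rss, n_points=m, alpha=alpha)


def hookregnl_call(curve: AmplificationCurve, trim: int = DEFAULT_TRIM,
                   alpha: float = DEFAULT_ALPHA,
                   snr_min: float = DEFAULT_SNR_MIN) -> HookCall:
    """Run the nonlinear hook detector on one curve.

    Negative reactions are gated out exactly as in the linear detector;
    otherwise the six-parameter model is fitted and a hook is called iff
    the fit converged and both CI bounds of the drift k are negative.
    Non-convergence maps to ``status = fit_failed`` (never an exception:
    plate-scale batch runs must not abort on one bad well).
    """
    if is_negative_reaction(curve, snr_min=snr_min):
        return HookCall(METHOD, curve.well_id, hook=False, status=STATUS_NEGATIVE_REACTION)
    try:
        fit = fit_l6(curve, trim=trim, alpha=alpha)
    except InsufficientDataError:
        return HookCall(METHOD, curve.well_id, hook=False, status=STATUS_INSUFFICIENT_TAIL)
    except DegenerateCurveError:
        return HookCall(METHOD, curve.well_id, hook=False, status=STATUS_NEGATIVE_REACTION)
    if not fit.converged:
        return HookCall(METHOD, curve.well_id, hook=False, status=STATUS_FIT_FAILED)
    hook = bool(fit.k_ci_high < 0.0 and fit.k_ci_low < 0.0)
    return HookCall(METHOD, curve.well_id, hook=hook, status=STATUS_OK,
                    slope=fit.k, p_value=None, ci_low=fit.k_ci_low, ci_high=fit.k_ci_high)
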
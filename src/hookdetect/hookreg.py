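"""Linear hook detector.

Locates the fluorescence maximum, regresses the tail from that cycle to
the end of the run, and calls a hook effect when the tail slope is
significantly negative: one-sided p below ``alpha`` (default 0.0025,
i.e. the 99.75% confidence level) or the whole CI of the slope below
zero.  Negative (non-amplifying) reactions are discarded beforehand by a
signal-to-noise gate, and curves with fewer than ``min_tail`` cycles
after the maximum are reported as ``insufficient_tail`` rather than
scored — a late maximum leaves nothing to regress.
"""

from __future__ import annotations

import numpy as np

from .calls import (HookCall, STATUS_INSUFFICIENT_TAIL, STATUS_NEGATIVE_REACTION,
                    STATUS_OK)
from .curve import AmplificationCurve, CurveError
from .linfit import ols_line

__all__ = ["find_max_cycle", "normalize_curve", "is_negative_reaction",
           "hookreg_call", "DegenerateCurveError"]

METHOD = "hookreg"

#: defaults of the decision rule
DEFAULT_ALPHA = 0.0025
DEFAULT_MIN_TAIL = 5
DEFAULT_SNR_MIN = 10.0
_BASELINE_CYCLES = 10  # early-cycle window for the noise estimate


class DegenerateCurveError(CurveError):
    """Flat signal: the 99th percentile of the min-subtracted series is zero."""


def find_max_cycle(curve: AmplificationCurve) -> float:
    """Cycle at which fluorescence attains its maximum (earliest on ties)."""
    return float(curve.cycles[int(np.argmax(curve.fluorescence))])


def normalize_curve(curve: AmplificationCurve) -> AmplificationCurve:
    """Normalize fluorescence to the 99th percentile of the min-subtracted series.

    ``y' = (y - min y) / q99(y - min y)`` with the linear-interpolation
    percentile definition; the transform is a positive affine map, so the
    location of the maximum and all downstream decisions are unchanged.
    Raises :class:`DegenerateCurveError` on a flat signal (q99 = 0).
    """
    y = curve.fluorescence
    shifted = y - y.min()
    q99 = float(np.percentile(shifted, 99))
    if q99 <= 0.0:
        raise DegenerateCurveError(f"curve {curve.well_id!r}: flat signal, q99 = 0")
    return curve.with_fluorescence(shifted / q99)


def is_negative_reaction(curve: AmplificationCurve, snr_min: float = DEFAULT_SNR_MIN) -> bool:
    """True when the curve shows no amplification.

    The gate compares the total amplitude ``max(y) - min(y)`` with the
    noise of the first ten cycles (the ground phase): a ratio below
    ``snr_min`` means the signal never rose meaningfully above the
    baseline noise.  The noise estimate is the residual sd about a
    straight line through the early cycles, so a sloping baseline — the
    hallmark of a pronounced hook measured without baseline correction —
    does not masquerade as noise.  A zero-amplitude curve is negative by
    definition; zero baseline noise with positive amplitude is an
    infinite SNR, i.e. not negative.  Scale-free, so it can run on raw or
    normalized data.
    """
    y = curve.fluorescence
    amplitude = float(y.max() - y.min())
    if amplitude == 0.0:
        return True
    n_head = min(_BASELINE_CYCLES, y.size)
    head = y[:n_head]
    if n_head >= 3:
        x_head = curve.cycles[:n_head]
        coef = np.polyfit(x_head, head, 1)
        resid = head - np.polyval(coef, x_head)
        sd = float(np.sqrt(resid @ resid / (n_head - 2)))
    elif n_head == 2:
        sd = float(np.std(head, ddof=1))
    else:
        sd = 0.0
    if sd == 0.0:
        return False
    return amplitude / sd < snr_min


def hookreg_call(curve: AmplificationCurve, alpha: float = DEFAULT_ALPHA,
                 min_tail: int = DEFAULT_MIN_TAIL,
                 snr_min: float = DEFAULT_SNR_MIN) -> HookCall:
    """Run the linear hook detector on one curve.

    Pipeline: negative-reaction gate → 99th-percentile normalization →
    locate the maximum x0 → require at least ``min_tail`` cycles strictly
    after x0 → OLS on the tail (x0 included) → hook iff the one-sided p
    is below ``alpha`` or both CI bounds are negative.
    """
    if is_negative_reaction(curve, snr_min=snr_min):
        return HookCall(METHOD, curve.well_id, hook=False, status=STATUS_NEGATIVE_REACTION)
    try:
        norm = normalize_curve(curve)
    except DegenerateCurveError:
        return HookCall(METHOD, curve.well_id, hook=False, status=STATUS_NEGATIVE_REACTION)

    i_max = int(np.argmax(norm.fluorescence))
    x0 = float(norm.cycles[i_max])
    n_after = len(norm) - i_max - 1
    if n_after < min_tail:
        return HookCall(METHOD, curve.well_id, hook=False, status=STATUS_INSUFFICIENT_TAIL,
                        hook_start_cycle=x0)

    tail = norm.tail_from(i_max)
    fit = ols_line(tail.cycles, tail.fluorescence, alpha=alpha)
    if not fit.defined:
        return HookCall(METHOD, curve.well_id, hook=False, status=STATUS_INSUFFICIENT_TAIL,
                        hook_start_cycle=x0)
    hook = bool(fit.p_one_sided < alpha or (fit.ci_high < 0.0 and fit.ci_low < 0.0))
    return HookCall(METHOD, curve.well_id, hook=hook, status=STATUS_OK,
                    slope=fit.slope, p_value=fit.p_one_sided,
                    ci_low=fit.ci_low, ci_high=fit.ci_high, hook_start_cycle=x0)
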
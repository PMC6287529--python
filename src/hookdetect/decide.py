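"""Combine the linear and sigmoid detectors into the final classifier.

The two detectors complement each other: the linear one needs a long
enough tail after the maximum, the sigmoid one needs a fittable overall
shape.  Their union (logical OR of the hook decisions) is the package's
default classifier.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Sequence

from .calls import HookCall, STATUS_FIT_FAILED, STATUS_OK
from .curve import AmplificationCurve
from . import hookreg as _hr
from . import hookregnl as _nl

__all__ = ["combine_calls", "analyze_curve", "analyze_plate", "METHODS"]

METHOD = "combined"
METHODS = ("hookreg", "hookregNL", "combined")


def combine_calls(a: HookCall, b: HookCall) -> HookCall:
    """OR-combine a linear-detector call with a sigmoid-detector call.

    ``hook = a.hook or b.hook``; the status is ``ok`` as soon as either
    input is ok.  Both slope estimates are preserved in ``provenance``;
    the reported ``slope``/``p_value``/CI are those of the linear call
    when it is ok (it carries a p-value), else the sigmoid call's.
    """
    if a.well_id != b.well_id:
        raise ValueError(f"well_id mismatch: {a.well_id!r} vs {b.well_id!r}")
    hook = a.hook or b.hook
    if a.status == STATUS_OK or b.status == STATUS_OK:
        status = STATUS_OK
    else:
        status = a.status if a.status == b.status else STATUS_FIT_FAILED
    primary = a if a.status == STATUS_OK else b
    prov = {}
    if a.slope is not None:
        prov["hookreg_slope"] = a.slope
    if b.slope is not None:
        prov["hookregnl_slope"] = b.slope
    return HookCall(METHOD, a.well_id, hook=hook, status=status,
                    slope=primary.slope, p_value=a.p_value,
                    ci_low=primary.ci_low, ci_high=primary.ci_high,
                    hook_start_cycle=a.hook_start_cycle, provenance=prov)


def analyze_curve(curve: AmplificationCurve, method: str = "combined",
                  alpha: float = _hr.DEFAULT_ALPHA, min_tail: int = _hr.DEFAULT_MIN_TAIL,
                  trim: int = _nl.DEFAULT_TRIM,
                  snr_min: float = _hr.DEFAULT_SNR_MIN) -> HookCall:
    """Run the selected detector (``hookreg``, ``hookregNL`` or ``combined``)."""
    if method == "hookreg":
        return _hr.hookreg_call(curve, alpha=alpha, min_tail=min_tail, snr_min=snr_min)
    if method == "hookregNL":
        return _nl.hookregnl_call(curve, trim=trim, alpha=alpha, snr_min=snr_min)
    if method == "combined":
        a = _hr.hookreg_call(curve, alpha=alpha, min_tail=min_tail, snr_min=snr_min)
        b = _nl.hookregnl_call(curve, trim=trim, alpha=alpha, snr_min=snr_min)
        return combine_calls(a, b)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def analyze_plate(curves: Iterable[AmplificationCurve], method: str = "combined",
                  **params) -> List[HookCall]:
    """Apply :func:`analyze_curve` to every curve, sorted by well id."""
    ordered = sorted(curves, key=lambda c: c.well_id)
    return [analyze_curve(c, method=method, **params) for c in ordered]
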
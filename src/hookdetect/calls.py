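"""The per-curve decision record shared by all detectors."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

__all__ = ["HookCall", "STATUS_OK", "STATUS_INSUFFICIENT_TAIL",
           "STATUS_NEGATIVE_REACTION", "STATUS_FIT_FAILED"]

STATUS_OK = "ok"
STATUS_INSUFFICIENT_TAIL = "insufficient_tail"
STATUS_NEGATIVE_REACTION = "negative_reaction"
STATUS_FIT_FAILED = "fit_failed"

_STATUSES = {STATUS_OK, STATUS_INSUFFICIENT_TAIL, STATUS_NEGATIVE_REACTION, STATUS_FIT_FAILED}


@dataclass(frozen=True)
class HookCall:
    """One detector's boolean hook decision for one curve plus its evidence.

    Invariants: ``hook`` can only be True when ``status == "ok"``; any
    non-ok status forces ``hook = False``.  ``slope`` is the estimated
    tail slope (the OLS beta1 for the linear detector, the drift k for
    the sigmoid detector) in normalized RFU per cycle.  ``p_value`` is
    absent (None) for the sigmoid detector, which reports a CI only.
    """

    method: str
    well_id: str
    hook: bool
    status: str = STATUS_OK
    slope: Optional[float] = None
    p_value: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    hook_start_cycle: Optional[float] = None
    provenance: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.status not in _STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.hook and self.status != STATUS_OK:
            raise ValueError("hook=True requires status='ok'")
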
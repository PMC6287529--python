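"""Benchmarking of hook calls against human ratings.

Confusion counts with the hook class as positive, and the five derived
metrics commonly reported for binary curve classifiers: sensitivity,
specificity, false positive rate, false negative rate, accuracy.
Metrics are stored at full precision and rounded only for display.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .calls import HookCall
from .curve import HOOK, NO_HOOK

__all__ = ["PerformanceReport", "evaluate", "report_frame"]


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


@dataclass(frozen=True)
class PerformanceReport:
    """Confusion counts and derived metrics for one detector.

    Metrics with a zero denominator are ``None`` (undefined), never
    silently coerced to 0.
    """

    method: str
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def sensitivity(self) -> Optional[float]:
        return _ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> Optional[float]:
        return _ratio(self.tn, self.tn + self.fp)

    @property
    def fpr(self) -> Optional[float]:
        return _ratio(self.fp, self.fp + self.tn)

    @property
    def fnr(self) -> Optional[float]:
        return _ratio(self.fn, self.fn + self.tp)

    @property
    def accuracy(self) -> Optional[float]:
        return _ratio(self.tp + self.tn, self.n)

    def rounded(self, ndigits: int = 2) -> dict:
        """Display form: metrics rounded to ``ndigits`` decimals."""
        out = {"method": self.method, "tp": self.tp, "tn": self.tn,
               "fp": self.fp, "fn": self.fn}
        for name in ("sensitivity", "specificity", "fpr", "fnr", "accuracy"):
            v = getattr(self, name)
            out[name] = None if v is None else round(v, ndigits)
        return out


def evaluate(calls: Sequence[HookCall], labels: Mapping[str, str],
             method: Optional[str] = None) -> PerformanceReport:
    """Score calls against truth labels (positive class = hook).

    Every call's well must be labelled; missing wells raise with the
    full list so plate/label mismatches surface at once.
    """
    missing = sorted({c.well_id for c in calls} - set(labels))
    if missing:
        raise KeyError(f"no label for wells: {missing}")
    tp = tn = fp = fn = 0
    for call in calls:
        truth_hook = labels[call.well_id] == HOOK
        if call.hook and truth_hook:
            tp += 1
        elif call.hook and not truth_hook:
            fp += 1
        elif not call.hook and truth_hook:
            fn += 1
        else:
            tn += 1
    name = method or (calls[0].method if calls else "")
    return PerformanceReport(name, tp=tp, tn=tn, fp=fp, fn=fn)


def report_frame(reports: Iterable[PerformanceReport], ndigits: int = 2) -> pd.DataFrame:
    """One display-rounded row per method, ready for CSV output."""
    return pd.DataFrame([r.rounded(ndigits) for r in reports])
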
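"""Core data records for amplification-curve analysis.

An :class:`AmplificationCurve` holds one well's (cycle, fluorescence)
series — the universal input record of the package.  Fluorescence is kept
in the instrument's arbitrary units (RFU); the detectors normalize
internally and their decisions are invariant under positive affine
transforms of the readout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AmplificationCurve",
    "LabelledCurveSet",
    "CurveError",
    "HOOK",
    "NO_HOOK",
]

#: canonical label strings used throughout the package
HOOK = "hook"
NO_HOOK = "no_hook"


class CurveError(ValueError):
    """Invalid amplification-curve data."""


@dataclass(frozen=True)
class AmplificationCurve:
    """One well's qPCR amplification trace.

    Parameters
    ----------
    well_id : str
        Plate position label, e.g. ``"A01"``.
    cycles : array-like of int
        Strictly increasing PCR cycle indices (1-based in practice; used
        exactly as stored).
    fluorescence : array-like of float
        Cycle-dependent fluorescence readings in RFU; must be finite and
        of the same length as ``cycles``.
    sample_name, detector : str
        Optional identity metadata (sample and dye/probe chemistry).
    """

    well_id: str
    cycles: np.ndarray
    fluorescence: np.ndarray
    sample_name: str = ""
    detector: str = ""

    def __post_init__(self) -> None:
        cyc = np.asarray(self.cycles, dtype=float)
        flu = np.asarray(self.fluorescence, dtype=float)
        if cyc.ndim != 1 or flu.ndim != 1:
            raise CurveError(f"curve {self.well_id!r}: cycles and fluorescence must be 1-D")
        if cyc.size != flu.size:
            raise CurveError(
                f"curve {self.well_id!r}: {cyc.size} cycles vs {flu.size} fluorescence values"
            )
        if cyc.size < 1:
            raise CurveError(f"curve {self.well_id!r}: empty series")
        if not np.all(np.isfinite(cyc)) or not np.all(np.isfinite(flu)):
            raise CurveError(f"curve {self.well_id!r}: non-finite values")
        if np.any(np.diff(cyc) <= 0):
            raise CurveError(f"curve {self.well_id!r}: cycles must be strictly increasing")
        object.__setattr__(self, "cycles", cyc)
        object.__setattr__(self, "fluorescence", flu)
        self.cycles.setflags(write=False)
        self.fluorescence.setflags(write=False)

    def __len__(self) -> int:
        return int(self.cycles.size)

    def with_fluorescence(self, values: Iterable[float]) -> "AmplificationCurve":
        """Copy of this curve with the fluorescence series replaced."""
        return AmplificationCurve(
            well_id=self.well_id,
            cycles=np.array(self.cycles),
            fluorescence=np.asarray(list(values), dtype=float),
            sample_name=self.sample_name,
            detector=self.detector,
        )

    def tail_from(self, index: int) -> "AmplificationCurve":
        """Sub-curve from positional ``index`` (inclusive) to the end."""
        return AmplificationCurve(
            well_id=self.well_id,
            cycles=np.array(self.cycles[index:]),
            fluorescence=np.array(self.fluorescence[index:]),
            sample_name=self.sample_name,
            detector=self.detector,
        )


@dataclass
class LabelledCurveSet:
    """A set of curves together with per-well truth labels.

    ``labels`` maps ``well_id`` to :data:`HOOK` or :data:`NO_HOOK` — the
    curve-level human rating ("y"/"n") used for benchmarking.
    """

    curves: Sequence[AmplificationCurve]
    labels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        well_ids = [c.well_id for c in self.curves]
        counts = {w: well_ids.count(w) for w in self.labels}
        bad = [w for w, n in counts.items() if n != 1]
        if bad:
            raise CurveError(f"labels do not match exactly one curve each: {sorted(bad)}")
        bad_labels = {v for v in self.labels.values()} - {HOOK, NO_HOOK}
        if bad_labels:
            raise CurveError(f"unknown labels {sorted(bad_labels)}; expected {{hook, no_hook}}")

    def __len__(self) -> int:
        return len(self.curves)
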
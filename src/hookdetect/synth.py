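"""Synthetic qPCR amplification-curve generator.

Curves are drawn from the same six-parameter log-logistic surface the
nonlinear detector fits, plus homoscedastic Gaussian noise — the
simplest noise model consistent with instrument RFU traces.  Four shapes
cover the qualitative repertoire of a real plate: a clean ``sigmoid``
(no drift), a ``hook`` (negative linear drift over the plateau), a
``no_plateau`` curve still rising at the last cycle (late midpoint), and
a flat ``negative`` reaction (baseline plus noise only).  The benchmark
builder spans five classes by splitting hooks into slight and pronounced
drift, mirroring the mix of curvatures a QC tool must separate.
"""

from __future__ import annotations

import zipfile
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np

from .curve import HOOK, NO_HOOK, AmplificationCurve, LabelledCurveSet
from .hookregnl import l6_model

__all__ = ["CurveSpec", "generate", "generate_benchmark", "BENCHMARK_CLASSES",
           "write_rdml_fixture"]

SHAPES = ("sigmoid", "hook", "no_plateau", "negative")

#: the five benchmark classes and their drift ranges (normalized RFU/cycle)
BENCHMARK_CLASSES = ("sigmoid", "hook_slight", "hook_pronounced", "no_plateau", "negative")
_DRIFT_SLIGHT = (-0.008, -0.003)
_DRIFT_PRONOUNCED = (-0.02, -0.008)

# randomized-parameter ranges for the benchmark builder
_RANGES = {
    "baseline": (0.0, 0.2),
    "amplitude": (0.5, 3.0),
    "midpoint": (15.0, 30.0),
    "steepness": (-15.0, -5.0),
    "asymmetry": (0.5, 2.0),
}


@dataclass(frozen=True)
class CurveSpec:
    """Parameters of one synthetic curve.

    ``baseline`` is the lower asymptote c, ``amplitude`` the rise d - c,
    ``midpoint`` the inflection location e (cycles), ``steepness`` the
    sigmoidal slope b (negative: rising curve), ``asymmetry`` the
    exponent f, ``drift`` the per-cycle linear term k (negative for hook
    shapes).  ``noise_sd`` is the Gaussian noise scale in the same RFU
    units as the amplitude.
    """

    shape: str = "sigmoid"
    n_cycles: int = 45
    baseline: float = 0.05
    amplitude: float = 1.0
    midpoint: float = 22.0
    steepness: float = -10.0
    asymmetry: float = 1.0
    drift: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    well_id: str = "S01"

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}; expected one of {SHAPES}")
        if self.shape == "hook" and not self.drift < 0:
            raise ValueError("hook shape requires negative drift")
        if self.shape == "negative" and self.amplitude != 0:
            raise ValueError("negative shape requires zero amplitude")
        if self.n_cycles < 1 or self.noise_sd < 0:
            raise ValueError("invalid n_cycles or noise_sd")


def generate(spec: CurveSpec) -> Tuple[AmplificationCurve, str]:
    """Generate one curve and its truth label, deterministic under the seed.

    The label is ``hook`` exactly when the spec is a hook shape (negative
    drift); all other shapes are ``no_hook``.
    """
    rng = np.random.default_rng(spec.seed)
    x = np.arange(1, spec.n_cycles + 1, dtype=float)
    if spec.shape == "negative":
        clean = np.full_like(x, spec.baseline)
    else:
        e = spec.midpoint
        if spec.shape == "no_plateau":
            e = max(e, 0.95 * spec.n_cycles)
        clean = l6_model(x, spec.steepness, spec.baseline,
                         spec.baseline + spec.amplitude, e, spec.asymmetry,
                         spec.drift)
    y = clean + rng.normal(0.0, spec.noise_sd, size=x.size) if spec.noise_sd > 0 else clean
    curve = AmplificationCurve(well_id=spec.well_id, cycles=x, fluorescence=y,
                               sample_name=spec.shape)
    label = HOOK if (spec.shape == "hook" and spec.drift < 0) else NO_HOOK
    return curve, label


def _class_spec(cls: str, rng: np.random.Generator, n_cycles: int,
                noise_sd: float, well_id: str,
                min_abs_drift: float = 0.003) -> CurveSpec:
    u = lambda lo_hi: float(rng.uniform(*lo_hi))
    base = dict(
        n_cycles=n_cycles, noise_sd=noise_sd, well_id=well_id,
        seed=int(rng.integers(0, 2**31 - 1)),
        baseline=u(_RANGES["baseline"]), amplitude=u(_RANGES["amplitude"]),
        midpoint=u(_RANGES["midpoint"]), steepness=u(_RANGES["steepness"]),
        asymmetry=u(_RANGES["asymmetry"]),
    )
    if cls == "sigmoid":
        return CurveSpec(shape="sigmoid", drift=0.0, **base)
    if cls == "hook_slight":
        hi = -max(min_abs_drift, -_DRIFT_SLIGHT[1])
        return CurveSpec(shape="hook", drift=u((_DRIFT_SLIGHT[0], hi)), **base)
    if cls == "hook_pronounced":
        return CurveSpec(shape="hook", drift=u(_DRIFT_PRONOUNCED), **base)
    if cls == "no_plateau":
        return CurveSpec(shape="no_plateau", drift=0.0, **base)
    if cls == "negative":
        base["amplitude"] = 0.0
        return CurveSpec(shape="negative", drift=0.0, **base)
    raise ValueError(f"unknown benchmark class {cls!r}")


def generate_benchmark(n_per_class: int, seed: int = 0, noise_sd: float = 0.005,
                       n_cycles: int = 45,
                       min_abs_drift: float = 0.003) -> LabelledCurveSet:
    """Balanced labelled benchmark over the five curve classes.

    ``n_per_class`` curves per class with parameters randomized within
    the documented ranges; two of the five classes are hooks (slight and
    pronounced drift), so the hook prevalence is 40%.  ``min_abs_drift``
    floors the slight-hook drift magnitude, defining how subtle the
    hardest true hooks are allowed to be.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    curves: List[AmplificationCurve] = []
    labels: Dict[str, str] = {}
    i = 0
    for cls in BENCHMARK_CLASSES:
        for _ in range(n_per_class):
            i += 1
            well = f"C{i:03d}"
            spec = _class_spec(cls, rng, n_cycles, noise_sd, well,
                               min_abs_drift=min_abs_drift)
            curve, label = generate(spec)
            curves.append(curve)
            labels[well] = label
    return LabelledCurveSet(curves=curves, labels=labels)


_RDML_NS = "http://www.rdml.org"


def write_rdml_fixture(curves, path, zipped: bool = True) -> None:
    """Write a minimal RDML file (one run, one react per curve).

    A deliberately small writer used for io round-trip tests and demo
    data; it emits only the elements the reader needs (run/react/data/
    adp with cyc and fluor) under the RDML namespace.  Not a complete
    RDML exporter.
    """
    path = Path(path)
    lines = [f'<rdml xmlns="{_RDML_NS}" version="1.2">', "<experiment id=\"exp1\"><run id=\"run1\">",
             "<pcrFormat><rows>8</rows><columns>12</columns></pcrFormat>"]
    for i, curve in enumerate(curves, start=1):
        lines.append(f'<react id="{i}">')
        if curve.sample_name:
            lines.append(f'<sample id="{curve.sample_name}"/>')
        lines.append("<data>")
        if curve.detector:
            lines.append(f'<tar id="{curve.detector}"/>')
        for cyc, fluor in zip(curve.cycles, curve.fluorescence):
            c = int(cyc) if float(cyc).is_integer() else float(cyc)
            lines.append(f"<adp><cyc>{c}</cyc><fluor>{float(fluor)!r}</fluor></adp>")
        lines.append("</data></react>")
    lines.append("</run></experiment></rdml>")
    xml = "\n".join(lines).encode()
    if zipped:
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            zf.writestr("data.rdml", xml)
    else:
        path.write_bytes(xml)
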
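"""Readers and writers for qPCR plate data.

Supports RDML (Real-time PCR Data Markup Language: an XML document,
usually inside a ZIP archive) for instrument exports, and plain CSV
tables with one cycle column plus one fluorescence column per well.
Truth labels for benchmarking are read from two-column CSV
(``well_id,label`` with labels ``y``/``n``).

The RDML reader is deliberately version-tolerant: it matches elements by
local name (``react``, ``data``, ``adp``, ``cyc``, ``fluor``) so that the
v1.1 and v1.2 namespace URIs, or files with no namespace at all, parse
identically.
"""

from __future__ import annotations

import io as _io
import logging
import warnings
import zipfile
from pathlib import Path
from typing import Dict, List, Sequence
from xml.etree import ElementTree

import numpy as np
import pandas as pd

from .curve import HOOK, NO_HOOK, AmplificationCurve

__all__ = [
    "read_rdml",
    "read_csv_plate",
    "write_csv_plate",
    "read_labels",
    "write_labels",
    "RdmlFormatError",
    "RdmlEmptyError",
    "PlateFormatError",
]

log = logging.getLogger(__name__)


class RdmlFormatError(ValueError):
    """The file is neither a ZIP archive containing XML nor a bare XML document."""


class RdmlEmptyError(ValueError):
    """Valid RDML, but no run/react elements with amplification data."""


class PlateFormatError(ValueError):
    """Malformed CSV plate or label table."""


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _find_local(elem: ElementTree.Element, name: str):
    for child in elem:
        if _localname(child.tag) == name:
            yield child


def _iter_local(root: ElementTree.Element, name: str):
    for elem in root.iter():
        if _localname(elem.tag) == name:
            yield elem


def _load_rdml_xml(path: Path) -> ElementTree.Element:
    raw = path.read_bytes()
    if zipfile.is_zipfile(_io.BytesIO(raw)):
        with zipfile.ZipFile(_io.BytesIO(raw)) as zf:
            names = [n for n in zf.namelist() if n.lower().endswith(".rdml") or n.lower().endswith(".xml")]
            if not names:
                raise RdmlFormatError(f"{path}: ZIP archive contains no RDML/XML member")
            raw = zf.read(names[0])
    try:
        return ElementTree.fromstring(raw)
    except ElementTree.ParseError as exc:
        raise RdmlFormatError(f"{path}: not a ZIP archive and not parseable XML ({exc})") from exc


def _well_id_from_react(react_id: str, n_columns: int) -> str:
    """Map a numeric react identifier to a plate coordinate like ``A01``.

    RDML stores the reaction position as an integer counted row-major over
    the plate.  Non-numeric identifiers are used verbatim.
    """
    if not react_id.isdigit():
        return react_id
    idx = int(react_id) - 1
    row, col = divmod(idx, n_columns)
    if 0 <= row < 26:
        return f"{chr(ord('A') + row)}{col + 1:02d}"
    return react_id


def _plate_columns(run: ElementTree.Element) -> int:
    for fmt in _find_local(run, "pcrFormat"):
        for cols in _find_local(fmt, "columns"):
            try:
                n = int(cols.text.strip())
            except (TypeError, ValueError):
                continue
            if n > 0:
                return n
    return 12  # 96-well default


def read_rdml(path) -> List[AmplificationCurve]:
    """Read amplification curves from an RDML file.

    Returns one :class:`AmplificationCurve` per reaction ("react") per
    target, ordered by cycle.  When a react carries several targets the
    well id is suffixed with the target name (hook detection is
    per-trace).  Reacts without amplification data points are skipped
    with a warning.

    Raises
    ------
    RdmlFormatError
        If the file is neither zipped nor bare RDML XML.
    RdmlEmptyError
        If the document parses but holds no run/react elements.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    root = _load_rdml_xml(path)

    curves: List[AmplificationCurve] = []
    saw_react = False
    for run in _iter_local(root, "run"):
        n_columns = _plate_columns(run)
        for react in _find_local(run, "react"):
            saw_react = True
            react_id = react.get("id", "")
            sample = ""
            for s in _find_local(react, "sample"):
                sample = s.get("id", "") or (s.text or "").strip()
            data_elems = list(_find_local(react, "data"))
            base_well = _well_id_from_react(react_id, n_columns)
            for data in data_elems:
                target = ""
                for tar in _find_local(data, "tar"):
                    target = tar.get("id", "") or (tar.text or "").strip()
                points = []
                for adp in _find_local(data, "adp"):
                    cyc = fluor = None
                    for child in adp:
                        name = _localname(child.tag)
                        if name == "cyc":
                            cyc = float(child.text)
                        elif name == "fluor":
                            fluor = float(child.text)
                    if cyc is not None and fluor is not None:
                        points.append((cyc, fluor))
                if not points:
                    log.warning("react %s target %s: no amplification data points, skipped",
                                react_id, target or "-")
                    continue
                points.sort(key=lambda p: p[0])
                cycles = np.array([p[0] for p in points])
                fluor_arr = np.array([p[1] for p in points])
                well = base_well if len(data_elems) == 1 else f"{base_well}_{target or 'tar'}"
                curves.append(AmplificationCurve(
                    well_id=well, cycles=cycles, fluorescence=fluor_arr,
                    sample_name=sample, detector=target))
    if not saw_react:
        raise RdmlEmptyError(f"{path}: RDML document contains no run/react elements")
    return curves


def read_csv_plate(path, cycle_column: str | None = None) -> List[AmplificationCurve]:
    """Read a wide CSV plate: one cycle column, one fluorescence column per well.

    ``cycle_column`` defaults to the first column.  Missing cells at a
    column's tail are trimmed; interior missing cells are an error.
    """
    path = Path(path)
    with open(path, "r", newline="") as fh:
        header = fh.readline().strip()
    names = [h.strip() for h in header.split(",")]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise PlateFormatError(f"{path}: duplicate column headers {sorted(dupes)}")

    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if cycle_column is None:
        cycle_column = df.columns[0]
    if cycle_column not in df.columns:
        raise PlateFormatError(f"{path}: no cycle column {cycle_column!r}")

    def numeric(col: str) -> np.ndarray:
        vals = []
        for row_i, cell in enumerate(df[col]):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
                vals.append(np.nan)
                continue
            try:
                vals.append(float(cell))
            except ValueError:
                raise PlateFormatError(
                    f"{path}: non-numeric cell at row {row_i + 2}, column {col!r}: {cell!r}"
                ) from None
        return np.array(vals)

    cycles = numeric(cycle_column)
    if np.any(np.isnan(cycles)):
        raise PlateFormatError(f"{path}: missing values in cycle column {cycle_column!r}")

    well_cols = [c for c in df.columns if c != cycle_column]
    if not well_cols:
        warnings.warn(f"{path}: plate has a cycle column but no well columns", stacklevel=2)
        return []

    curves = []
    for col in well_cols:
        y = numeric(col)
        valid = ~np.isnan(y)
        if not valid.any():
            warnings.warn(f"{path}: column {col!r} is entirely empty, skipped", stacklevel=2)
            continue
        last = int(np.max(np.nonzero(valid)[0]))
        if np.any(np.isnan(y[: last + 1])):
            bad = int(np.nonzero(np.isnan(y[: last + 1]))[0][0])
            raise PlateFormatError(
                f"{path}: interior missing cell at row {bad + 2}, column {col!r}"
            )
        curves.append(AmplificationCurve(
            well_id=col, cycles=np.array(cycles[: last + 1]), fluorescence=y[: last + 1]))
    return curves


def write_csv_plate(curves: Sequence[AmplificationCurve], path, cycle_column: str = "cyc") -> None:
    """Write curves as a wide CSV plate readable by :func:`read_csv_plate`.

    Values are written with ``repr`` precision so a write/read round trip
    reproduces every float exactly.
    """
    path = Path(path)
    grids = [tuple(c.cycles.tolist()) for c in curves]
    max_len = max((len(g) for g in grids), default=0)
    longest = max(grids, key=len, default=())
    for g in grids:
        if g != longest[: len(g)]:
            raise PlateFormatError("curves must share a common leading cycle grid")
    with open(path, "w", newline="") as fh:
        fh.write(",".join([cycle_column] + [c.well_id for c in curves]) + "\n")
        for i in range(max_len):
            row = [repr(longest[i])]
            for c in curves:
                row.append(repr(float(c.fluorescence[i])) if i < len(c) else "")
            fh.write(",".join(row) + "\n")


_LABEL_MAP = {"y": HOOK, "n": NO_HOOK}


def read_labels(path) -> Dict[str, str]:
    """Read per-well hook ratings: CSV rows ``well_id,label`` with label y/n.

    A header row ``well_id,label`` (any capitalisation) is tolerated.
    Labels are normalised to ``hook`` / ``no_hook``.
    """
    path = Path(path)
    labels: Dict[str, str] = {}
    with open(path, "r", newline="") as fh:
        for row_i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) < 2:
                raise PlateFormatError(f"{path}: row {row_i} has no label column: {line!r}")
            well, raw = parts[0], parts[1].lower()
            if row_i == 1 and raw in ("label", "rating", "hook"):
                continue  # header row
            if raw not in _LABEL_MAP:
                raise PlateFormatError(
                    f"{path}: row {row_i}: label {parts[1]!r} for well {well!r} not in {{y, n}}"
                )
            labels[well] = _LABEL_MAP[raw]
    return labels


def write_labels(labels: Dict[str, str], path) -> None:
    """Write labels in the ``well_id,y/n`` form read by :func:`read_labels`."""
    inverse = {HOOK: "y", NO_HOOK: "n"}
    with open(path, "w", newline="") as fh:
        fh.write("well_id,label\n")
        for well in sorted(labels):
            fh.write(f"{well},{inverse[labels[well]]}\n")
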
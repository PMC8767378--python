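"""File formats: landmark JSON, wide landmark CSV, measurement CSV, config.

Landmark JSON schema (one file per subject-view)::

    {"subject_id": "...", "view": "frontal|lateral|basilar",
     "points": {"code": [x, y], ...},
     "confidence": {"code": c, ...}}        # optional

Writing is canonical (sorted keys, fixed float precision), so
``write(read(f))`` is byte-identical for valid files.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ParseError
from .landmarks import LandmarkSet, VIEWS, landmark_catalog
from .anthropometry import MeasurementTable

_VALID_CODES = {d.code for d in landmark_catalog(include_supplementary=True)}
_FLOAT_DIGITS = 4


def _canonical(ls: LandmarkSet) -> dict:
    doc = {
        "subject_id": ls.subject_id,
        "view": ls.view,
        "points": {c: [round(float(x), _FLOAT_DIGITS), round(float(y), _FLOAT_DIGITS)]
                   for c, (x, y) in sorted(ls.points.items())},
    }
    if ls.confidence:
        doc["confidence"] = {c: round(float(v), _FLOAT_DIGITS)
                             for c, v in sorted(ls.confidence.items())}
    return doc


def write_landmark_file(ls: LandmarkSet, path) -> None:
    """Write a landmark set as canonical JSON."""
    with open(path, "w") as fh:
        json.dump(_canonical(ls), fh, sort_keys=True, indent=1)
        fh.write("\n")


def read_landmark_file(path) -> LandmarkSet:
    """Read and validate a landmark JSON file.

    Schema violations raise :class:`ParseError` carrying the JSON path of the
    offending field.
    """
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise ParseError(f"invalid JSON: {e}") from e
    if not isinstance(doc, dict):
        raise ParseError("top level must be an object")
    for key in ("subject_id", "view", "points"):
        if key not in doc:
            raise ParseError("missing required field", f"$.{key}")
    if doc["view"] not in VIEWS:
        raise ParseError(f"unknown view {doc['view']!r}", "$.view")
    if not isinstance(doc["points"], dict):
        raise ParseError("points must be an object", "$.points")
    points: dict[str, tuple[float, float]] = {}
    for code, xy in doc["points"].items():
        jp = f"$.points.{code}"
        if code not in _VALID_CODES:
            raise ParseError(f"unknown landmark code {code!r}", jp)
        if (not isinstance(xy, (list, tuple)) or len(xy) != 2
                or not all(isinstance(v, (int, float)) for v in xy)):
            raise ParseError("point must be [x, y]", jp)
        if not all(math.isfinite(v) for v in xy):
            raise ParseError("coordinates must be finite", jp)
        points[code] = (float(xy[0]), float(xy[1]))
    confidence = None
    if "confidence" in doc:
        confidence = {}
        for code, v in doc["confidence"].items():
            jp = f"$.confidence.{code}"
            if code not in points:
                raise ParseError("confidence for absent point", jp)
            if not isinstance(v, (int, float)) or not 0.0 <= v <= 1.0:
                raise ParseError("confidence must be in [0, 1]", jp)
            confidence[code] = float(v)
    return LandmarkSet(subject_id=str(doc["subject_id"]), view=doc["view"],
                       points=points, confidence=confidence)


def landmark_sets_to_wide_frame(sets: Iterable[LandmarkSet]):
    """Wide CSV layout: one row per subject-view, two columns per code."""
    import pandas as pd

    rows = []
    for ls in sets:
        row: dict = {"subject_id": ls.subject_id, "view": ls.view}
        for c, (x, y) in sorted(ls.points.items()):
            row[f"{c}.x"] = x
            row[f"{c}.y"] = y
        rows.append(row)
    return pd.DataFrame(rows)


def measurements_to_frame(tables: Sequence[MeasurementTable]):
    """Measurement CSV: one row per subject, one column per code; the first
    data row carries the units."""
    import pandas as pd

    codes = sorted({c for t in tables for c in t.values})
    rows = []
    for t in tables:
        row: dict = {"subject_id": t.subject_id, "provenance": t.provenance}
        for c in codes:
            row[c] = t.get(c)
        rows.append(row)
    frame = pd.DataFrame(rows)
    units = {"subject_id": "units", "provenance": ""}
    for c in codes:
        for t in tables:
            if c in t.values:
                units[c] = t.values[c][1]
                break
    return pd.concat([pd.DataFrame([units]), frame], ignore_index=True)


def config_hash(doc: dict) -> str:
    """Stable short hash of a configuration mapping (provenance logging)."""
    text = json.dumps(doc, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def load_config(path) -> dict:
    """Load a pipeline YAML config."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ParseError("config must be a mapping")
    return doc
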
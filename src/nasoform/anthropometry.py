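"""Calibrated anthropometric measurement from landmark pixel geometry.

Pixel coordinates become physical measurements through a ruler-derived scale:
an in-frame steel ruler with known tick spacing gives millimetres-per-pixel
for each view, after which linear measurements are Euclidean pixel distances
times the scale, while angles need no calibration at all.

The measurement catalog (distances, vertex-in-middle angles, ratios, with
units per code) ships as a versioned YAML file next to this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import yaml

from .errors import CalibrationError, GeometryError, MeasurementError
from .landmarks import CalibrationInfo, LandmarkSet, View

Kind = Literal["distance", "angle", "ratio"]


@dataclass(frozen=True)
class MeasurementDef:
    """One catalog measurement: a distance, an angle, or a ratio of distances."""

    code: str
    kind: Kind
    operands: tuple[str, ...]     # landmark codes (distance/angle) or measurement codes (ratio)
    view: View
    units: Literal["mm", "cm", "degrees", "dimensionless"]
    optional: bool = False

    def __post_init__(self) -> None:
        want = {"distance": 2, "angle": 3, "ratio": 2}[self.kind]
        if len(self.operands) != want:
            raise ValueError(
                f"{self.code}: {self.kind} needs {want} operands, got {len(self.operands)}")


def _load_catalog() -> tuple[MeasurementDef, ...]:
    text = resources.files("nasoform.data").joinpath("measurements.yaml").read_text()
    doc = yaml.safe_load(text)
    return tuple(
        MeasurementDef(
            code=m["code"], kind=m["kind"], operands=tuple(m["operands"]),
            view=m["view"], units=m["units"], optional=bool(m.get("optional", False)),
        )
        for m in doc["measurements"]
    )


_CATALOG: tuple[MeasurementDef, ...] = _load_catalog()
_BY_CODE = {d.code: d for d in _CATALOG}


def measurement_catalog() -> tuple[MeasurementDef, ...]:
    """The shipped measurement catalog, in file order."""
    return _CATALOG


def measurement_def(code: str) -> MeasurementDef:
    try:
        return _BY_CODE[code]
    except KeyError:
        raise KeyError(f"unknown measurement code: {code!r}") from None


@dataclass
class MeasurementTable:
    """Per-subject measurements keyed by catalog code, with units."""

    subject_id: str
    values: dict[str, tuple[float, str]] = field(default_factory=dict)
    provenance: Literal["ground_truth", "detected"] = "detected"

    def value(self, code: str) -> float:
        return self.values[code][0]

    def get(self, code: str, default: float | None = None) -> float | None:
        v = self.values.get(code)
        return default if v is None else v[0]

    def __contains__(self, code: str) -> bool:
        return code in self.values


# ---------------------------------------------------------------------------
# geometric primitives
# ---------------------------------------------------------------------------

def euclidean_distance(p: Sequence[float], q: Sequence[float]) -> float:
    """Straight-line (Pythagorean) distance between two points in pixels."""
    return float(np.sqrt(np.sum((np.asarray(q, float) - np.asarray(p, float)) ** 2)))


def metric_inner_product(g_i: Sequence[float], g_j: Sequence[float]) -> float:
    """Scalar product <g_i, g_j> = |g_i||g_j| cos(theta_ij).

    The metric-coefficient form of the inner product; used to project shared
    axes when checking cross-view consistency of measurements.
    """
    return float(np.dot(np.asarray(g_i, float), np.asarray(g_j, float)))


def angle_at_vertex(a: Sequence[float], b: Sequence[float], c: Sequence[float]) -> float:
    """Interior angle /_abc at vertex ``b``, in degrees, range (0, 180].

    Invariant under translation, rotation and uniform scaling of the triple.
    """
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    u, v = a - b, c - b
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise GeometryError(f"coincident points in angle: a={a}, b={b}, c={c}")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def calibrate_scale(
    tick_positions_px: Sequence[Sequence[float]],
    tick_spacing_mm: float,
    view: View = "frontal",
    max_residual_frac: float = 0.10,
) -> CalibrationInfo:
    """Derive mm-per-pixel from ruler tick positions with known mm spacing.

    Fits the principal axis of the ticks, projects them onto it, and
    least-squares regresses projected position on tick index; the slope is the
    mean inter-tick pixel distance.  Rejects non-collinear ticks or irregular
    spacing with residuals beyond ``max_residual_frac`` of the spacing.
    """
    if tick_spacing_mm <= 0:
        raise CalibrationError(f"tick spacing must be positive, got {tick_spacing_mm}")
    pts = np.asarray(tick_positions_px, float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise CalibrationError(
            f"need >= 3 ruler ticks, got {0 if pts.ndim != 2 else pts.shape[0]}")
    centred = pts - pts.mean(axis=0)
    # principal axis via SVD
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    axis = vt[0]
    t = centred @ axis
    perp = centred - np.outer(t, axis)
    order = np.argsort(t)
    t_sorted = t[order]
    idx = np.arange(len(t_sorted))
    # least-squares slope of position vs tick index = mean inter-tick distance
    slope, intercept = np.polyfit(idx, t_sorted, 1)
    if slope <= 0:
        raise CalibrationError("degenerate tick layout (zero spread)")
    fit_resid = np.max(np.abs(t_sorted - (slope * idx + intercept)))
    perp_resid = np.max(np.linalg.norm(perp, axis=1))
    if perp_resid > max_residual_frac * slope:
        raise CalibrationError(
            f"ticks not collinear: perpendicular residual {perp_resid:.3g} px "
            f"exceeds {max_residual_frac:.0%} of spacing {slope:.3g} px")
    if fit_resid > max_residual_frac * slope:
        raise CalibrationError(
            f"irregular tick spacing: residual {fit_resid:.3g} px "
            f"exceeds {max_residual_frac:.0%} of spacing {slope:.3g} px")
    return CalibrationInfo(view=view, mm_per_px=float(tick_spacing_mm / slope),
                           source="ruler_ticks")


# ---------------------------------------------------------------------------
# subject measurement
# ---------------------------------------------------------------------------

def _convert(mm: float, units: str) -> float:
    if units == "mm":
        return mm
    if units == "cm":
        return mm / 10.0
    raise ValueError(f"not a linear unit: {units}")


def measure_subject(
    landmark_sets: Mapping[str, LandmarkSet],
    calib: Mapping[str, CalibrationInfo],
    defs: Iterable[MeasurementDef] | None = None,
    provenance: Literal["ground_truth", "detected"] = "detected",
) -> MeasurementTable:
    """Evaluate catalog measurements on per-view landmark sets.

    Distances are pixel distances scaled by the view's mm-per-pixel and
    reported in the def's units; angles are calibration-free; ratios divide
    two same-view distances.  Measurements whose operands include an optional
    (supplementary) landmark that is absent are silently skipped; a missing
    *required* landmark or calibration raises :class:`MeasurementError`.
    """
    defs = tuple(defs) if defs is not None else _CATALOG
    subject_id = next(iter(landmark_sets.values())).subject_id if landmark_sets else ""
    table = MeasurementTable(subject_id=subject_id, provenance=provenance)

    def resolve(d: MeasurementDef) -> list[tuple[float, float]] | None:
        ls = landmark_sets.get(d.view)
        if ls is None:
            if d.optional:
                return None
            raise MeasurementError(f"{d.code}: no landmark set for view {d.view!r}")
        pts = []
        for code in d.operands:
            p = ls.get(code)
            if p is None:
                if d.optional:
                    return None
                raise MeasurementError(
                    f"{d.code}: landmark {code!r} missing in {d.view} view")
            pts.append(p)
        return pts

    # distances and angles first, ratios second (they reference distance codes)
    for d in defs:
        if d.kind == "distance":
            pts = resolve(d)
            if pts is None:
                continue
            cal = calib.get(d.view)
            if cal is None:
                raise MeasurementError(f"{d.code}: no calibration for view {d.view!r}")
            mm = euclidean_distance(*pts) * cal.mm_per_px
            table.values[d.code] = (_convert(mm, d.units), d.units)
        elif d.kind == "angle":
            pts = resolve(d)
            if pts is None:
                continue
            table.values[d.code] = (angle_at_vertex(*pts), d.units)
    for d in defs:
        if d.kind == "ratio":
            num_code, den_code = d.operands
            if num_code not in table.values or den_code not in table.values:
                if d.optional:
                    continue
                missing = num_code if num_code not in table.values else den_code
                raise MeasurementError(f"{d.code}: operand measurement {missing!r} absent")
            den = table.value(den_code)
            if den == 0:
                raise MeasurementError(f"{d.code}: zero denominator {den_code!r}")
            table.values[d.code] = (table.value(num_code) / den, d.units)
    return table


def frontal_symmetry_ratios(ls: LandmarkSet) -> dict[str, float]:
    """Intranasal symmetry indices from a frontal landmark set.

    Returns the nasal height(g-sn)/width(mf-mf) ratio, right/left half-width
    ratios at the mid-alar (mal), subalare (ac) and alare (al) levels measured
    perpendicular to the g-sn midline axis, the total nose width |al_R al_L|
    in pixels, and the angle between the dorsum long axis (n->prn) and the
    midline, in degrees.  A perfectly symmetric face gives ratios of 1 and an
    axis angle of 0.
    """
    if ls.view != "frontal":
        raise MeasurementError(f"expected a frontal set, got {ls.view!r}")
    required = ["g", "sn", "n", "prn", "mf_R", "mf_L", "mal_R", "mal_L",
                "ac_R", "ac_L", "al_R", "al_L"]
    missing = [c for c in required if c not in ls.points]
    if missing:
        raise MeasurementError(f"frontal symmetry ratios: missing {missing}")
    P = {c: np.asarray(ls.points[c], float) for c in required}

    axis = P["sn"] - P["g"]
    axis_len = np.linalg.norm(axis)
    if axis_len == 0:
        raise GeometryError("g and sn coincide; midline axis undefined")
    axis /= axis_len
    normal = np.array([-axis[1], axis[0]])   # +normal points to subject's right

    def half_widths(code: str) -> tuple[float, float]:
        r = float(np.dot(P[f"{code}_R"] - P["g"], normal))
        l = float(np.dot(P[f"{code}_L"] - P["g"], normal))
        return abs(r), abs(l)

    def lr_ratio(code: str) -> float:
        r, l = half_widths(code)
        if l == 0:
            raise GeometryError(f"left {code} lies on the midline axis")
        return r / l

    width = euclidean_distance(P["mf_R"], P["mf_L"])
    if width == 0:
        raise GeometryError("mf_R and mf_L coincide")
    dorsum = P["prn"] - P["n"]
    if np.linalg.norm(dorsum) == 0:
        raise GeometryError("n and prn coincide; dorsum axis undefined")
    cosang = np.clip(np.dot(dorsum / np.linalg.norm(dorsum), axis), -1.0, 1.0)
    axis_angle = float(np.degrees(np.arccos(cosang)))

    return {
        "height_width_ratio": euclidean_distance(P["g"], P["sn"]) / width,
        "mid_alar_lr_ratio": lr_ratio("mal"),
        "base_lr_ratio": lr_ratio("ac"),
        "alar_lr_ratio": lr_ratio("al"),
        "total_width_px": euclidean_distance(P["al_R"], P["al_L"]),
        "axis_angle_deg": axis_angle,
    }
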
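"""Canonical catalog of facial anthropometric landmarks and landmark-set validation.

The nose-centred photogrammetric protocol works with 29 landmark points per
subject: 9 midline (midsagittal) points and 10 bilateral pairs, identified in
up to three standardised views (frontal, lateral, basilar).  Paired landmarks
are stored as sided codes, e.g. ``al_L`` / ``al_R`` for left and right alare.

A small set of *supplementary* landmarks (kyphion ``k``, columella ``cm``,
labrale inferius/superius ``li``/``ls``) is carried in the catalog as optional
entries: they are anatomically absent or unreliable in some subjects (the
kyphion only exists when a dorsal hump is present) and are not counted among
the 29 core points.

Coordinate convention: image pixel coordinates, origin at the top-left corner,
x rightward, y downward, 0-based, sub-pixel floats allowed.  Lateral-view
subjects face +x; superior is -y.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

View = Literal["frontal", "lateral", "basilar"]
VIEWS: tuple[View, ...] = ("frontal", "lateral", "basilar")

#: base codes of midline landmarks (9)
MIDLINE_CODES: tuple[str, ...] = ("tr", "g", "n", "s", "r", "prn", "sn", "pg", "gn")

#: base codes of paired landmarks (10); each contributes two points, _L and _R
PAIRED_CODES: tuple[str, ...] = (
    "en", "ex", "mf", "al", "mal", "ac", "zy", "ch", "po", "or",
)

#: optional supplementary midline codes, not counted in the 29 core points
SUPPLEMENTARY_CODES: tuple[str, ...] = ("k", "cm", "li", "ls")

_FULL_NAMES = {
    "tr": "trichion",
    "g": "glabella",
    "n": "nasion",
    "s": "sellion",
    "r": "rhinion",
    "prn": "pronasale",
    "sn": "subnasale",
    "pg": "pogonion",
    "gn": "gnathion",
    "en": "endocanthion",
    "ex": "exocanthion",
    "mf": "maxillofrontale",
    "al": "alare",
    "mal": "mid-alare",
    "ac": "subalare",
    "zy": "zygion",
    "ch": "cheilion",
    "po": "porion",
    "or": "orbitale",
    "k": "kyphion",
    "cm": "columella",
    "li": "labrale inferius",
    "ls": "labrale superius",
}

# which views each base code can appear in
_VIEW_SETS: dict[str, frozenset[str]] = {
    "tr": frozenset({"frontal", "lateral"}),
    "g": frozenset({"frontal", "lateral"}),
    "n": frozenset({"frontal", "lateral"}),
    "s": frozenset({"lateral"}),
    "r": frozenset({"lateral"}),
    "prn": frozenset({"frontal", "lateral", "basilar"}),
    "sn": frozenset({"frontal", "lateral", "basilar"}),
    "pg": frozenset({"frontal", "lateral"}),
    "gn": frozenset({"frontal", "lateral"}),
    "en": frozenset({"frontal"}),
    "ex": frozenset({"frontal"}),
    "mf": frozenset({"frontal"}),
    "al": frozenset({"frontal", "basilar"}),
    "mal": frozenset({"frontal"}),
    "ac": frozenset({"frontal", "basilar"}),
    "zy": frozenset({"frontal"}),
    "ch": frozenset({"frontal"}),
    "po": frozenset({"lateral"}),
    "or": frozenset({"lateral"}),
    "k": frozenset({"lateral"}),
    "cm": frozenset({"lateral", "basilar"}),
    "li": frozenset({"lateral"}),
    "ls": frozenset({"lateral"}),
}


@dataclass(frozen=True)
class LandmarkDef:
    """Definition of one landmark *point* (sided codes are separate entries)."""

    code: str                      # e.g. "prn" or "al_R"
    base_code: str                 # e.g. "prn" or "al"
    full_name: str
    view_set: frozenset[str]
    laterality: Literal["midline", "paired"]
    supplementary: bool = False    # optional/not-always-present; outside the 29


def _build_catalog() -> tuple[LandmarkDef, ...]:
    defs: list[LandmarkDef] = []
    for code in MIDLINE_CODES:
        defs.append(LandmarkDef(code, code, _FULL_NAMES[code], _VIEW_SETS[code], "midline"))
    for code in PAIRED_CODES:
        for side in ("R", "L"):
            defs.append(
                LandmarkDef(
                    f"{code}_{side}", code,
                    f"{_FULL_NAMES[code]} ({'right' if side == 'R' else 'left'})",
                    _VIEW_SETS[code], "paired",
                )
            )
    for code in SUPPLEMENTARY_CODES:
        defs.append(
            LandmarkDef(code, code, _FULL_NAMES[code], _VIEW_SETS[code], "midline",
                        supplementary=True)
        )
    return tuple(defs)


_CATALOG: tuple[LandmarkDef, ...] = _build_catalog()
_BY_CODE: dict[str, LandmarkDef] = {d.code: d for d in _CATALOG}


def landmark_catalog(include_supplementary: bool = True) -> tuple[LandmarkDef, ...]:
    """Return the fixed landmark catalog in stable order.

    The core roster has exactly 29 entries (9 midline points + 10 pairs as 20
    sided points).  With ``include_supplementary`` (default) the optional
    kyphion/columella/labial entries are appended, flagged via
    :attr:`LandmarkDef.supplementary`.
    """
    if include_supplementary:
        return _CATALOG
    return tuple(d for d in _CATALOG if not d.supplementary)


def landmark_def(code: str) -> LandmarkDef:
    """Look up a catalog entry by (possibly sided) code."""
    try:
        return _BY_CODE[code]
    except KeyError:
        raise KeyError(f"unknown landmark code: {code!r}") from None


def paired_midline_partition() -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Disjoint, exhaustive partition of core base codes into (paired, midline)."""
    return PAIRED_CODES, MIDLINE_CODES


def codes_for_view(view: View, include_supplementary: bool = False) -> tuple[str, ...]:
    """All catalog codes valid in ``view``, in catalog order."""
    return tuple(
        d.code for d in landmark_catalog(include_supplementary)
        if view in d.view_set
    )


@dataclass
class LandmarkSet:
    """Named 2D pixel coordinates for one view of one subject."""

    subject_id: str
    view: View
    points: dict[str, tuple[float, float]]
    confidence: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.view not in VIEWS:
            raise ValueError(f"unknown view: {self.view!r}")

    def get(self, code: str) -> tuple[float, float] | None:
        return self.points.get(code)

    def __contains__(self, code: str) -> bool:
        return code in self.points


@dataclass(frozen=True)
class CalibrationInfo:
    """Millimetres-per-pixel scale for one view, from ruler ticks or metadata."""

    view: View
    mm_per_px: float
    source: Literal["ruler_ticks", "metadata"] = "metadata"

    def __post_init__(self) -> None:
        import math

        if not (math.isfinite(self.mm_per_px) and self.mm_per_px > 0):
            raise ValueError(f"mm_per_px must be positive and finite, got {self.mm_per_px}")


@dataclass(frozen=True)
class Violation:
    """One landmark-set invariant violation (data, not an exception)."""

    code: str
    rule: str
    detail: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.code}: {self.rule} {self.detail}".rstrip()


def validate_landmark_set(
    ls: LandmarkSet, image_shape: tuple[int, int] | None = None
) -> list[Violation]:
    """Check a landmark set against the catalog and (optionally) image bounds.

    Returns an empty list iff every point has a catalog code valid for the
    set's view, all coordinates are finite, and — when ``image_shape`` (h, w)
    is given — every point lies inside the image.
    """
    import math

    violations: list[Violation] = []
    for code, (x, y) in ls.points.items():
        d = _BY_CODE.get(code)
        if d is None:
            violations.append(Violation(code, "unknown-code"))
            continue
        if ls.view not in d.view_set:
            violations.append(
                Violation(code, "wrong-view", f"not valid in {ls.view} view")
            )
        if not (math.isfinite(x) and math.isfinite(y)):
            violations.append(Violation(code, "non-finite", f"({x}, {y})"))
            continue
        if image_shape is not None:
            h, w = image_shape
            if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
                violations.append(
                    Violation(code, "out-of-bounds", f"({x:.1f}, {y:.1f}) outside {w}x{h}")
                )
    if ls.confidence:
        for code, c in ls.confidence.items():
            if code not in ls.points:
                violations.append(Violation(code, "confidence-without-point"))
            elif not 0.0 <= c <= 1.0:
                violations.append(Violation(code, "confidence-out-of-range", f"{c}"))
    return violations
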
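"""Evaluation metrics and group statistics for keypoint and morphology results.

Keypoint regression quality is scored with the mean absolute error (MAE),
the coefficient of determination R^2, and a detection-style mean average
precision (mAP): each landmark code is treated as a detection category, a
predicted point counts as correct iff it falls within a fixed radius of the
true point, and AP is the 101-point interpolated area under the
precision-recall curve, averaged over categories.

Group summaries follow the reporting conventions of craniofacial
anthropometry: sample-size-weighted pooled means, Welch's unequal-variance
t-test for two-group contrasts, and the Kruskal-Wallis rank test for
multi-group contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .errors import ParameterError, StatError


def mae(y_true: Sequence[float], y_pred: Sequence[float]) -> float:
    """Mean absolute error between paired vectors."""
    t = np.asarray(y_true, float)
    p = np.asarray(y_pred, float)
    if t.shape != p.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {p.shape}")
    if t.size == 0:
        raise ValueError("empty input")
    return float(np.mean(np.abs(t - p)))


def r_squared(y_true: Sequence[float], y_pred: Sequence[float]) -> float:
    """R^2 = 1 - SS_residual / SS_total; 1 for perfect prediction."""
    t = np.asarray(y_true, float)
    p = np.asarray(y_pred, float)
    if t.shape != p.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {p.shape}")
    if t.size < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    if ss_tot == 0:
        raise StatError("R^2 undefined for constant y_true")
    return 1.0 - float(np.sum((t - p) ** 2)) / ss_tot


@dataclass(frozen=True)
class KeypointEvalConfig:
    """mAP settings: correctness radius (px or mm) and the category codes."""

    radius: float = 5.0
    categories: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ParameterError(f"radius must be positive, got {self.radius}")


@dataclass(frozen=True)
class Detection:
    image_id: str
    code: str
    point: tuple[float, float]
    confidence: float


@dataclass(frozen=True)
class GroundTruth:
    image_id: str
    code: str
    point: tuple[float, float]


def _average_precision(dets: list[Detection], truths: list[GroundTruth],
                       radius: float) -> float:
    """101-point interpolated AP for one category.

    Detections are matched greedily in order of decreasing confidence; a
    detection is a true positive iff it lies within ``radius`` of a so-far
    unmatched truth in the same image.
    """
    n_truth = len(truths)
    by_image: dict[str, list[tuple[GroundTruth, bool]]] = {}
    matched: dict[int, bool] = {id(t): False for t in truths}
    for t in truths:
        by_image.setdefault(t.image_id, []).append((t, False))
    order = sorted(dets, key=lambda d: -d.confidence)
    tp = np.zeros(len(order))
    for i, d in enumerate(order):
        best, best_dist = None, None
        for t in truths:
            if t.image_id != d.image_id or matched[id(t)]:
                continue
            dist = float(np.hypot(t.point[0] - d.point[0], t.point[1] - d.point[1]))
            if dist <= radius and (best_dist is None or dist < best_dist):
                best, best_dist = t, dist
        if best is not None:
            matched[id(best)] = True
            tp[i] = 1.0
    cum_tp = np.cumsum(tp)
    precision = cum_tp / np.arange(1, len(order) + 1)
    recall = cum_tp / n_truth
    # 101-point interpolation: mean over r in {0, .01, ..., 1} of max
    # precision at recall >= r
    ap = 0.0
    for r in np.linspace(0.0, 1.0, 101):
        mask = recall >= r - 1e-12
        ap += float(precision[mask].max()) if mask.any() else 0.0
    return ap / 101.0


def mean_average_precision(
    detections: Iterable[Detection],
    truths: Iterable[GroundTruth],
    cfg: KeypointEvalConfig,
) -> float:
    """Category-averaged AP over landmark codes; in [0, 1].

    Categories (from ``cfg.categories`` or the truth set) with no ground
    truth are skipped with a warning.
    """
    import logging

    dets = list(detections)
    gts = list(truths)
    categories = cfg.categories or tuple(sorted({t.code for t in gts}))
    aps = []
    for code in categories:
        t_k = [t for t in gts if t.code == code]
        if not t_k:
            logging.getLogger(__name__).warning(
                "category %r has no ground truth; skipped", code)
            continue
        d_k = [d for d in dets if d.code == code]
        aps.append(_average_precision(d_k, t_k, cfg.radius))
    if not aps:
        raise StatError("no categories with ground truth")
    return float(np.mean(aps))


@dataclass(frozen=True)
class GroupSummary:
    """label, n, mean, sd — one group of a mean +/- SD table."""

    label: str
    n: int
    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ParameterError(f"group {self.label!r}: n must be >= 1")
        if self.sd < 0:
            raise ParameterError(f"group {self.label!r}: sd must be >= 0")


def pooled_mean(groups: Sequence[GroupSummary]) -> float:
    """Sample-size-weighted mean across groups: sum(n_i m_i) / sum(n_i)."""
    if not groups:
        raise ParameterError("groups must be non-empty")
    n_total = sum(g.n for g in groups)
    return sum(g.n * g.mean for g in groups) / n_total


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, Satterthwaite df, two-sided p)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise StatError("each sample needs >= 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise StatError("both samples have zero variance")
    res = sps.ttest_ind(a, b, equal_var=False)
    na, nb = len(a), len(b)
    df = (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Kruskal-Wallis rank test with tie correction; returns (H, df, p)."""
    if len(groups) < 2:
        raise StatError("need >= 2 groups")
    if any(len(g) < 2 for g in groups):
        raise StatError("each group needs >= 2 observations")
    flat = np.concatenate([np.asarray(g, float) for g in groups])
    if np.ptp(flat) == 0:
        raise StatError("all values identical; H undefined")
    h, p = sps.kruskal(*groups)
    return float(h), len(groups) - 1, float(p)


def _round_half_up(x: float, digits: int) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(f"1e-{digits}"), ROUND_HALF_UP))


def summarize_classification(labels: Iterable[str]):
    """Frequency and percentage table of hard class labels.

    Returns a DataFrame indexed by label with ``count``, ``fraction``
    (exact), and ``percentage`` (half-up rounded to 1 decimal, for report
    parity with the usual qualitative-variable presentation).
    """
    import pandas as pd

    labels = list(labels)
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    total = len(labels)
    rows = {
        lab: {
            "count": k,
            "fraction": k / total,
            "percentage": _round_half_up(100.0 * k / total, 1),
        }
        for lab, k in sorted(counts.items())
    }
    return pd.DataFrame.from_dict(rows, orient="index")
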
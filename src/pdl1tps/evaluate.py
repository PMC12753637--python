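"""Pixel-, object- and patient-level evaluation of segmentation and scoring.

Pixel level compares masks pixel by pixel (accuracy, one-vs-rest
sensitivity and specificity per class, macro mean over the two tumour-cell
classes). Object level extracts cells from both masks with the same
radius-4 connected-component rule used for counting and matches them
one-to-one greedily by overlap. Patient level compares per-case TPS pairs
by Pearson (and Spearman) correlation and by concordance of the assigned
clinical interval.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .quantify import DEFAULT_MERGE_RADIUS_PX, label_cells

__all__ = [
    "PixelMetrics",
    "ObjectMetrics",
    "PatientMetrics",
    "pixel_metrics",
    "object_metrics",
    "patient_metrics",
    "clinical_category",
]

_CLASSES = (0, 1, 2)
_FOREGROUND = (1, 2)


@dataclass
class PixelMetrics:
    accuracy: float
    sensitivity: dict[int, float]    # per class; NaN when class absent from gt
    specificity: dict[int, float]
    macro_sensitivity: float         # mean over defined foreground classes
    macro_specificity: float
    confusion: np.ndarray = field(repr=False, default=None)


@dataclass
class ObjectMetrics:
    precision: float
    recall: float
    n_gt_objects: int
    n_pred_objects: int
    n_matched: int
    degenerate: bool = False         # no predicted objects while gt has some


@dataclass
class PatientMetrics:
    pearson_r: float
    spearman_r: float
    interval_concordance: float
    n_cases: int
    pairs: list[tuple[float, float]] = field(default_factory=list)


def pixel_metrics(gt: np.ndarray, pred: np.ndarray) -> PixelMetrics:
    """Per-pixel agreement between a ground-truth and a predicted mask.

    Sensitivity of a class absent from the ground truth is undefined and
    reported as NaN; macro averages skip undefined classes and cover the
    foreground (tumour-cell) classes only.
    """
    gt, pred = np.asarray(gt), np.asarray(pred)
    if gt.shape != pred.shape:
        raise ValueError("ground-truth and prediction shapes differ")
    cm = np.zeros((3, 3), dtype=np.int64)
    np.add.at(cm, (gt.ravel(), pred.ravel()), 1)
    total = cm.sum()
    accuracy = float(np.trace(cm)) / total
    sens, spec = {}, {}
    for c in _CLASSES:
        tp = cm[c, c]
        fn = cm[c].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = total - tp - fn - fp
        sens[c] = float(tp / (tp + fn)) if (tp + fn) > 0 else math.nan
        spec[c] = float(tn / (tn + fp)) if (tn + fp) > 0 else math.nan
    fg_sens = [sens[c] for c in _FOREGROUND if not math.isnan(sens[c])]
    fg_spec = [spec[c] for c in _FOREGROUND if not math.isnan(spec[c])]
    return PixelMetrics(
        accuracy=accuracy, sensitivity=sens, specificity=spec,
        macro_sensitivity=float(np.mean(fg_sens)) if fg_sens else math.nan,
        macro_specificity=float(np.mean(fg_spec)) if fg_spec else math.nan,
        confusion=cm)


def object_metrics(gt: np.ndarray, pred: np.ndarray, class_label: int,
                   merge_radius_px: int = DEFAULT_MERGE_RADIUS_PX,
                   min_iou: float = 0.0) -> ObjectMetrics:
    """Per-object precision/recall for one tumour-cell class.

    Objects come from :func:`label_cells` on each mask. Matching is
    one-to-one and greedy by descending pixel overlap (ties broken by the
    smaller ground-truth then prediction index); a candidate pair must
    overlap in at least one pixel and, when ``min_iou`` > 0, reach that IoU.
    With no predicted and no ground-truth objects both rates are 1; with no
    predictions against a non-empty ground truth, precision is reported as 0
    and the result is flagged degenerate.
    """
    if np.asarray(gt).shape != np.asarray(pred).shape:
        raise ValueError("ground-truth and prediction shapes differ")
    gt_objs = label_cells(gt, class_label, merge_radius_px)
    pr_objs = label_cells(pred, class_label, merge_radius_px)
    n_gt, n_pr = len(gt_objs), len(pr_objs)
    if n_gt == 0 and n_pr == 0:
        return ObjectMetrics(1.0, 1.0, 0, 0, 0)
    candidates = []
    for i, g in enumerate(gt_objs):
        for j, p in enumerate(pr_objs):
            inter = int(np.count_nonzero(g & p))
            if inter == 0:
                continue
            if min_iou > 0:
                union = int(np.count_nonzero(g | p))
                if inter / union < min_iou:
                    continue
            candidates.append((-inter, i, j))
    candidates.sort()
    used_g, used_p = set(), set()
    n_matched = 0
    for _, i, j in candidates:
        if i in used_g or j in used_p:
            continue
        used_g.add(i)
        used_p.add(j)
        n_matched += 1
    precision = n_matched / n_pr if n_pr else 0.0
    recall = n_matched / n_gt if n_gt else 1.0
    return ObjectMetrics(precision=precision, recall=recall,
                         n_gt_objects=n_gt, n_pred_objects=n_pr,
                         n_matched=n_matched,
                         degenerate=(n_pr == 0 and n_gt > 0))


def clinical_category(tps: float) -> str:
    """The NSCLC PD-L1 reporting category: <1%, 1-49% or >=50%."""
    if not 0.0 <= tps <= 100.0:
        raise ValueError("TPS must lie in [0, 100]")
    if tps < 1.0:
        return "<1%"
    if tps < 50.0:
        return "1-49%"
    return ">=50%"


def patient_metrics(gt_scores, pred_scores,
                    interval_scheme=None) -> PatientMetrics:
    """Case-level agreement between ground-truth and estimated TPS.

    ``interval_scheme`` maps a score to an interval label; by default the
    three clinical reporting categories are used, and a routing
    :class:`~pdl1tps.router.IntervalScheme` may be passed for band-level
    concordance. Pearson correlation is NaN (with a warning) when either
    score vector is constant.
    """
    gt = np.asarray(gt_scores, dtype=np.float64)
    pr = np.asarray(pred_scores, dtype=np.float64)
    if gt.shape != pr.shape or gt.ndim != 1:
        raise ValueError("score lists must be 1-D and of equal length")
    if gt.size < 2:
        raise ValueError("need at least two cases for correlation")
    to_interval = interval_scheme
    if to_interval is None:
        to_interval = clinical_category
    elif hasattr(to_interval, "band_of"):
        scheme = to_interval
        to_interval = lambda s: scheme.band_of(s)  # noqa: E731
    concordance = float(np.mean([to_interval(a) == to_interval(b)
                                 for a, b in zip(gt, pr)]))
    if np.ptp(gt) == 0 or np.ptp(pr) == 0:
        warnings.warn("constant score vector: correlation undefined",
                      stacklevel=2)
        pearson = spearman = math.nan
    else:
        pearson = float(stats.pearsonr(gt, pr).statistic)
        spearman = float(stats.spearmanr(gt, pr).statistic)
    return PatientMetrics(pearson_r=pearson, spearman_r=spearman,
                          interval_concordance=concordance,
                          n_cases=int(gt.size),
                          pairs=list(zip(gt.tolist(), pr.tolist())))
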
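"""Instance-segmentation metrics: IoU, TP/FP/FN matching, PR curves, AP.

The evaluation protocol works on pairs of instance sets per image: a labelled
set ``S_l`` (ground truth or generated labels) and a predicted set ``S_p``
whose instances carry confidence scores.  Given an IoU threshold ``T_iou``,
predictions are matched one-to-one to labels; matched pairs are true
positives, unmatched predictions false positives and unmatched labels false
negatives.  Sweeping a score threshold ``T_s`` over the predictions yields a
precision-recall curve per image; average precision (AP) is the mean of
interpolated precision over ``M`` fixed recall evaluation points of that
curve, and the reported AP is its arithmetic mean over images.

Degenerate-frame conventions (documented design choices):

* ``precision := 1`` when ``TP + FP = 0`` and ``recall := 1`` when
  ``TP + FN = 0`` (vacuous truth);
* ``mask_iou := 1`` when both masks are empty, ``0`` when exactly one is;
* an image with no labels and no predictions contributes ``AP = 1``;
* an image with labels (or predictions) but no true positive at any score
  threshold contributes ``AP = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import json
import numpy as np
import pandas as pd

from .instances import InstanceMaskSet, box_iou

__all__ = [
    "MatchResult",
    "PRCurve",
    "APResult",
    "mask_iou",
    "box_iou",
    "match_instances",
    "precision_recall",
    "pr_curve",
    "average_precision",
    "evaluate_suite",
    "mean_mask_iou",
]

DEFAULT_IOU_GRID = tuple(np.round(np.arange(0.3, 0.7001, 0.05), 2))


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard index of two binary masks on a common grid."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    inter = np.count_nonzero(a & b)
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0
    return inter / union


@dataclass
class MatchResult:
    """TP/FP/FN bookkeeping for one image at one IoU threshold."""

    t_iou: float
    pairs: list[tuple[int, int, float]]  # (label idx, prediction idx, IoU)
    fp_indices: list[int]
    fn_indices: list[int]

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fp(self) -> int:
        return len(self.fp_indices)

    @property
    def fn(self) -> int:
        return len(self.fn_indices)


def _iou_matrix(s_l: InstanceMaskSet, s_p: InstanceMaskSet, mode: str) -> np.ndarray:
    n_l, n_p = len(s_l), len(s_p)
    iou = np.zeros((n_l, n_p), dtype=float)
    if n_l == 0 or n_p == 0:
        return iou
    if mode == "mask":
        for i, ml in enumerate(s_l.masks):
            for j, mp in enumerate(s_p.masks):
                iou[i, j] = mask_iou(ml, mp)
    elif mode == "box":
        lb, pb = s_l.boxes, s_p.boxes
        for i in range(n_l):
            for j in range(n_p):
                iou[i, j] = box_iou(lb[i], pb[j])
    else:
        raise ValueError(f"mode must be 'mask' or 'box', got {mode!r}")
    return iou


def match_instances(
    s_l: InstanceMaskSet,
    s_p: InstanceMaskSet,
    t_iou: float,
    mode: str = "mask",
) -> MatchResult:
    """One-to-one greedy matching of predictions to labels.

    Predictions are visited in descending score order (index order when no
    scores are present); each claims the unclaimed label of highest IoU,
    provided that IoU strictly exceeds ``t_iou``.
    """
    if not (0.0 < t_iou < 1.0):
        raise ValueError(f"t_iou must lie in (0, 1), got {t_iou}")
    if s_l.shape != s_p.shape:
        raise ValueError("label and prediction sets live on different grids")
    iou = _iou_matrix(s_l, s_p, mode)
    order = range(len(s_p))
    if s_p.scores is not None:
        order = sorted(order, key=lambda j: -s_p.scores[j])
    claimed = set()
    pairs: list[tuple[int, int, float]] = []
    fp: list[int] = []
    for j in order:
        best_i, best_iou = -1, t_iou
        for i in range(len(s_l)):
            if i in claimed:
                continue
            if iou[i, j] > best_iou:
                best_i, best_iou = i, iou[i, j]
        if best_i >= 0:
            claimed.add(best_i)
            pairs.append((best_i, j, float(best_iou)))
        else:
            fp.append(j)
    fn = [i for i in range(len(s_l)) if i not in claimed]
    return MatchResult(t_iou=float(t_iou), pairs=pairs, fp_indices=fp, fn_indices=fn)


def precision_recall(m: MatchResult) -> tuple[float, float]:
    """``(TP/(TP+FP), TP/(TP+FN))`` with 0/0 mapped to 1 (vacuous truth)."""
    precision = 1.0 if m.tp + m.fp == 0 else m.tp / (m.tp + m.fp)
    recall = 1.0 if m.tp + m.fn == 0 else m.tp / (m.tp + m.fn)
    return precision, recall


@dataclass
class PRCurve:
    """Precision-recall points obtained by sweeping the score threshold."""

    t_iou: float
    points: list[tuple[float, float, float]] = field(default_factory=list)  # (T_s, P, R)

    @property
    def thresholds(self) -> list[float]:
        return [p[0] for p in self.points]


def pr_curve(
    s_l: InstanceMaskSet,
    s_p: InstanceMaskSet,
    t_iou: float,
    thresholds: list[float] | None = None,
    mode: str = "mask",
) -> PRCurve:
    """PR curve over score thresholds (default: the distinct scores present).

    For each ``T_s`` predictions scoring below ``T_s`` are removed, the
    remainder re-matched, and one (precision, recall) point recorded.
    """
    if s_p.scores is None:
        raise ValueError("pr_curve requires scored predictions")
    if thresholds is None:
        thresholds = sorted(set(s_p.scores))
        if not thresholds:
            thresholds = [0.0]
    curve = PRCurve(t_iou=float(t_iou))
    for t_s in thresholds:
        kept = s_p.filtered_by_score(t_s)
        p, r = precision_recall(match_instances(s_l, kept, t_iou, mode=mode))
        curve.points.append((float(t_s), p, r))
    return curve


@dataclass
class APResult:
    per_image_ap: list[float]
    mean_ap: float
    m_points: list[int]  # recall evaluation points used per image


#: number of recall evaluation points per image in the AP inner mean
AP_RECALL_POINTS = 100


def _single_image_ap(
    s_l: InstanceMaskSet, s_p: InstanceMaskSet, t_iou: float, mode: str
) -> tuple[float, int]:
    if len(s_l) == 0 and len(s_p) == 0:
        return 1.0, 0
    if len(s_p) == 0 or s_p.scores is None or len(s_l) == 0:
        # missed everything, or pure false positives on an empty frame
        return 0.0, 0
    curve = pr_curve(s_l, s_p, t_iou, mode=mode)
    pts = [(p, r) for (_, p, r) in curve.points]
    if not any(r > 0.0 for _, r in pts):
        # no true positive at any score threshold
        return 0.0, 0
    # interpolated precision on a fixed grid of M recall evaluation points
    # (j/M for j = 1..M): the best precision among operating points whose
    # recall reaches the level, 0 if the level is never reached
    m = AP_RECALL_POINTS
    ap_terms = []
    for j in range(1, m + 1):
        r_level = j / m
        reached = [p for p, r in pts if r >= r_level - 1e-12]
        ap_terms.append(max(reached) if reached else 0.0)
    return float(np.mean(ap_terms)), m


def average_precision(
    images: list[tuple[InstanceMaskSet, InstanceMaskSet]],
    t_iou: float,
    mode: str = "mask",
) -> APResult:
    """Per-image AP averaged over images.

    For each image the PR curve is traced over its distinct prediction
    scores; AP is the mean of interpolated precision over a fixed grid of
    ``AP_RECALL_POINTS`` recall evaluation points (precision at a recall
    level is the best precision among operating points reaching it, zero if
    unreached), and ``mean_ap`` averages those per-image values.  The fixed
    grid makes AP non-increasing in the IoU threshold.
    """
    if not images:
        raise ValueError("average_precision requires at least one image")
    per, ms = [], []
    for s_l, s_p in images:
        ap, m = _single_image_ap(s_l, s_p, t_iou, mode)
        per.append(ap)
        ms.append(m)
    return APResult(per_image_ap=per, mean_ap=float(np.mean(per)), m_points=ms)


def evaluate_suite(
    images: list[tuple[InstanceMaskSet, InstanceMaskSet]],
    iou_grid=DEFAULT_IOU_GRID,
    modes: tuple[str, ...] = ("box", "mask"),
) -> pd.DataFrame:
    """AP for every IoU threshold in ``iou_grid``, for box and mask IoU.

    Returns a tidy DataFrame with columns ``mode, t_iou, mean_ap`` (one row
    per mode/threshold combination).
    """
    rows = []
    for mode in modes:
        for t in iou_grid:
            res = average_precision(images, float(t), mode=mode)
            rows.append({"mode": mode, "t_iou": round(float(t), 4), "mean_ap": res.mean_ap})
    return pd.DataFrame(rows)


def export_report(df: pd.DataFrame, csv_path, json_path=None) -> None:
    df.to_csv(csv_path, index=False, float_format="%.6f")
    if json_path is not None:
        records = df.to_dict(orient="records")
        with open(json_path, "w") as fh:
            json.dump(records, fh, indent=2, sort_keys=True)


def mean_mask_iou(
    golden: list[InstanceMaskSet],
    predicted: list[InstanceMaskSet],
    t_iou: float = 0.5,
) -> tuple[float, float]:
    """Mean and SD of matched-pair mask IoU pooled over frames.

    Frames are paired positionally; instances are matched at ``t_iou`` and the
    IoUs of all matched pairs across all frames are pooled.
    """
    if len(golden) != len(predicted):
        raise ValueError(
            f"frame counts differ: {len(golden)} golden vs {len(predicted)} predicted"
        )
    ious: list[float] = []
    for s_l, s_p in zip(golden, predicted):
        m = match_instances(s_l, s_p, t_iou, mode="mask")
        ious.extend(iou for (_, _, iou) in m.pairs)
    if not ious:
        raise ValueError("no matched instance pairs; cannot compute mean IoU")
    arr = np.asarray(ious)
    return float(arr.mean()), float(arr.std(ddof=0))
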
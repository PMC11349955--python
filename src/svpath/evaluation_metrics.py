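"""Segmentation and detection evaluation: Dice, IoU, acceptable fraction,
and box-level precision / recall / mAP.

Two mAP figures are reported side by side: ``map_standard``, the
all-point-interpolated area under the precision-recall curve at a fixed
box-IoU matching threshold (the definition object-detection benchmarks
use), and ``map_paper_style``, the plain mean of precision and recall,
which some validation reports quote as "mAP". Both are labeled explicitly
so they are never confused.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .segmentation import MaskSet
from .wsi_geometry import BBox

logger = logging.getLogger(__name__)

__all__ = [
    "SegEvalReport",
    "DetEvalReport",
    "dice",
    "iou",
    "box_iou",
    "seg_eval",
    "det_eval",
    "average_precision",
]


@dataclasses.dataclass
class SegEvalReport:
    per_item_dice: list[float]
    per_item_iou: list[float]
    mean_dice: float
    mean_iou: float
    min_dice: float
    max_dice: float
    acceptable_fraction: float
    threshold: float = 0.7

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class DetEvalReport:
    precision: float
    recall: float
    map_standard: float
    map_paper_style: float
    iou_match_threshold: float = 0.5
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a, b


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity 2|A∩B| / (|A| + |B|); 1 when both masks are empty."""
    a, b = _check_pair(a, b)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        logger.debug("dice of two empty masks: scored 1 by convention")
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union |A∩B| / |A∪B|; 1 when both masks are empty."""
    a, b = _check_pair(a, b)
    union = int((a | b).sum())
    if union == 0:
        logger.debug("iou of two empty masks: scored 1 by convention")
        return 1.0
    return int((a & b).sum()) / union


def seg_eval(
    pred: list[MaskSet],
    truth: list[MaskSet],
    structure: str = "sv",
    threshold: float = 0.7,
) -> SegEvalReport:
    """Per-item Dice/IoU over aligned prediction/truth mask pairs.

    Items are aligned by patch identity; ``structure`` selects the SV or the
    capillary mask. ``acceptable_fraction`` is the share of items with
    Dice above ``threshold`` (0.7 is the conventional cut for acceptable
    segmentation).
    """
    if len(pred) == 0 or len(pred) != len(truth):
        raise ValueError(f"need equal nonempty lists, got {len(pred)} vs {len(truth)}")
    if structure not in ("sv", "cap"):
        raise ValueError("structure must be 'sv' or 'cap'")
    for p, t in zip(pred, truth):
        if p.patch_ref and t.patch_ref and p.patch_ref != t.patch_ref:
            raise ValueError(f"misaligned items: {p.patch_ref!r} vs {t.patch_ref!r}")
    attr = "sv_mask" if structure == "sv" else "cap_mask"
    dices = [dice(getattr(p, attr), getattr(t, attr)) for p, t in zip(pred, truth)]
    ious = [iou(getattr(p, attr), getattr(t, attr)) for p, t in zip(pred, truth)]
    n = len(dices)
    return SegEvalReport(
        per_item_dice=dices,
        per_item_iou=ious,
        mean_dice=float(np.mean(dices)),
        mean_iou=float(np.mean(ious)),
        min_dice=float(np.min(dices)),
        max_dice=float(np.max(dices)),
        acceptable_fraction=sum(d > threshold for d in dices) / n,
        threshold=threshold,
    )


def box_iou(a: BBox, b: BBox) -> float:
    """IoU of two axis-aligned half-open boxes."""
    ir = max(0, min(a.row_max, b.row_max) - max(a.row_min, b.row_min))
    ic = max(0, min(a.col_max, b.col_max) - max(a.col_min, b.col_min))
    inter = ir * ic
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def _greedy_match(pred: list[BBox], truth: list[BBox], thr: float) -> list[bool]:
    """TP/FP flag per prediction, in descending-score order; each truth box
    matches at most one prediction."""
    order = sorted(
        range(len(pred)),
        key=lambda i: (-(pred[i].score if pred[i].score is not None else 1.0), i),
    )
    matched = [False] * len(truth)
    flags = [False] * len(pred)
    for i in order:
        best_j, best_iou = -1, thr
        for j, t in enumerate(truth):
            if matched[j]:
                continue
            v = box_iou(pred[i], t)
            if v >= best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            matched[best_j] = True
            flags[i] = True
    return [flags[i] for i in order]


def average_precision(tp_flags: list[bool], n_truth: int) -> float:
    """All-point-interpolated AP from TP/FP flags in descending-score order."""
    if n_truth == 0:
        return 1.0 if not tp_flags else 0.0
    if not tp_flags:
        return 0.0
    tp_cum = np.cumsum(tp_flags)
    fp_cum = np.cumsum(~np.asarray(tp_flags, dtype=bool))
    recall = tp_cum / n_truth
    precision = tp_cum / (tp_cum + fp_cum)
    # precision envelope + sum over recall increments
    mrec = np.concatenate([[0.0], recall, [recall[-1]]])
    mpre = np.concatenate([[0.0], precision, [0.0]])
    for i in range(len(mpre) - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    idx = np.nonzero(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


def det_eval(
    pred: list[BBox],
    truth: list[BBox],
    iou_match_threshold: float = 0.5,
) -> DetEvalReport:
    """Box-detection evaluation against ground truth boxes in one frame.

    Predictions are matched to truth greedily in descending score order; a
    match requires box IoU at or above ``iou_match_threshold`` and each
    truth box matches at most once. Precision = TP/(TP+FP), recall =
    TP/(TP+FN); ``map_standard`` is the all-point-interpolated AP and
    ``map_paper_style`` the plain mean of precision and recall.
    """
    frames = {b.frame_id for b in pred} | {b.frame_id for b in truth}
    if len(frames) > 1:
        raise ValueError(f"boxes span multiple frames: {sorted(frames)}")
    flags = _greedy_match(pred, truth, iou_match_threshold)
    tp = sum(flags)
    fp = len(pred) - tp
    fn = len(truth) - tp
    precision = tp / (tp + fp) if (tp + fp) else (1.0 if not truth else 0.0)
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    ap = average_precision(flags, len(truth))
    return DetEvalReport(
        precision=precision,
        recall=recall,
        map_standard=ap,
        map_paper_style=(precision + recall) / 2.0,
        iou_match_threshold=iou_match_threshold,
        tp=tp,
        fp=fp,
        fn=fn,
    )
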
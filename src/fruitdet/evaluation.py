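"""Detection metrics: precision/recall/F1 at the balance point, and AP.

Matching is greedy one-to-one in descending score order at a fixed IoU
threshold (default 0.5). AP is the area under the precision–recall
curve with all-point interpolation (the precision envelope); an
11-point variant is available for cross-checking. The balance point is
the confidence threshold where precision and recall are closest, which
is where the single-number P/R/F1 summary is taken.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import BoundingBox, Detection, ImageAnnotation, iou


@dataclass
class EvalResult:
    precision: float
    recall: float
    f1: float
    ap: float
    balance_threshold: float
    iou_threshold: float
    pr_curve: list[tuple[float, float, float]] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "ap": self.ap,
            "balance_threshold": self.balance_threshold,
            "iou_threshold": self.iou_threshold,
        }


def match_detections(
    dets: list[Detection],
    gts: list[BoundingBox],
    iou_threshold: float = 0.5,
) -> tuple[list[bool], int]:
    """Greedy one-to-one matching in score order.

    *dets* must be sorted by descending score. Returns a TP flag per
    detection and the count of ground-truth boxes left unmatched.
    """
    scores = [d.score for d in dets]
    if scores != sorted(scores, reverse=True):
        raise ValueError("detections must be sorted by descending score")
    matched = [False] * len(gts)
    flags = []
    for det in dets:
        best, best_iou = -1, 0.0
        for j, gt in enumerate(gts):
            if matched[j]:
                continue
            v = iou(det.box, gt)
            if v > best_iou:
                best, best_iou = j, v
        if best >= 0 and best_iou >= iou_threshold:
            matched[best] = True
            flags.append(True)
        else:
            flags.append(False)
    return flags, matched.count(False)


def _global_flags(
    dets_per_image: list[list[Detection]],
    gts_per_image: list[ImageAnnotation] | list[list[BoundingBox]],
    iou_threshold: float,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Pooled (score, tp) pairs sorted by descending score, plus GT total."""
    scores, flags = [], []
    n_gt = 0
    for dets, gts in zip(dets_per_image, gts_per_image, strict=True):
        boxes = gts.boxes if isinstance(gts, ImageAnnotation) else gts
        n_gt += len(boxes)
        dets = sorted(dets, key=lambda d: -d.score)
        tp, _ = match_detections(dets, boxes, iou_threshold)
        scores.extend(d.score for d in dets)
        flags.extend(tp)
    order = np.argsort(-np.asarray(scores), kind="stable") if scores else np.zeros(0, int)
    return (
        np.asarray(scores, dtype=np.float64)[order],
        np.asarray(flags, dtype=bool)[order],
        n_gt,
    )


def average_precision(
    dets_per_image: list[list[Detection]],
    gts_per_image,
    iou_threshold: float = 0.5,
    interpolation: str = "all_point",
) -> float:
    """AP over the whole test set at the given IoU threshold."""
    scores, tp, n_gt = _global_flags(dets_per_image, gts_per_image, iou_threshold)
    if n_gt == 0:
        raise ValueError("AP is undefined with zero ground-truth boxes")
    if len(scores) == 0:
        return 0.0
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(~tp)
    recall = cum_tp / n_gt
    precision = cum_tp / (cum_tp + cum_fp)
    if interpolation == "all_point":
        # precision envelope, integrated over recall increments
        env = np.maximum.accumulate(precision[::-1])[::-1]
        r_prev = np.concatenate([[0.0], recall[:-1]])
        return float(np.sum((recall - r_prev) * env))
    if interpolation == "11_point":
        return float(
            np.mean(
                [
                    precision[recall >= t].max() if np.any(recall >= t) else 0.0
                    for t in np.linspace(0.0, 1.0, 11)
                ]
            )
        )
    raise ValueError(f"unknown interpolation {interpolation!r}")


def pr_curve(
    dets_per_image, gts_per_image, iou_threshold: float = 0.5
) -> list[tuple[float, float, float]]:
    """(threshold, precision, recall) at every distinct detection score."""
    scores, tp, n_gt = _global_flags(dets_per_image, gts_per_image, iou_threshold)
    if n_gt == 0:
        raise ValueError("PR curve is undefined with zero ground-truth boxes")
    curve = []
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(~tp)
    # walk distinct scores; at threshold s all detections with score >= s count
    for i in range(len(scores)):
        if i + 1 < len(scores) and scores[i + 1] == scores[i]:
            continue
        p = cum_tp[i] / (cum_tp[i] + cum_fp[i])
        r = cum_tp[i] / n_gt
        curve.append((float(scores[i]), float(p), float(r)))
    return curve


def _f1(p: float, r: float) -> float:
    return 2 * p * r / (p + r) if (p + r) > 0 else 0.0


def balance_point(
    curve: list[tuple[float, float, float]]
) -> tuple[float, float, float, float]:
    """Threshold minimizing |P − R|; ties go to higher F1, then lower threshold.

    Returns (threshold, precision, recall, f1).
    """
    if not curve:
        raise ValueError("empty PR curve")
    best = min(curve, key=lambda t: (abs(t[1] - t[2]), -_f1(t[1], t[2]), t[0]))
    thr, p, r = best
    return thr, p, r, _f1(p, r)


def evaluate(
    dets_per_image: list[list[Detection]],
    gts_per_image,
    iou_threshold: float = 0.5,
    interpolation: str = "all_point",
) -> EvalResult:
    """End-to-end metric computation over matched detection/GT lists."""
    if not gts_per_image:
        raise ValueError("empty test set")
    ap = average_precision(dets_per_image, gts_per_image, iou_threshold, interpolation)
    curve = pr_curve(dets_per_image, gts_per_image, iou_threshold)
    if curve:
        thr, p, r, f1 = balance_point(curve)
    else:
        thr, p, r, f1 = 1.0, 0.0, 0.0, 0.0
    return EvalResult(p, r, f1, ap, thr, iou_threshold, curve)


def evaluate_files(
    label_path, gt_path, dialect: str = "coco", iou_threshold: float = 0.5
) -> EvalResult:
    """Audit exported label files against ground-truth annotation files.

    Exported labels carry no scores, so every pseudo-label counts with
    score 1.0; AP then reduces to precision at full output.
    """
    from .annotations import read_annotations

    labels = {a.image_id: a for a in read_annotations(label_path, dialect)}
    gts = read_annotations(gt_path, dialect)
    dets = [
        [Detection(b, 1.0) for b in labels.get(g.image_id, ImageAnnotation(g.image_id, g.width, g.height)).boxes]
        for g in gts
    ]
    return evaluate(dets, gts, iou_threshold)
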
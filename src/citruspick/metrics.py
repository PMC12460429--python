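"""Instance-segmentation evaluation: precision, recall, AP, mAP50, F1, and the
picking-point detection rate.

Definitions used throughout::

    Precision = TP / (TP + FP)        Recall = TP / (TP + FN)
    AP        = integral of P(R) dR   (all-point precision-envelope form)
    mAP       = mean of per-class AP  (N = 2 classes: fruit, stem)
    F1        = 2 P R / (P + R)

Matching is greedy in descending prediction confidence (ties broken by
ascending instance id): a prediction is a true positive when its best mask-IoU
against a not-yet-consumed same-class ground-truth instance reaches the IoU
threshold (0.5 by default); each truth is consumed at most once; leftover
truths are false negatives.  Zero-denominator conventions: P, R and F1 are 0
when their denominators are 0.

Because class-aggregation conventions differ between toolchains, the summary
report carries both the micro (pooled counts) and macro (mean of per-class
rates) aggregates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .labelio import InstanceMask


@dataclass
class ConfusionCounts:
    class_id: int
    TP: int = 0
    FP: int = 0
    FN: int = 0

    @property
    def precision(self) -> float:
        return self.TP / (self.TP + self.FP) if (self.TP + self.FP) else 0.0

    @property
    def recall(self) -> float:
        return self.TP / (self.TP + self.FN) if (self.TP + self.FN) else 0.0


@dataclass
class EvalReport:
    per_class: dict[int, dict[str, float]]
    mAP50: float
    precision: float  # micro-aggregated
    recall: float
    F1: float
    macro_precision: float
    macro_recall: float
    macro_F1: float
    n_classes: int
    pick_point_detection_rate: float | None = None

    def to_dict(self) -> dict:
        d = {
            "per_class": {str(k): v for k, v in self.per_class.items()},
            "mAP50": self.mAP50,
            "precision": self.precision,
            "recall": self.recall,
            "F1": self.F1,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_F1": self.macro_F1,
            "n_classes": self.n_classes,
        }
        if self.pick_point_detection_rate is not None:
            d["pick_point_detection_rate"] = self.pick_point_detection_rate
        return d


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two boolean masks of equal shape."""
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return float(inter) / float(union) if union else 0.0


def _f1(p: float, r: float) -> float:
    return 2.0 * p * r / (p + r) if (p + r) > 0 else 0.0


def match_instances(
    predictions: list[InstanceMask],
    truths: list[InstanceMask],
    iou_threshold: float = 0.5,
) -> tuple[dict[int, ConfusionCounts], dict[int, list[tuple[float, bool]]]]:
    """Greedy confidence-ordered matching of predicted to ground-truth instances.

    Returns per-class confusion counts and, for AP computation, the per-class
    ranked list of (confidence, is_TP) in match order.
    """
    all_masks = predictions + truths
    if all_masks:
        shape = all_masks[0].raster.shape
        for m in all_masks:
            if m.raster.shape != shape:
                raise ValueError("all masks must share the image dimensions")
    class_ids = sorted({m.class_id for m in predictions} | {m.class_id for m in truths})
    counts: dict[int, ConfusionCounts] = {}
    ranked: dict[int, list[tuple[float, bool]]] = {}
    for cid in class_ids:
        preds = sorted(
            (p for p in predictions if p.class_id == cid),
            key=lambda p: (-p.confidence, p.instance_id),
        )
        gts = [t for t in truths if t.class_id == cid]
        consumed = [False] * len(gts)
        cc = ConfusionCounts(class_id=cid)
        rk: list[tuple[float, bool]] = []
        for p in preds:
            best_iou, best_j = 0.0, -1
            for j, t in enumerate(gts):
                if consumed[j]:
                    continue
                iou = mask_iou(p.raster, t.raster)
                if iou > best_iou:
                    best_iou, best_j = iou, j
            if best_j >= 0 and best_iou >= iou_threshold:
                consumed[best_j] = True
                cc.TP += 1
                rk.append((p.confidence, True))
            else:
                cc.FP += 1
                rk.append((p.confidence, False))
        cc.FN = consumed.count(False)
        counts[cid] = cc
        ranked[cid] = rk
    return counts, ranked


def average_precision(ranked: list[tuple[float, bool]], n_truth: int) -> float:
    """Area under the precision-recall curve (all-point interpolation).

    `ranked` must be sorted by descending confidence.  Precision at each
    recall level is replaced by the maximum precision at any recall >= that
    level (the monotone precision envelope) before integrating over the
    recall steps.
    """
    if n_truth < 0:
        raise ValueError("n_truth must be >= 0")
    tp_total = sum(1 for _, is_tp in ranked if is_tp)
    if tp_total > n_truth:
        raise ValueError(f"TP count {tp_total} exceeds number of truths {n_truth}")
    if n_truth == 0:
        return 0.0
    if not ranked:
        return 0.0
    confidences = [c for c, _ in ranked]
    if any(c1 < c2 for c1, c2 in zip(confidences, confidences[1:])):
        raise ValueError("ranked list must be sorted by descending confidence")
    tps = np.cumsum([1 if is_tp else 0 for _, is_tp in ranked])
    fps = np.cumsum([0 if is_tp else 1 for _, is_tp in ranked])
    precision = tps / (tps + fps)
    recall = tps / n_truth
    # monotone non-increasing precision envelope
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    ap = 0.0
    prev_recall = 0.0
    for p, r in zip(envelope, recall):
        if r > prev_recall:
            ap += (r - prev_recall) * p
            prev_recall = r
    return float(ap)


def summarize(
    counts: dict[int, ConfusionCounts],
    aps: dict[int, float],
    pick_point_detection_rate: float | None = None,
) -> EvalReport:
    """Aggregate per-class counts and APs into a single evaluation report."""
    per_class = {
        cid: {"precision": cc.precision, "recall": cc.recall, "AP": aps.get(cid, 0.0)}
        for cid, cc in counts.items()
    }
    n = len(counts)
    tp = sum(c.TP for c in counts.values())
    fp = sum(c.FP for c in counts.values())
    fn = sum(c.FN for c in counts.values())
    p = tp / (tp + fp) if (tp + fp) else 0.0
    r = tp / (tp + fn) if (tp + fn) else 0.0
    macro_p = float(np.mean([c.precision for c in counts.values()])) if n else 0.0
    macro_r = float(np.mean([c.recall for c in counts.values()])) if n else 0.0
    return EvalReport(
        per_class=per_class,
        mAP50=float(np.mean(list(aps.values()))) if aps else 0.0,
        precision=p,
        recall=r,
        F1=_f1(p, r),
        macro_precision=macro_p,
        macro_recall=macro_r,
        macro_F1=_f1(macro_p, macro_r),
        n_classes=n,
        pick_point_detection_rate=pick_point_detection_rate,
    )


def evaluate_instances(
    predictions: list[InstanceMask],
    truths: list[InstanceMask],
    iou_threshold: float = 0.5,
    pick_point_detection_rate: float | None = None,
) -> EvalReport:
    """Convenience wrapper: match, per-class AP, then summarize."""
    counts, ranked = match_instances(predictions, truths, iou_threshold)
    n_truth = {cid: cc.TP + cc.FN for cid, cc in counts.items()}
    aps = {cid: average_precision(ranked[cid], n_truth[cid]) for cid in counts}
    return summarize(counts, aps, pick_point_detection_rate)


def pick_point_detection_rate(
    predicted_points: dict[int, tuple[float, float]],
    truth_points: dict[int, tuple[float, float]],
    tolerance: float = 5.0,
) -> float:
    """Fraction of ground-truth picking points recovered within a pixel tolerance.

    Points are keyed by stem id; a truth point counts as detected when the
    prediction for the same stem lies within `tolerance` pixels.  Each
    prediction is consumed at most once (ids are unique keys, so this holds by
    construction).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if not truth_points:
        return 0.0
    hits = 0
    for stem_id, (tx, ty) in truth_points.items():
        pred = predicted_points.get(stem_id)
        if pred is None:
            continue
        if np.hypot(pred[0] - tx, pred[1] - ty) <= tolerance:
            hits += 1
    return hits / len(truth_points)
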
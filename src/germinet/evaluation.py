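"""Detection evaluation: greedy IoU matching, precision/recall, COCO-style
average precision, the missed/false-alarm/repeated error taxonomy, and a
class-vs-class confusion matrix.

Detections are (box, class_id, confidence) with normalized (cx, cy, w, h)
boxes; ground truths are (box, class_id).  Both plain tuples and objects
with ``box``/``class_id``/``confidence`` attributes are accepted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

COCO_IOU_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


def _det(d):
    if hasattr(d, "box"):
        return tuple(d.box), int(d.class_id), float(d.confidence)
    box, cls, conf = d
    return tuple(box), int(cls), float(conf)


def _gt(g):
    if hasattr(g, "box"):
        return tuple(g.box), int(g.class_id)
    box, cls = g
    return tuple(box), int(cls)


def box_iou(a, b) -> float:
    """IoU of two (cx, cy, w, h) boxes."""
    ax1, ay1 = a[0] - a[2] / 2, a[1] - a[3] / 2
    ax2, ay2 = a[0] + a[2] / 2, a[1] + a[3] / 2
    bx1, by1 = b[0] - b[2] / 2, b[1] - b[3] / 2
    bx2, by2 = b[0] + b[2] / 2, b[1] + b[3] / 2
    iw = max(0.0, min(ax2, bx2) - max(ax1, bx1))
    ih = max(0.0, min(ay2, by2) - max(ay1, by1))
    inter = iw * ih
    union = a[2] * a[3] + b[2] * b[3] - inter
    return inter / union if union > 0 else 0.0


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    det_flags: list[str]          # per detection: "tp" | "repeated" | "false_alarm"
    det_gt: list[int]             # matched gt index or -1
    unmatched_gt: list[int]


@dataclass
class ErrorTally:
    """Error taxonomy over a batch of dish images."""

    missed: int
    false_alarm: int
    repeated: int
    n_images: int
    seeds_per_image: int
    error_rate: float = field(init=False)

    def __post_init__(self):
        if self.seeds_per_image <= 0:
            raise ValueError("seeds_per_image must be positive")
        total = self.missed + self.false_alarm + self.repeated
        self.error_rate = total / (self.n_images * self.seeds_per_image)


@dataclass
class EvalResult:
    per_class: dict[int, dict]
    precision: float
    recall: float
    map50: float
    map50_95: float


def match_detections(dets, gts, iou_threshold: float = 0.5) -> MatchResult:
    """Greedy confidence-ordered one-to-one matching at IoU >= threshold.

    Class-aware: a detection can only consume a ground truth of its own
    class.  A second detection hitting an already-consumed ground truth is
    a false positive flagged ``repeated``; an unmatched detection that
    overlaps no consumed ground truth is a ``false_alarm``.
    """
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError("iou threshold must lie in (0, 1)")
    dets = sorted((_det(d) for d in dets), key=lambda d: -d[2])
    gts = [_gt(g) for g in gts]
    consumed = [False] * len(gts)
    flags, det_gt = [], []
    for box, cls, _ in dets:
        best, best_iou = -1, iou_threshold
        overlap_consumed = False
        for j, (gbox, gcls) in enumerate(gts):
            if gcls != cls:
                continue
            iou = box_iou(box, gbox)
            if iou >= iou_threshold and consumed[j]:
                overlap_consumed = True
            if not consumed[j] and iou >= best_iou:
                best, best_iou = j, iou
        if best >= 0:
            consumed[best] = True
            flags.append("tp")
            det_gt.append(best)
        else:
            flags.append("repeated" if overlap_consumed else "false_alarm")
            det_gt.append(-1)
    tp = flags.count("tp")
    unmatched = [j for j, c in enumerate(consumed) if not c]
    return MatchResult(tp, len(dets) - tp, len(unmatched), flags, det_gt, unmatched)


def precision_recall(tp: int, fp: int, fn: int) -> tuple[float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN); empty-prediction convention P = 1."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    p = tp / (tp + fp) if tp + fp else 1.0
    r = tp / (tp + fn) if tp + fn else 0.0
    return p, r


def _per_image(x):
    """Validate a per-image list-of-lists argument."""
    if not isinstance(x, (list, tuple)):
        raise TypeError("expected a list of per-image lists")
    return [list(img) for img in x]


def _ap_from_flags(flags: np.ndarray, n_gt: int) -> float:
    """101-point interpolated area under the precision-recall envelope."""
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(1 - flags)
    recall = tp_cum / n_gt
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1)
    grid = np.linspace(0, 1, 101)
    ap = 0.0
    for r in grid:
        mask = recall >= r - 1e-12
        ap += precision[mask].max() if mask.any() else 0.0
    return ap / len(grid)


def average_precision(dets, gts, iou_threshold: float = 0.5,
                      class_id: int | None = None) -> float:
    """AP over a set of images; class-aware (wrong-class hits are FPs).

    ``dets``/``gts`` are per-image lists: for a single image pass
    ``[dets], [gts]``."""
    det_imgs, gt_imgs = _per_image(dets), _per_image(gts)
    if len(det_imgs) != len(gt_imgs):
        raise ValueError("detections and ground truths must cover the same images")
    if class_id is not None:
        det_imgs = [[d for d in ds if _det(d)[1] == class_id] for ds in det_imgs]
        gt_imgs = [[g for g in gs if _gt(g)[1] == class_id] for gs in gt_imgs]
    n_gt = sum(len(g) for g in gt_imgs)
    if n_gt == 0:
        warnings.warn("no ground truth boxes: AP undefined")
        return float("nan")
    records = []  # (confidence, is_tp)
    for ds, gs in zip(det_imgs, gt_imgs):
        res = match_detections(ds, gs, iou_threshold)
        confs = sorted((_det(d)[2] for d in ds), reverse=True)
        for conf, flag in zip(confs, res.det_flags):
            records.append((conf, 1 if flag == "tp" else 0))
    if not records:
        return 0.0
    records.sort(key=lambda r: -r[0])
    flags = np.array([r[1] for r in records])
    return _ap_from_flags(flags, n_gt)


def mean_ap(dets, gts, thresholds=COCO_IOU_THRESHOLDS) -> tuple[float, float]:
    """(mAP@0.5, mAP@[0.5:0.95]) averaged over the classes present in gts."""
    gt_imgs = _per_image(gts)
    classes = sorted({_gt(g)[1] for gs in gt_imgs for g in gs})
    if not classes:
        raise ValueError("no ground-truth objects; mAP undefined")
    ap50 = [average_precision(dets, gts, 0.5, c) for c in classes]
    ap_all = [
        np.mean([average_precision(dets, gts, t, c) for t in thresholds])
        for c in classes
    ]
    return float(np.mean(ap50)), float(np.mean(ap_all))


def evaluate(dets, gts, iou_threshold: float = 0.5) -> EvalResult:
    """Aggregate P/R (at the given IoU) and COCO-style mAP over images."""
    det_imgs, gt_imgs = _per_image(dets), _per_image(gts)
    classes = sorted({_gt(g)[1] for gs in gt_imgs for g in gs})
    per_class = {}
    tp = fp = fn = 0
    for c in classes:
        ctp = cfp = cfn = 0
        for ds, gs in zip(det_imgs, gt_imgs):
            res = match_detections(
                [d for d in ds if _det(d)[1] == c],
                [g for g in gs if _gt(g)[1] == c],
                iou_threshold,
            )
            ctp, cfp, cfn = ctp + res.tp, cfp + res.fp, cfn + res.fn
        p, r = precision_recall(ctp, cfp, cfn)
        per_class[c] = {
            "tp": ctp, "fp": cfp, "fn": cfn, "precision": p, "recall": r,
            "ap50": average_precision(dets, gts, 0.5, c),
        }
        tp, fp, fn = tp + ctp, fp + cfp, fn + cfn
    p, r = precision_recall(tp, fp, fn)
    map50, map5095 = mean_ap(dets, gts)
    return EvalResult(per_class, p, r, map50, map5095)


def error_taxonomy(dets, gts, n_images: int, seeds_per_image: int,
                   iou_threshold: float = 0.5) -> ErrorTally:
    """Tally missed detections, false alarms, and repeated detections."""
    det_imgs, gt_imgs = _per_image(dets), _per_image(gts)
    missed = false_alarm = repeated = 0
    for ds, gs in zip(det_imgs, gt_imgs):
        res = match_detections(ds, gs, iou_threshold)
        missed += len(res.unmatched_gt)
        repeated += res.det_flags.count("repeated")
        false_alarm += res.det_flags.count("false_alarm")
    return ErrorTally(missed, false_alarm, repeated, n_images, seeds_per_image)


def confusion_matrix(dets, gts, n_classes: int = 2,
                     iou_threshold: float = 0.5) -> np.ndarray:
    """(n_classes+1) x (n_classes+1) counts; rows = predicted, cols = true.

    The last row/column is background: unmatched ground truths land in the
    background row, unlocalized detections in the background column.
    Same-class matches are assigned first, then remaining detections may
    match remaining ground truths across classes (off-diagonal cells).
    """
    det_imgs, gt_imgs = _per_image(dets), _per_image(gts)
    bg = n_classes
    cm = np.zeros((n_classes + 1, n_classes + 1), dtype=int)
    for ds, gs in zip(det_imgs, gt_imgs):
        ds = [_det(d) for d in ds]
        gs = [_gt(g) for g in gs]
        res = match_detections(ds, gs, iou_threshold)
        order = sorted(range(len(ds)), key=lambda i: -ds[i][2])
        leftover_gt = set(res.unmatched_gt)
        for flag, gi, di in zip(res.det_flags, res.det_gt, order):
            box, cls, _ = ds[di]
            if flag == "tp":
                cm[cls, gs[gi][1]] += 1
                continue
            # second pass: cross-class localization
            best, best_iou = -1, iou_threshold
            for j in leftover_gt:
                iou = box_iou(box, gs[j][0])
                if iou >= best_iou:
                    best, best_iou = j, iou
            if best >= 0:
                leftover_gt.discard(best)
                cm[cls, gs[best][1]] += 1
            else:
                cm[cls, bg] += 1
        for j in leftover_gt:
            cm[bg, gs[j][1]] += 1
    return cm
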
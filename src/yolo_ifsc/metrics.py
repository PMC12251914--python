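"""Detection evaluation: greedy IoU matching, precision/recall/F1,
per-class average precision as the continuous area under the monotone
precision envelope, and mAP@0.5.

Matching follows the standard protocol: within each class, detections are
taken in descending confidence order (ties broken by input order) and each
is matched to the unmatched ground truth with the highest IoU at or above
the threshold (ties broken by the smaller ground-truth index).  Unmatched
detections count as false positives, unmatched ground truths as false
negatives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .network import Detection, box_iou

__all__ = ["ConfusionCounts", "PRCurve", "EvalReport", "match_detections",
           "compute_pr_ap", "compute_map", "precision_recall_f1", "evaluate"]


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0


@dataclass
class PRCurve:
    recall: np.ndarray
    precision: np.ndarray
    ap: float


@dataclass
class EvalReport:
    per_class: dict = field(default_factory=dict)   # class -> dict(P,R,F1,AP,n_gt)
    map50: float = 0.0

    def as_json(self) -> dict:
        return {"mAP50": self.map50,
                "per_class": {str(k): v for k, v in self.per_class.items()}}


def _sorted_dets(dets):
    return sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))


def match_detections(preds, gts, iou_thr: float = 0.5) -> dict:
    """Per-class confusion counts for one image.

    ``preds``/``gts`` are lists of :class:`Detection` / objects exposing
    ``class_id`` and ``xyxy()``.
    """
    if not 0.0 < iou_thr <= 1.0:
        raise ValueError("iou_thr must lie in (0, 1]")
    counts: dict = {}
    classes = {p.class_id for p in preds} | {g.class_id for g in gts}
    for c in classes:
        cp = [p for p in preds if p.class_id == c]
        cg = [g for g in gts if g.class_id == c]
        cc = counts.setdefault(c, ConfusionCounts())
        matched = [False] * len(cg)
        for i in _sorted_dets(cp):
            best, best_iou = -1, iou_thr
            for j, g in enumerate(cg):
                if matched[j]:
                    continue
                iou = box_iou(cp[i].xyxy(), g.xyxy())
                if iou > best_iou or (iou == best_iou and best == -1 and iou >= iou_thr):
                    best, best_iou = j, iou
            if best >= 0:
                matched[best] = True
                cc.tp += 1
            else:
                cc.fp += 1
        cc.fn += matched.count(False)
    return counts


def compute_pr_ap(is_tp, confidences, n_gt: int) -> PRCurve:
    """AP from a ranked detection list of one class.

    ``is_tp``/``confidences`` are parallel sequences over all detections of
    the class (all images pooled); ``n_gt`` is the number of ground-truth
    instances.  Precision is made monotone non-increasing (the envelope) and
    AP is the exact area under the envelope polyline.
    """
    if n_gt < 1:
        raise ValueError("AP undefined without ground truths")
    is_tp = np.asarray(is_tp, dtype=bool)
    conf = np.asarray(confidences, dtype=float)
    order = np.lexsort((np.arange(len(conf)), -conf))
    is_tp = is_tp[order]
    tp_cum = np.cumsum(is_tp)
    fp_cum = np.cumsum(~is_tp)
    recall = tp_cum / n_gt
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1)
    # monotone envelope from the right
    env = np.maximum.accumulate(precision[::-1])[::-1]
    # area under the step function of the envelope over recall
    r_prev = 0.0
    ap = 0.0
    for r, p in zip(recall, env):
        if r > r_prev:
            ap += (r - r_prev) * p
            r_prev = r
    return PRCurve(recall, precision, float(ap))


def compute_map(per_class_ap) -> float:
    """Arithmetic mean of the defined per-class APs."""
    aps = list(per_class_ap.values()) if isinstance(per_class_ap, dict) else list(per_class_ap)
    if not aps:
        raise ValueError("no class with a defined AP")
    return float(np.mean(aps))


def precision_recall_f1(cc: ConfusionCounts):
    """P, R and their harmonic mean, with 0/0 defined as 0."""
    p = cc.tp / (cc.tp + cc.fp) if cc.tp + cc.fp else 0.0
    r = cc.tp / (cc.tp + cc.fn) if cc.tp + cc.fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def evaluate(preds_per_image, gts_per_image, iou_thr: float = 0.5) -> EvalReport:
    """Corpus-level evaluation: pooled per-class PR sweeps and mAP@0.5."""
    classes = set()
    for preds, gts in zip(preds_per_image, gts_per_image):
        classes |= {g.class_id for g in gts} | {p.class_id for p in preds}
    report = EvalReport()
    aps = {}
    for c in sorted(classes):
        flags, confs = [], []
        n_gt = 0
        agg = ConfusionCounts()
        for preds, gts in zip(preds_per_image, gts_per_image):
            cp = [p for p in preds if p.class_id == c]
            cg = [g for g in gts if g.class_id == c]
            n_gt += len(cg)
            matched = [False] * len(cg)
            for i in _sorted_dets(cp):
                best, best_iou = -1, iou_thr
                for j, g in enumerate(cg):
                    if not matched[j]:
                        iou = box_iou(cp[i].xyxy(), g.xyxy())
                        if iou >= iou_thr and (best == -1 or iou > best_iou):
                            best, best_iou = j, iou
                if best >= 0:
                    matched[best] = True
                    flags.append(True)
                else:
                    flags.append(False)
                confs.append(cp[i].confidence)
            agg.tp += matched.count(True)
            agg.fp += len(cp) - matched.count(True)
            agg.fn += matched.count(False)
        if n_gt == 0:
            warnings.warn(f"class {c} has no ground truth; excluded from mAP")
            continue
        curve = compute_pr_ap(flags, confs, n_gt)
        p, r, f1 = precision_recall_f1(agg)
        report.per_class[c] = {"P": p, "R": r, "F1": f1, "AP": curve.ap, "n_gt": n_gt}
        aps[c] = curve.ap
    report.map50 = compute_map(aps) if aps else 0.0
    return report
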
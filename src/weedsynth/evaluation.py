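"""Detection and segmentation scoring with 11-point interpolated AP.

Matching follows the community-standard greedy protocol: within each class
and image, detections are ranked by descending confidence and each is
matched to the unmatched ground truth of the same class with the highest
IoU; the match is a true positive iff IoU >= threshold (0.5 by default),
otherwise a false positive, and a detection landing on an already-claimed
ground truth is a false positive. Unmatched ground truths are false
negatives.

AP per class is the 11-point interpolation of the precision-recall curve,

    AP = (1/11) * sum over r in {0.0, 0.1, ..., 1.0} of p_max(r),

where p_max(r) is the maximum precision at any operating point whose
recall is >= r (0 when no such point exists). mAP is the unweighted mean
of AP over classes with at least one ground truth — reported separately
for bounding boxes (mAP_b) and masks (mAP_m).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coco_io import AnnotationSet, decode_segmentation

__all__ = [
    "Detection",
    "MatchTally",
    "PRCurve",
    "APResult",
    "iou_bbox",
    "iou_mask",
    "match_detections",
    "interpolated_ap",
    "evaluate",
]

RECALL_LEVELS = np.linspace(0.0, 1.0, 11)


@dataclass
class Detection:
    """A scored model output: box, optional mask, confidence in [0, 1]."""

    image_id: int
    category_id: int
    score: float
    bbox: list[float]
    segmentation: object | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")
        if self.bbox[2] <= 0 or self.bbox[3] <= 0:
            raise ValueError(f"bbox {self.bbox} must have positive width and height")


@dataclass
class MatchTally:
    """TP/FP/FN counts per class; TP + FN equals the ground-truth count."""

    tp: dict[int, int] = field(default_factory=dict)
    fp: dict[int, int] = field(default_factory=dict)
    fn: dict[int, int] = field(default_factory=dict)


@dataclass
class PRCurve:
    """Operating points along the score-ranked detection list."""

    recalls: np.ndarray
    precisions: np.ndarray
    total_gt: int


@dataclass
class APResult:
    """Per-class AP and the class-mean mAP for boxes and masks."""

    ap_bbox: dict[int, float]
    ap_mask: dict[int, float]
    map_bbox: float
    map_mask: float | None
    iou_threshold: float = 0.5


def iou_bbox(a: list[float], b: list[float]) -> float:
    """Intersection-over-union of two [x, y, w, h] boxes."""
    ax0, ay0, aw, ah = a
    bx0, by0, bw, bh = b
    ix0, iy0 = max(ax0, bx0), max(ay0, by0)
    ix1, iy1 = min(ax0 + aw, bx0 + bw), min(ay0 + ah, by0 + bh)
    iw, ih = max(0.0, ix1 - ix0), max(0.0, iy1 - iy0)
    inter = iw * ih
    union = aw * ah + bw * bh - inter
    return inter / union if union > 0 else 0.0


def iou_mask(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two boolean masks; 0 when both empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask extents differ: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    return np.count_nonzero(a & b) / union


def _gt_by_image_class(gt: AnnotationSet) -> dict[tuple[int, int], list[dict]]:
    groups: dict[tuple[int, int], list[dict]] = {}
    for ann in gt.annotations:
        groups.setdefault((ann["image_id"], ann["category_id"]), []).append(ann)
    return groups


def match_detections(
    dets: list[Detection],
    gt: AnnotationSet,
    iou_threshold: float = 0.5,
    mode: str = "bbox",
) -> tuple[MatchTally, dict[int, list[tuple[float, bool]]]]:
    """Greedy one-to-one matching of detections to ground truth.

    Returns the per-class tally and, per class, the score-ranked list of
    (score, is_tp) labels from which PR curves are built. Ties in score
    keep input order; ties in IoU go to the lowest ground-truth id.
    """
    if mode not in ("bbox", "mask"):
        raise ValueError("mode must be 'bbox' or 'mask'")
    sizes = {im["id"]: (im["height"], im["width"]) for im in gt.images}
    groups = _gt_by_image_class(gt)

    # stable sort on negative score preserves input order among ties
    order = sorted(range(len(dets)), key=lambda i: -dets[i].score)
    matched: set[int] = set()  # id() keys of claimed gt records
    labels: dict[int, list[tuple[float, bool]]] = {}
    tally = MatchTally()
    claimed: dict[tuple[int, int], set[int]] = {}

    for i in order:
        det = dets[i]
        key = (det.image_id, det.category_id)
        candidates = groups.get(key, [])
        claimed_set = claimed.setdefault(key, set())
        best_iou, best_j = 0.0, None
        for j, ann in enumerate(candidates):
            if j in claimed_set:
                continue
            if mode == "bbox":
                iou = iou_bbox(det.bbox, ann["bbox"])
            else:
                if det.segmentation is None or ann.get("segmentation") is None:
                    continue
                h, w = sizes[det.image_id]
                iou = iou_mask(
                    decode_segmentation(det.segmentation, h, w),
                    decode_segmentation(ann["segmentation"], h, w),
                )
            if iou > best_iou or (
                iou == best_iou
                and best_j is not None
                and iou > 0
                and ann["id"] < candidates[best_j]["id"]
            ):
                best_iou, best_j = iou, j
        is_tp = best_j is not None and best_iou >= iou_threshold
        if is_tp:
            claimed_set.add(best_j)
        labels.setdefault(det.category_id, []).append((det.score, is_tp))

    gt_counts: dict[int, int] = {}
    for (img, cat), anns in groups.items():
        gt_counts[cat] = gt_counts.get(cat, 0) + len(anns)
    for cat in set(gt_counts) | set(labels):
        tp = sum(1 for _, ok in labels.get(cat, []) if ok)
        fp = sum(1 for _, ok in labels.get(cat, []) if not ok)
        tally.tp[cat] = tp
        tally.fp[cat] = fp
        tally.fn[cat] = gt_counts.get(cat, 0) - tp
    return tally, labels


def pr_curve(labels: list[tuple[float, bool]], total_gt: int) -> PRCurve:
    """Precision/recall at each prefix of the score-ranked detections."""
    if total_gt <= 0:
        raise ValueError("PR curve undefined without ground truth")
    tps = np.cumsum([1 if ok else 0 for _, ok in labels])
    fps = np.cumsum([0 if ok else 1 for _, ok in labels])
    n = np.arange(1, len(labels) + 1)
    precisions = tps / n if len(labels) else np.array([])
    recalls = tps / total_gt if len(labels) else np.array([])
    return PRCurve(recalls=recalls, precisions=precisions, total_gt=total_gt)


def interpolated_ap(curve: PRCurve) -> float:
    """11-point interpolated average precision of a PR curve."""
    if curve.total_gt <= 0:
        raise ValueError("AP undefined for a class without ground truth")
    ap = 0.0
    for r in RECALL_LEVELS:
        sel = curve.recalls >= r - 1e-12
        ap += float(curve.precisions[sel].max()) if np.any(sel) else 0.0
    return ap / 11.0


def evaluate(
    dets: list[Detection], gt: AnnotationSet, iou_threshold: float = 0.5
) -> APResult:
    """Per-class AP and mAP for boxes and (when masks are present) masks.

    Classes absent from the ground truth are excluded from the mean;
    the result is invariant to the input order of detections.
    """
    gt_counts: dict[int, int] = {}
    for ann in gt.annotations:
        gt_counts[ann["category_id"]] = gt_counts.get(ann["category_id"], 0) + 1

    def _aps(mode: str) -> dict[int, float]:
        _, labels = match_detections(dets, gt, iou_threshold, mode=mode)
        out = {}
        for cat, total in gt_counts.items():
            out[cat] = interpolated_ap(pr_curve(labels.get(cat, []), total))
        return out

    ap_b = _aps("bbox")
    have_masks = any(d.segmentation is not None for d in dets) and any(
        a.get("segmentation") is not None for a in gt.annotations
    )
    ap_m = _aps("mask") if have_masks else {}
    map_b = float(np.mean(list(ap_b.values()))) if ap_b else 0.0
    map_m = float(np.mean(list(ap_m.values()))) if ap_m else None
    return APResult(
        ap_bbox=ap_b, ap_mask=ap_m, map_bbox=map_b, map_mask=map_m,
        iou_threshold=iou_threshold,
    )
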
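"""Detection scoring: IoU, greedy matching, 11-point interpolated AP."""

import numpy as np
import pytest

from weedsynth.coco_io import AnnotationSet, encode_rle
from weedsynth.evaluation import (
    Detection,
    PRCurve,
    evaluate,
    interpolated_ap,
    iou_bbox,
    iou_mask,
    match_detections,
    pr_curve,
)

RECALLS = [i / 10 for i in range(11)]


def ap_brute_force(labels, total_gt):
    """Oracle: direct scan of every curve point at each recall level."""
    points = []
    tp = fp = 0
    for _, ok in labels:
        tp, fp = tp + ok, fp + (not ok)
        points.append((tp / total_gt, tp / (tp + fp)))
    total = 0.0
    for r in RECALLS:
        pmax = 0.0
        for rec, prec in points:
            if rec >= r - 1e-12 and prec > pmax:
                pmax = prec
        total += pmax
    return total / 11


def _gt(boxes_by_image, height=128, width=128, with_masks=False):
    """boxes_by_image: {image_id: [(category, [x,y,w,h]), ...]}"""
    images, anns = [], []
    ann_id = 1
    for img_id, boxes in boxes_by_image.items():
        images.append({"id": img_id, "file_name": f"{img_id}.png",
                       "height": height, "width": width})
        for cat, bbox in boxes:
            ann = {"id": ann_id, "image_id": img_id, "category_id": cat,
                   "bbox": [float(v) for v in bbox],
                   "area": bbox[2] * bbox[3], "iscrowd": 0}
            if with_masks:
                m = np.zeros((height, width), dtype=bool)
                x, y, w, h = (int(v) for v in bbox)
                m[y : y + h, x : x + w] = True
                ann["segmentation"] = encode_rle(m)
            anns.append(ann)
            ann_id += 1
    return AnnotationSet(images=images, annotations=anns)


# ------------------------------------------------------------------ IoU

@pytest.mark.parametrize(
    "a, b, expected",
    [
        ([0, 0, 10, 10], [0, 0, 10, 10], 1.0),
        ([0, 0, 10, 10], [20, 20, 5, 5], 0.0),
        ([0, 0, 10, 10], [5, 0, 10, 10], 1 / 3),
    ],
)
def test_iou_bbox_cases(a, b, expected):
    assert iou_bbox(a, b) == pytest.approx(expected)
    assert iou_bbox(b, a) == pytest.approx(expected)


def test_iou_mask_cases():
    a = np.zeros((8, 8), dtype=bool)
    a[2:6, 2:6] = True
    assert iou_mask(a, a) == 1.0
    assert iou_mask(a, ~a) == 0.0
    assert iou_mask(np.zeros((4, 4), bool), np.zeros((4, 4), bool)) == 0.0
    with pytest.raises(ValueError):
        iou_mask(a, np.zeros((4, 4), bool))


@pytest.mark.parametrize("seed", range(5))
def test_iou_mask_matches_pixel_loop(seed):
    rng = np.random.default_rng(seed)
    a = rng.random((64, 64)) < 0.3
    b = rng.random((64, 64)) < 0.3
    inter = union = 0
    for i in range(64):
        for j in range(64):
            inter += a[i, j] and b[i, j]
            union += a[i, j] or b[i, j]
    assert iou_mask(a, b) == pytest.approx(inter / union)


# ------------------------------------------------------------- matching

def test_perfect_detections_all_tp():
    gt = _gt({1: [(1, [10, 10, 20, 20]), (2, [50, 50, 20, 20])]})
    dets = [Detection(1, 1, 1.0, [10, 10, 20, 20]),
            Detection(1, 2, 1.0, [50, 50, 20, 20])]
    tally, _ = match_detections(dets, gt)
    assert tally.tp == {1: 1, 2: 1}
    assert tally.fp == {1: 0, 2: 0} and tally.fn == {1: 0, 2: 0}


def test_no_detections_all_fn():
    gt = _gt({1: [(1, [10, 10, 20, 20]), (1, [60, 60, 10, 10])]})
    tally, _ = match_detections([], gt)
    assert tally.fn == {1: 2}


def test_double_detection_second_is_fp():
    gt = _gt({1: [(1, [10, 10, 20, 20])]})
    dets = [Detection(1, 1, 0.9, [10, 10, 20, 20]),
            Detection(1, 1, 0.8, [11, 11, 20, 20])]
    tally, labels = match_detections(dets, gt)
    assert tally.tp == {1: 1} and tally.fp == {1: 1}
    assert labels[1][0] == (0.9, True) and labels[1][1] == (0.8, False)


def test_low_iou_match_is_fp():
    gt = _gt({1: [(1, [0, 0, 10, 10])]})
    dets = [Detection(1, 1, 0.9, [8, 8, 10, 10])]  # IoU well below 0.5
    tally, _ = match_detections(dets, gt)
    assert tally.tp == {1: 0} and tally.fp == {1: 1} and tally.fn == {1: 1}


def test_mask_mode_uses_mask_iou():
    gt = _gt({1: [(1, [10, 10, 20, 20])]}, with_masks=True)
    m = np.zeros((128, 128), dtype=bool)
    m[10:30, 10:30] = True
    dets = [Detection(1, 1, 0.9, [10, 10, 20, 20], segmentation=encode_rle(m))]
    tally, _ = match_detections(dets, gt, mode="mask")
    assert tally.tp == {1: 1}


# ---------------------------------------------------------------- 11-pt AP

def test_ap_perfect_and_empty():
    assert interpolated_ap(pr_curve([(1.0, True)] * 4, 4)) == pytest.approx(1.0)
    assert interpolated_ap(pr_curve([], 3)) == 0.0
    assert interpolated_ap(pr_curve([(0.9, False)] * 5, 3)) == 0.0


def test_ap_worked_example_two_gt():
    """2 ground truths, ranked TP then FP: points (0.5, 1.0), (0.5, 0.5);
    p_max is 1 at recall levels 0-0.5 and 0 above -> AP = 6/11."""
    labels = [(0.9, True), (0.8, False)]
    assert interpolated_ap(pr_curve(labels, 2)) == pytest.approx(6 / 11)
    assert ap_brute_force(labels, 2) == pytest.approx(6 / 11)


def test_ap_undefined_without_ground_truth():
    with pytest.raises(ValueError):
        interpolated_ap(PRCurve(np.array([]), np.array([]), total_gt=0))


def test_ap_matches_brute_force_on_random_rankings():
    """Oracle equivalence on 500 random ranked label sequences."""
    rng = np.random.default_rng(42)
    for _ in range(500):
        total_gt = int(rng.integers(1, 12))
        n_det = int(rng.integers(0, 20))
        n_tp = int(rng.integers(0, min(total_gt, n_det) + 1)) if n_det else 0
        flags = np.zeros(n_det, dtype=bool)
        flags[:n_tp] = True
        rng.shuffle(flags)
        scores = np.sort(rng.random(n_det))[::-1]
        labels = list(zip(scores.tolist(), flags.tolist()))
        assert interpolated_ap(pr_curve(labels, total_gt)) == pytest.approx(
            ap_brute_force(labels, total_gt)
        )


def test_relabeling_fp_to_tp_never_decreases_ap(rng):
    for _ in range(50):
        n = int(rng.integers(2, 10))
        flags = rng.random(n) < 0.5
        labels = [(1 - i / n, bool(f)) for i, f in enumerate(flags)]
        total_gt = int(flags.sum()) + int(rng.integers(1, 4))
        base = interpolated_ap(pr_curve(labels, total_gt))
        fps = [i for i, (_, f) in enumerate(labels) if not f]
        if not fps:
            continue
        i = fps[0]
        promoted = labels.copy()
        promoted[i] = (promoted[i][0], True)
        assert interpolated_ap(pr_curve(promoted, total_gt)) >= base - 1e-12


# ---------------------------------------------------------------- evaluate

def test_evaluate_perfect_three_class_fixture():
    gt = _gt({1: [(1, [5, 5, 20, 20]), (2, [40, 40, 20, 20]), (3, [80, 80, 20, 20])],
              2: [(1, [5, 5, 20, 20])]}, with_masks=True)
    dets = [
        Detection(a["image_id"], a["category_id"], 1.0, a["bbox"],
                  segmentation=a["segmentation"])
        for a in gt.annotations
    ]
    result = evaluate(dets, gt)
    assert result.map_bbox == pytest.approx(1.0)
    assert result.map_mask == pytest.approx(1.0)
    assert set(result.ap_bbox) == {1, 2, 3}


def test_evaluate_empty_detections_is_zero():
    gt = _gt({1: [(1, [5, 5, 20, 20])]})
    result = evaluate([], gt)
    assert result.map_bbox == 0.0


def test_evaluate_excludes_absent_classes_from_mean():
    gt = _gt({1: [(1, [5, 5, 20, 20]), (2, [40, 40, 20, 20])]})
    dets = [Detection(1, 1, 0.9, [5, 5, 20, 20])]
    result = evaluate(dets, gt)
    assert set(result.ap_bbox) == {1, 2}  # class 3 absent everywhere
    assert result.map_bbox == pytest.approx((1.0 + 0.0) / 2)


def test_evaluate_invariant_to_detection_order(rng):
    gt = _gt({1: [(1, [5, 5, 20, 20]), (1, [50, 50, 20, 20]),
                  (2, [90, 90, 20, 20])]})
    dets = [
        Detection(1, 1, 0.9, [5, 5, 20, 20]),
        Detection(1, 1, 0.7, [49, 49, 20, 20]),
        Detection(1, 1, 0.6, [5, 6, 20, 20]),
        Detection(1, 2, 0.8, [90, 90, 20, 20]),
    ]
    base = evaluate(dets, gt)
    for _ in range(5):
        shuffled = list(dets)
        rng.shuffle(shuffled)
        got = evaluate(shuffled, gt)
        assert got.map_bbox == pytest.approx(base.map_bbox)
        assert got.ap_bbox == pytest.approx(base.ap_bbox)


def test_recall_limited_ap_matches_enumeration():
    """Detections covering a fraction of ground truth at precision 1:
    AP equals the brute-force PR enumeration exactly."""
    boxes = [(1, [10 * k, 10 * k, 8, 8]) for k in range(10)]
    gt = _gt({1: boxes})
    dets = [Detection(1, 1, 0.9 - 0.01 * k, list(map(float, b[1])))
            for k, b in enumerate(boxes[:4])]
    result = evaluate(dets, gt)
    labels = [(d.score, True) for d in dets]
    assert result.ap_bbox[1] == pytest.approx(ap_brute_force(labels, 10))
    assert result.ap_bbox[1] == pytest.approx(5 / 11)  # recall 0.4 -> levels 0..0.4
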
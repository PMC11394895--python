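"""Model evaluation metrics: GFLOPs, precision/recall, mAP50, FPS.

The convolution cost model counts, per output position, one
multiply–accumulate for every input-channel × kernel tap plus the
bias add:

    GFLOPs = X · Y · Cout · (Cin · k² + 1) / 1e9.

Average precision integrates the precision–recall curve with
all-points interpolation; mAP50 averages per-class AP with matches
counted greedily at IoU ≥ 0.5.  FPS is the reciprocal of the mean
per-image inference time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

__all__ = ["ConvCost", "ConfusionCounts", "Detection", "GroundTruth",
           "UndefinedMetricError", "conv_gflops", "model_gflops",
           "precision_recall", "box_iou", "mask_iou", "polygon_iou",
           "average_precision", "map50", "fps_from_times"]


class UndefinedMetricError(ZeroDivisionError):
    pass


@dataclass
class ConvCost:
    """One convolution layer's cost inputs (spatial size at that layer)."""

    x: int          # input width (pixels)
    y: int          # input height (pixels)
    cin: int
    cout: int
    k: int

    def __post_init__(self):
        for name in ("x", "y", "cin", "cout", "k"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")


def conv_gflops(cost: ConvCost) -> float:
    """X·Y·Cout·(Cin·k² + 1) / 1e9 for one layer."""
    return cost.x * cost.y * cost.cout * (cost.cin * cost.k * cost.k + 1) / 1e9


def model_gflops(layers: list[ConvCost]) -> float:
    """Sum of per-layer costs (spatial sizes already traced through strides)."""
    return sum(conv_gflops(c) for c in layers)


def precision_recall(c: ConfusionCounts) -> tuple[float, float]:
    if c.tp + c.fp == 0:
        raise UndefinedMetricError("precision undefined: TP + FP = 0")
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("recall undefined: TP + FN = 0")
    return c.tp / (c.tp + c.fp), c.tp / (c.tp + c.fn)


# ----------------------------------------------------------------------
# detection evaluation
# ----------------------------------------------------------------------

@dataclass
class Detection:
    """One prediction: class, confidence and either a box or a mask."""

    class_id: int
    confidence: float
    box: tuple[float, float, float, float] | None = None   # x1, y1, x2, y2
    mask: np.ndarray | None = None
    polygon: np.ndarray | None = None                      # (V, 2) normalized

    def __post_init__(self):
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must be in [0, 1]")


@dataclass
class GroundTruth:
    class_id: int
    box: tuple[float, float, float, float] | None = None
    mask: np.ndarray | None = None
    polygon: np.ndarray | None = None


def box_iou(a, b) -> float:
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    iw = max(0.0, min(ax2, bx2) - max(ax1, bx1))
    ih = max(0.0, min(ay2, by2) - max(ay1, by1))
    inter = iw * ih
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return inter / union if union > 0 else 0.0


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    union = np.logical_or(a, b).sum()
    return float(np.logical_and(a, b).sum() / union) if union else 0.0


def polygon_iou(a: np.ndarray, b: np.ndarray, raster: int = 128) -> float:
    """IoU of two normalized polygons on a raster grid."""
    from skimage.draw import polygon as draw_polygon

    def rasterize(p):
        m = np.zeros((raster, raster), dtype=bool)
        rr, cc = draw_polygon(np.asarray(p)[:, 1] * (raster - 1),
                              np.asarray(p)[:, 0] * (raster - 1),
                              shape=m.shape)
        m[rr, cc] = True
        return m

    return mask_iou(rasterize(a), rasterize(b))


def _pair_iou(det: Detection, gt: GroundTruth) -> float:
    if det.mask is not None and gt.mask is not None:
        return mask_iou(det.mask, gt.mask)
    if det.polygon is not None and gt.polygon is not None:
        return polygon_iou(det.polygon, gt.polygon)
    if det.box is not None and gt.box is not None:
        return box_iou(det.box, gt.box)
    raise ValueError("prediction and ground truth share no geometry type")


def average_precision(detections: list[Detection],
                      ground_truths: list[GroundTruth],
                      iou_threshold: float = 0.5) -> float:
    """All-points-interpolated AP for a single class.

    Predictions are ranked by confidence (ties broken by ground-truth
    matching order, which is stable); each greedily claims the
    highest-IoU unmatched ground truth at or above the threshold.
    """
    n_gt = len(ground_truths)
    if n_gt == 0:
        raise ValueError("average precision needs at least one ground truth")
    if not detections:
        return 0.0
    order = sorted(range(len(detections)),
                   key=lambda i: (-detections[i].confidence, i))
    matched = [False] * n_gt
    tp = np.zeros(len(order))
    for rank, i in enumerate(order):
        best_iou, best_j = 0.0, -1
        for j, gt in enumerate(ground_truths):
            if matched[j]:
                continue
            iou = _pair_iou(detections[i], gt)
            if iou >= iou_threshold and iou > best_iou:
                best_iou, best_j = iou, j
        if best_j >= 0:
            matched[best_j] = True
            tp[rank] = 1.0
    cum_tp = np.cumsum(tp)
    precision = cum_tp / (np.arange(len(order)) + 1)
    recall = cum_tp / n_gt
    # all-points interpolation: envelope of the PR curve
    mrec = np.concatenate([[0.0], recall, [1.0]])
    mpre = np.concatenate([[1.0], precision, [0.0]])
    mpre = np.maximum.accumulate(mpre[::-1])[::-1]
    idx = np.where(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


def map50(detections: list[Detection], ground_truths: list[GroundTruth],
          num_classes: int | None = None, iou_threshold: float = 0.5) -> float:
    """Mean AP at IoU 0.5 over classes that have ground truth."""
    if not ground_truths:
        raise ValueError("mAP50 needs at least one ground-truth instance")
    classes = sorted({g.class_id for g in ground_truths}) if num_classes is None \
        else list(range(num_classes))
    aps = []
    for c in classes:
        gts = [g for g in ground_truths if g.class_id == c]
        if not gts:
            warnings.warn(f"class {c} has no ground truth; excluded from mAP50",
                          stacklevel=2)
            continue
        dets = [d for d in detections if d.class_id == c]
        aps.append(average_precision(dets, gts, iou_threshold))
    return float(np.mean(aps))


def fps_from_times(durations) -> float:
    """1 / mean(per-image inference durations in seconds)."""
    d = np.asarray(list(durations), dtype=np.float64)
    if d.size == 0:
        raise ValueError("need at least one duration")
    if np.any(d <= 0):
        raise ValueError("durations must be positive")
    return float(1.0 / d.mean())
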
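"""Box geometry, prediction-annotation matching and the detection accuracy metric.

The accuracy metric is the one used by the Global Wheat Head Detection (GWHD)
challenge: per test image,

    accuracy = TP / (TP + FN + FP)

where a true positive is an annotated box matched to a predicted box at
IoU >= 0.5 with prediction confidence > 0.5.  Image accuracies are averaged
within an image set (one acquisition session = one visual domain), and set
accuracies are averaged to give the split-level (ID or OOD) score.  The
two-level mean weights every domain equally regardless of how many images it
contributed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Box",
    "MatchResult",
    "EvalThresholds",
    "iou",
    "nms",
    "match_detections",
    "image_accuracy",
    "aggregate_accuracy",
    "count_error",
    "boxes_to_array",
    "boxes_from_array",
]


@dataclass(frozen=True)
class Box:
    """Axis-aligned box in continuous pixel coordinates (origin top-left).

    ``confidence`` is present on predictions (in [0, 1]) and ``None`` on
    ground-truth annotations.
    """

    min_x: float
    min_y: float
    max_x: float
    max_y: float
    confidence: float | None = None

    def __post_init__(self) -> None:
        if not (self.min_x < self.max_x and self.min_y < self.max_y):
            raise ValueError(
                f"degenerate box: ({self.min_x}, {self.min_y}, "
                f"{self.max_x}, {self.max_y}) has non-positive extent"
            )
        if self.confidence is not None and not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")

    @property
    def area(self) -> float:
        return (self.max_x - self.min_x) * (self.max_y - self.min_y)

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.min_x + self.max_x), 0.5 * (self.min_y + self.max_y))

    def translate(self, dx: float, dy: float) -> "Box":
        return Box(self.min_x + dx, self.min_y + dy,
                   self.max_x + dx, self.max_y + dy, self.confidence)

    def with_confidence(self, confidence: float | None) -> "Box":
        return Box(self.min_x, self.min_y, self.max_x, self.max_y, confidence)


@dataclass(frozen=True)
class MatchResult:
    """TP/FP/FN tallies for one image plus the matched index pairs.

    ``pairs`` holds (prediction index, annotation index) tuples using the
    caller's original input indices; ``tp == len(pairs)``.
    """

    tp: int
    fp: int
    fn: int
    pairs: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("negative tally")
        if self.tp != len(self.pairs):
            raise ValueError("tp must equal number of matched pairs")


@dataclass(frozen=True)
class EvalThresholds:
    """Matching thresholds: IoU >= iou_min (inclusive), confidence > conf_min
    (strict when ``exclusive_conf``, the challenge convention)."""

    iou_min: float = 0.5
    conf_min: float = 0.5
    exclusive_conf: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.iou_min <= 1.0 and 0.0 <= self.conf_min <= 1.0):
            raise ValueError("thresholds must lie in [0, 1]")

    def passes_confidence(self, confidence: float) -> bool:
        if self.exclusive_conf:
            return confidence > self.conf_min
        return confidence >= self.conf_min


def boxes_to_array(boxes: Sequence[Box]) -> np.ndarray:
    """(n, 4) float array of [min_x, min_y, max_x, max_y]."""
    if not boxes:
        return np.empty((0, 4), dtype=float)
    return np.array([[b.min_x, b.min_y, b.max_x, b.max_y] for b in boxes], dtype=float)


def boxes_from_array(arr: np.ndarray,
                     confidences: Sequence[float] | None = None) -> list[Box]:
    if confidences is None:
        return [Box(*row) for row in np.asarray(arr, dtype=float)]
    return [Box(*row, confidence=float(c))
            for row, c in zip(np.asarray(arr, dtype=float), confidences)]


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two boxes (geometric areas); 0 when disjoint."""
    ix = min(a.max_x, b.max_x) - max(a.min_x, b.min_x)
    iy = min(a.max_y, b.max_y) - max(a.min_y, b.min_y)
    if ix <= 0.0 or iy <= 0.0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def _iou_matrix(preds: Sequence[Box], annos: Sequence[Box]) -> np.ndarray:
    """(n_pred, n_anno) pairwise IoU, vectorised."""
    p = boxes_to_array(preds)
    a = boxes_to_array(annos)
    if p.size == 0 or a.size == 0:
        return np.zeros((len(preds), len(annos)))
    ix = (np.minimum(p[:, None, 2], a[None, :, 2])
          - np.maximum(p[:, None, 0], a[None, :, 0]))
    iy = (np.minimum(p[:, None, 3], a[None, :, 3])
          - np.maximum(p[:, None, 1], a[None, :, 1]))
    inter = np.clip(ix, 0, None) * np.clip(iy, 0, None)
    area_p = (p[:, 2] - p[:, 0]) * (p[:, 3] - p[:, 1])
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    return inter / (area_p[:, None] + area_a[None, :] - inter)


def nms(boxes: Sequence[Box], iou_thresh: float = 0.4) -> list[Box]:
    """Greedy non-maximum suppression.

    Repeatedly keeps the highest-confidence remaining box (ties broken by
    ascending input index) and discards remaining boxes whose IoU with it
    strictly exceeds ``iou_thresh``.  Output is sorted by descending
    confidence.
    """
    for b in boxes:
        if b.confidence is None:
            raise ValueError("nms requires scored boxes")
    order = sorted(range(len(boxes)), key=lambda i: (-boxes[i].confidence, i))
    kept: list[int] = []
    suppressed = [False] * len(boxes)
    for i in order:
        if suppressed[i]:
            continue
        kept.append(i)
        for j in order:
            if not suppressed[j] and j != i and iou(boxes[i], boxes[j]) > iou_thresh:
                suppressed[j] = True
    return [boxes[i] for i in kept]


def match_detections(predictions: Sequence[Box],
                     annotations: Sequence[Box],
                     thresholds: EvalThresholds = EvalThresholds()) -> MatchResult:
    """Greedy one-to-one matching of predictions to annotations.

    Predictions failing the confidence filter are discarded before matching
    (they count as neither TP nor FP).  Survivors are processed in descending
    confidence order (ties by ascending input index); each is matched to the
    unmatched annotation with the highest IoU, provided that IoU passes
    ``iou_min`` (IoU ties broken by ascending annotation index).  Unmatched
    surviving predictions are false positives; unmatched annotations are
    false negatives.
    """
    keep = [i for i, p in enumerate(predictions)
            if p.confidence is not None and thresholds.passes_confidence(p.confidence)]
    order = sorted(keep, key=lambda i: (-predictions[i].confidence, i))
    mat = _iou_matrix([predictions[i] for i in order], list(annotations))
    matched_ann: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for row, pi in enumerate(order):
        best_j, best_iou = -1, -1.0
        for j in range(len(annotations)):
            if j in matched_ann:
                continue
            v = mat[row, j]
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou >= thresholds.iou_min:
            matched_ann.add(best_j)
            pairs.append((pi, best_j))
    tp = len(pairs)
    return MatchResult(tp=tp, fp=len(order) - tp, fn=len(annotations) - tp,
                       pairs=tuple(pairs))


def image_accuracy(m: MatchResult) -> float:
    """TP / (TP + FN + FP); 1.0 for an empty image where the detector made no
    mistake (tp = fp = fn = 0)."""
    denom = m.tp + m.fn + m.fp
    if denom == 0:
        return 1.0
    return m.tp / denom


def aggregate_accuracy(
    per_image: Mapping[str, Sequence[float]] | Iterable[Sequence[float]],
) -> tuple[list[float], float]:
    """Two-level mean: per-set mean of image accuracies, then unweighted mean
    of per-set values (never pooled over images)."""
    groups = list(per_image.values()) if isinstance(per_image, Mapping) else list(per_image)
    if not groups:
        raise ValueError("no image sets to aggregate")
    per_set = []
    for g in groups:
        vals = list(g)
        if not vals:
            raise ValueError("empty image set in aggregation")
        per_set.append(float(np.mean(vals)))
    return per_set, float(np.mean(per_set))


def count_error(predicted_counts: Sequence[int],
                annotated_counts: Sequence[int]) -> float:
    """Mean absolute difference between predicted and annotated object counts
    per image.  Predicted counts should already reflect the confidence filter."""
    if len(predicted_counts) != len(annotated_counts):
        raise ValueError("count sequences differ in length")
    if len(predicted_counts) == 0:
        raise ValueError("no images")
    p = np.asarray(predicted_counts, dtype=float)
    a = np.asarray(annotated_counts, dtype=float)
    return float(np.mean(np.abs(p - a)))
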
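"""Independent brute-force oracles used to pin the evaluation semantics.

These are deliberately naive re-implementations, kept separate from the
package so tests compare two independently coded paths.
"""

from __future__ import annotations

import numpy as np


def raster_iou(a, b, scale: int = 1) -> float:
    """Pixel-count IoU on an integer grid covering both boxes."""
    x0 = int(min(a.min_x, b.min_x)) * scale
    y0 = int(min(a.min_y, b.min_y)) * scale
    x1 = int(max(a.max_x, b.max_x)) * scale
    y1 = int(max(a.max_y, b.max_y)) * scale
    grid_a = np.zeros((y1 - y0, x1 - x0), dtype=bool)
    grid_b = np.zeros_like(grid_a)
    grid_a[int(a.min_y * scale) - y0:int(a.max_y * scale) - y0,
           int(a.min_x * scale) - x0:int(a.max_x * scale) - x0] = True
    grid_b[int(b.min_y * scale) - y0:int(b.max_y * scale) - y0,
           int(b.min_x * scale) - x0:int(b.max_x * scale) - x0] = True
    union = np.logical_or(grid_a, grid_b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(grid_a, grid_b).sum() / union)


def brute_iou(a, b) -> float:
    ix = max(0.0, min(a.max_x, b.max_x) - max(a.min_x, b.min_x))
    iy = max(0.0, min(a.max_y, b.max_y) - max(a.min_y, b.min_y))
    inter = ix * iy
    if inter == 0.0:
        return 0.0
    area_a = (a.max_x - a.min_x) * (a.max_y - a.min_y)
    area_b = (b.max_x - b.min_x) * (b.max_y - b.min_y)
    return inter / (area_a + area_b - inter)


def brute_match(predictions, annotations, iou_min=0.5, conf_min=0.5):
    """Naive restatement of the greedy matching policy: strict confidence
    filter, process survivors by descending confidence (input-index
    tie-break), match each to the unmatched annotation of highest IoU if
    that IoU passes the inclusive threshold."""
    survivors = [(i, p) for i, p in enumerate(predictions)
                 if p.confidence > conf_min]
    survivors.sort(key=lambda t: (-t[1].confidence, t[0]))
    used = set()
    tp = 0
    for _, p in survivors:
        candidates = []
        for j, a in enumerate(annotations):
            if j in used:
                continue
            candidates.append((brute_iou(p, a), -j))
        if not candidates:
            continue
        best_iou, neg_j = max(candidates)
        if best_iou >= iou_min:
            used.add(-neg_j)
            tp += 1
    fp = len(survivors) - tp
    fn = len(annotations) - tp
    return tp, fp, fn


def brute_accuracy(tp, fp, fn):
    return 1.0 if tp + fp + fn == 0 else tp / (tp + fp + fn)


def brute_nms(boxes, thresh):
    """Greedy NMS restated: keep best remaining, drop overlaps > thresh."""
    remaining = sorted(range(len(boxes)),
                       key=lambda i: (-boxes[i].confidence, i))
    kept = []
    while remaining:
        i = remaining.pop(0)
        kept.append(i)
        remaining = [j for j in remaining
                     if brute_iou(boxes[i], boxes[j]) <= thresh]
    return [boxes[i] for i in kept]
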
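"""Fixed-size patch extraction and tiled-inference merging.

Detectors here consume 416 x 416 patches.  Training uses non-overlapping
patches; inference tiles the image with 50%-overlapping patches, predicts per
patch, and merges:

1. translate patch-local predictions to image coordinates;
2. deduplicate across overlaps by *ownership tiling* — the image is
   partitioned by nearest patch center, and a prediction survives only if its
   center lies in its source patch's cell;
3. non-maximum suppression (IoU 0.4) over the survivors.

Ownership tiling realises the intent of discarding overlap-region duplicates
while guaranteeing that every image point is owned by exactly one patch, so
no object can be lost to a mutual-overlap zone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .geometry import Box, nms

__all__ = [
    "PatchGrid",
    "PatchRecord",
    "plan_grid",
    "extract_patches",
    "augment_patch",
    "merge_patch_predictions",
]

DEFAULT_PATCH_SIZE = 416


@dataclass(frozen=True)
class PatchGrid:
    image_width: int
    image_height: int
    patch_size: int
    overlap_fraction: float
    origins: tuple[tuple[int, int], ...]  # (x, y) top-left corners, row-major

    @property
    def n_patches(self) -> int:
        return len(self.origins)

    def centers(self) -> np.ndarray:
        half = self.patch_size / 2.0
        return np.array([(x + half, y + half) for x, y in self.origins])


@dataclass(frozen=True)
class PatchRecord:
    """One training/inference tile: pixels plus patch-local annotations."""

    image_id: str
    origin: tuple[int, int]
    pixels: np.ndarray  # (patch, patch, 3) uint8
    annotations: tuple[Box, ...] = field(default_factory=tuple)


def _axis_origins(dim: int, patch: int, stride: int) -> list[int]:
    origins = list(range(0, dim - patch + 1, stride))
    if origins[-1] != dim - patch:
        origins.append(dim - patch)
    return origins


def plan_grid(image_width: int, image_height: int,
              patch_size: int = DEFAULT_PATCH_SIZE,
              overlap_fraction: float = 0.0) -> PatchGrid:
    """Plan patch origins: stride = patch_size * (1 - overlap), with a final
    origin shifted flush to the image edge when the stride does not divide the
    image dimension (duplicated coverage near edges, never padding)."""
    if patch_size > min(image_width, image_height):
        raise ValueError(
            f"patch_size {patch_size} exceeds image dims "
            f"{image_width}x{image_height}")
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1)")
    stride = max(1, int(round(patch_size * (1.0 - overlap_fraction))))
    xs = _axis_origins(image_width, patch_size, stride)
    ys = _axis_origins(image_height, patch_size, stride)
    origins = tuple((x, y) for y in ys for x in xs)  # row-major
    return PatchGrid(image_width, image_height, patch_size,
                     overlap_fraction, origins)


def _clip_box_to_patch(box: Box, ox: int, oy: int, patch: int,
                       keep_fraction: float) -> Box | None:
    nx0 = max(box.min_x, ox)
    ny0 = max(box.min_y, oy)
    nx1 = min(box.max_x, ox + patch)
    ny1 = min(box.max_y, oy + patch)
    if nx1 <= nx0 or ny1 <= ny0:
        return None
    clipped_area = (nx1 - nx0) * (ny1 - ny0)
    if clipped_area < keep_fraction * box.area:
        return None
    return Box(nx0 - ox, ny0 - oy, nx1 - ox, ny1 - oy, box.confidence)


def extract_patches(image, grid: PatchGrid,
                    keep_fraction: float = 0.5) -> list[PatchRecord]:
    """Cut an image into PatchRecords.

    Each annotation intersecting a patch is clipped to the patch and kept iff
    the clipped area is at least ``keep_fraction`` of the original area
    (default 0.5; 0 keeps every intersecting annotation).  Coordinates are
    shifted to the patch-local frame.  ``image`` is any object with
    ``.pixels``, ``.annotations`` and ``.image_id`` (see synth.ImageRecord).
    """
    patch = grid.patch_size
    records = []
    for ox, oy in grid.origins:
        local = []
        for b in image.annotations:
            c = _clip_box_to_patch(b, ox, oy, patch, keep_fraction)
            if c is not None:
                local.append(c)
        records.append(PatchRecord(
            image_id=image.image_id,
            origin=(ox, oy),
            pixels=image.pixels[oy:oy + patch, ox:ox + patch],
            annotations=tuple(local),
        ))
    return records


def _rot90_cw(b: Box, size: int) -> Box:
    # pixel (x, y) -> (size - y, x) for a clockwise quarter turn
    return Box(size - b.max_y, b.min_x, size - b.min_y, b.max_x, b.confidence)


def _hflip(b: Box, size: int) -> Box:
    return Box(size - b.max_x, b.min_y, size - b.min_x, b.max_y, b.confidence)


def _vflip(b: Box, size: int) -> Box:
    return Box(b.min_x, size - b.max_y, b.max_x, size - b.min_y, b.confidence)


def augment_patch(p: PatchRecord, rng: np.random.Generator) -> PatchRecord:
    """Training-time augmentation: a single 90-degree clockwise rotation, a
    horizontal flip and a vertical flip, applied in that fixed order, each
    independently with probability 0.5.  Boxes are transformed consistently
    with pixels.  Requires a square patch."""
    h, w = p.pixels.shape[:2]
    if h != w:
        raise ValueError("augment_patch requires a square patch")
    size = w
    pixels = p.pixels
    boxes = list(p.annotations)
    draws = rng.random(3)
    if draws[0] < 0.5:
        pixels = np.rot90(pixels, k=-1)
        boxes = [_rot90_cw(b, size) for b in boxes]
    if draws[1] < 0.5:
        pixels = pixels[:, ::-1]
        boxes = [_hflip(b, size) for b in boxes]
    if draws[2] < 0.5:
        pixels = pixels[::-1, :]
        boxes = [_vflip(b, size) for b in boxes]
    return replace(p, pixels=np.ascontiguousarray(pixels), annotations=tuple(boxes))


def merge_patch_predictions(patch_preds: Sequence[Sequence[Box]],
                            grid: PatchGrid,
                            nms_iou: float = 0.4) -> list[Box]:
    """Merge per-patch predictions into image-frame predictions.

    See module docstring for the three merge steps.  Raises if a prediction
    lies outside its source patch's bounds.
    """
    if len(patch_preds) != grid.n_patches:
        raise ValueError("one prediction list per grid patch required")
    patch = grid.patch_size
    centers = grid.centers()  # (k, 2)
    survivors: list[Box] = []
    for idx, ((ox, oy), preds) in enumerate(zip(grid.origins, patch_preds)):
        for b in preds:
            if b.min_x < 0 or b.min_y < 0 or b.max_x > patch or b.max_y > patch:
                raise ValueError(
                    f"prediction {b} outside patch bounds (patch {idx})")
            g = b.translate(ox, oy)
            cx, cy = g.center
            d2 = (centers[:, 0] - cx) ** 2 + (centers[:, 1] - cy) ** 2
            owner = int(np.argmin(d2))  # argmin takes lowest row-major index on ties
            if owner == idx:
                survivors.append(g)
    return nms(survivors, nms_iou)
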
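"""Annotation-noise models for training-set quality studies.

Two noise families:

* **Dilation** (loosely drawn boxes): each side of a box is pushed outward by
  an independent draw from the discrete uniform U{0, ..., N},

      min_x -= U{0,N};  min_y -= U{0,N};  max_x += U{0,N};  max_y += U{0,N}

  then clipped to the image/patch bounds.  N is the maximum expansion per
  side in pixels; the study grid runs N = 0..32 in steps of 2.

* **Removal** (missing boxes): each box is independently deleted with
  probability P; the study grid is P in {0, .05, .1, .15, .25, .5, .75, .9}.

Noise is applied to the full patch pool *before* any training-set
subsampling, matching the study protocol, and is deterministic given the
seed in :class:`NoiseConfig`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .geometry import Box
from .patching import PatchRecord

__all__ = ["NoiseConfig", "dilate_boxes", "drop_boxes", "corrupt_dataset",
           "DILATION_GRID", "REMOVAL_GRID"]

# full-scale study grids
DILATION_GRID: tuple[int, ...] = tuple(range(0, 34, 2))
REMOVAL_GRID: tuple[float, ...] = (0.0, 0.05, 0.1, 0.15, 0.25, 0.5, 0.75, 0.9)


@dataclass(frozen=True)
class NoiseConfig:
    """dilation_max: N in pixels; removal_prob: P; both default to 0 (clean)."""

    dilation_max: int = 0
    removal_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dilation_max < 0:
            raise ValueError("dilation_max must be >= 0")
        if not 0.0 <= self.removal_prob <= 1.0:
            raise ValueError("removal_prob must lie in [0, 1]")


def dilate_boxes(annotations: Sequence[Box], dilation_max: int,
                 bounds: tuple[float, float],
                 rng: np.random.Generator) -> list[Box]:
    """Dilate each box by four independent U{0..N} draws (fixed draw order
    min_x, min_y, max_x, max_y per box) and clip to ``bounds`` (width,
    height)."""
    if dilation_max < 0:
        raise ValueError("dilation_max must be >= 0")
    if not annotations:
        return []
    width, height = bounds
    draws = rng.integers(0, dilation_max + 1, size=(len(annotations), 4))
    out = []
    for b, (dx0, dy0, dx1, dy1) in zip(annotations, draws):
        out.append(Box(
            float(max(b.min_x - dx0, 0.0)),
            float(max(b.min_y - dy0, 0.0)),
            float(min(b.max_x + dx1, width)),
            float(min(b.max_y + dy1, height)),
            b.confidence,
        ))
    return out


def drop_boxes(annotations: Sequence[Box], removal_prob: float,
               rng: np.random.Generator) -> list[Box]:
    """Independently delete each box with probability P, preserving the order
    of survivors."""
    if not 0.0 <= removal_prob <= 1.0:
        raise ValueError("removal_prob must lie in [0, 1]")
    if not annotations:
        return []
    u = rng.random(len(annotations))
    return [b for b, draw in zip(annotations, u) if draw >= removal_prob]


def corrupt_dataset(patch_pool: Sequence[PatchRecord],
                    cfg: NoiseConfig) -> list[PatchRecord]:
    """Apply the configured noise to every patch's annotations.

    Pixels are untouched; the result is deterministic given ``cfg.seed``.
    The study protocol varies one noise type at a time; configuring both at
    once is allowed for exploration but flagged with a warning.
    """
    if cfg.dilation_max > 0 and cfg.removal_prob > 0:
        warnings.warn("both dilation and removal noise active; the study "
                      "protocol varies one at a time", stacklevel=2)
    rng = np.random.default_rng(cfg.seed)
    patch = None
    out = []
    for rec in patch_pool:
        annos: Sequence[Box] = rec.annotations
        if cfg.dilation_max > 0:
            patch = rec.pixels.shape[1], rec.pixels.shape[0]
            annos = dilate_boxes(annos, cfg.dilation_max, patch, rng)
        if cfg.removal_prob > 0:
            annos = drop_boxes(annos, cfg.removal_prob, rng)
        out.append(replace(rec, annotations=tuple(annos)))
    return out
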
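"""Experiment drivers: training-set size, diversity and quality studies.

Each driver samples training sets from the benchmark's patch pool, fits one
detector per (condition, replication) cell, evaluates it through the tiled
inference pipeline, and appends long-format rows to a result table

    experiment | condition | replication | split | set_id | metric | value

with one row per (test image set, metric).  Split-level scores are the
unweighted mean of per-set values (the two-level accuracy aggregation).
All randomness derives hierarchically from the spec's master seed, so a run
is byte-for-byte reproducible and any single cell can be re-executed from
its logged path.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone

from ._rng import child_rng
from .geometry import EvalThresholds, image_accuracy, match_detections
from .noise import NoiseConfig, corrupt_dataset
from .patching import PatchRecord, extract_patches, merge_patch_predictions, plan_grid
from .synth import BenchmarkLayout, ImageSet

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentSpec",
    "RESULT_COLUMNS",
    "sample_training_set",
    "training_patch_pool",
    "predict_image",
    "evaluate_sets",
    "run_size_series",
    "run_diversity_experiment",
    "relevance_analysis",
    "mixed_to_test_split",
    "run_mixed_to_test",
    "run_quality_experiment",
    "summarize",
    "split_summary",
    "matched_drop_contrast",
]

RESULT_COLUMNS = ["experiment", "condition", "replication", "split",
                  "set_id", "metric", "value"]

#: full-scale presets matching the original study protocol (for use with the
#: real dataset); the dataclass defaults below are the desk-scale conditions.
FULL_SCALE_SIZES = (250, 500, 1000, 2000, 4000, 8000, 16000, 24000, 32000, 38891)
FULL_SCALE_REPLICATIONS = 5
FULL_SCALE_BUDGET = 630
FULL_SCALE_QUALITY_TRAIN_SIZE = 16000


@dataclass(frozen=True)
class ExperimentSpec:
    """Conditions for one experiment run (desk-scale defaults)."""

    kind: str = "size"  # size | diversity | quality | mixed_to_test
    sizes: tuple[int, ...] = (100, 200, 400, 800, 1600, 3200)
    replications: int = 3
    budget: int | None = None       # diversity patch budget; None -> min set size
    dilation_grid: tuple[int, ...] = (0, 8, 16, 24, 32)
    removal_grid: tuple[float, ...] = (0.0, 0.1, 0.25, 0.5, 0.75, 0.9)
    quality_train_size: int = 800
    master_seed: int = 0
    patch_size: int = 416
    keep_fraction: float = 0.5
    inference_overlap: float = 0.5
    nms_iou: float = 0.4
    thresholds: EvalThresholds = field(default_factory=EvalThresholds)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sizes):
            raise ValueError("sizes must be positive")
        if self.replications < 1:
            raise ValueError("replications must be >= 1")


def sample_training_set(pool: Sequence[PatchRecord], n: int,
                        rng: np.random.Generator) -> list[PatchRecord]:
    """Uniform sample of n patches without replacement."""
    if n > len(pool):
        raise ValueError(f"requested {n} patches from a pool of {len(pool)}")
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in idx]


def training_patch_pool(train_sets: Sequence[ImageSet], patch_size: int = 416,
                        keep_fraction: float = 0.5) -> list[PatchRecord]:
    """Non-overlapping training patches pooled across image sets."""
    pool: list[PatchRecord] = []
    for s in train_sets:
        for img in s.images:
            h, w = img.pixels.shape[:2]
            grid = plan_grid(w, h, patch_size, overlap_fraction=0.0)
            pool.extend(extract_patches(img, grid, keep_fraction))
    return pool


def predict_image(detector, image, patch_size: int = 416,
                  overlap: float = 0.5, nms_iou: float = 0.4):
    """Tiled inference: 50%-overlap grid -> per-patch predict -> ownership
    merge -> NMS; returns image-frame scored boxes."""
    h, w = image.pixels.shape[:2]
    grid = plan_grid(w, h, patch_size, overlap_fraction=overlap)
    patch_preds = [detector.predict(image.pixels[oy:oy + patch_size,
                                                 ox:ox + patch_size])
                   for ox, oy in grid.origins]
    return merge_patch_predictions(patch_preds, grid, nms_iou)


def evaluate_sets(detector, sets: Sequence[ImageSet],
                  thresholds: EvalThresholds = EvalThresholds(),
                  patch_size: int = 416, overlap: float = 0.5,
                  nms_iou: float = 0.4) -> pd.DataFrame:
    """Per-image evaluation over image sets.

    Returns a frame with columns (set_id, image_id, accuracy, n_pred,
    n_anno); n_pred counts confidence-filtered predictions.
    """
    rows = []
    for s in sets:
        for img in s.images:
            preds = predict_image(detector, img, patch_size, overlap, nms_iou)
            m = match_detections(preds, list(img.annotations), thresholds)
            n_conf = sum(1 for p in preds
                         if thresholds.passes_confidence(p.confidence))
            rows.append((s.set_id, img.image_id, image_accuracy(m),
                         n_conf, len(img.annotations)))
    return pd.DataFrame(rows, columns=["set_id", "image_id", "accuracy",
                                       "n_pred", "n_anno"])


def _metric_rows(per_image: pd.DataFrame, experiment: str, condition,
                 replication: int, split: str,
                 with_count_error: bool = False) -> list[tuple]:
    rows = []
    for set_id, g in per_image.groupby("set_id", sort=True):
        rows.append((experiment, condition, replication, split, set_id,
                     "accuracy", float(g["accuracy"].mean())))
        if with_count_error:
            rows.append((experiment, condition, replication, split, set_id,
                         "count_error",
                         float((g["n_pred"] - g["n_anno"]).abs().mean())))
    return rows


def _fit_eval(detector, train_patches, benchmark: BenchmarkLayout,
              spec: ExperimentSpec, experiment: str, condition,
              replication: int, splits=("id_test", "ood_test"),
              with_count_error: bool = False,
              ood_sets: Sequence[ImageSet] | None = None) -> list[tuple]:
    det = clone(detector)
    det.fit(train_patches)
    rows: list[tuple] = []
    split_sets = {"id_test": benchmark.id_test_sets,
                  "ood_test": ood_sets if ood_sets is not None
                  else benchmark.ood_test_sets}
    for split in splits:
        per_image = evaluate_sets(det, split_sets[split], spec.thresholds,
                                  spec.patch_size, spec.inference_overlap,
                                  spec.nms_iou)
        rows.extend(_metric_rows(per_image, experiment, condition,
                                 replication, split, with_count_error))
    return rows


def run_size_series(spec: ExperimentSpec, benchmark: BenchmarkLayout,
                    detector) -> pd.DataFrame:
    """Training-set size study: for each size x replication, sample that many
    patches from the pooled training sets, fit, and evaluate on the ID and
    OOD test splits."""
    pool = training_patch_pool(benchmark.train_sets, spec.patch_size,
                               spec.keep_fraction)
    if max(spec.sizes) > len(pool):
        raise ValueError(f"largest size {max(spec.sizes)} exceeds pool "
                         f"of {len(pool)} patches")
    rows: list[tuple] = []
    for size in spec.sizes:
        for rep in range(spec.replications):
            rng = child_rng(spec.master_seed, "size", size, "rep", rep)
            logger.info("size=%d rep=%d seed-path=(size,%d,rep,%d)",
                        size, rep, size, rep)
            sample = sample_training_set(pool, size, rng)
            rows.extend(_fit_eval(detector, sample, benchmark, spec,
                                  "size", size, rep))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def run_diversity_experiment(spec: ExperimentSpec, benchmark: BenchmarkLayout,
                             detector) -> pd.DataFrame:
    """Diversity study at a fixed patch budget.

    Non-diverse models train on patches from a single image set; diverse
    models on the same number of patches sampled from the pooled sets.  All
    are evaluated on the OOD split only.
    """
    per_set_pools = {
        s.set_id: training_patch_pool([s], spec.patch_size, spec.keep_fraction)
        for s in benchmark.train_sets
    }
    min_set = min(per_set_pools, key=lambda k: len(per_set_pools[k]))
    budget = spec.budget if spec.budget is not None else len(per_set_pools[min_set])
    for sid, p in per_set_pools.items():
        if budget > len(p):
            raise ValueError(f"budget {budget} exceeds the {len(p)} patches "
                             f"of training set '{sid}'")
    rows: list[tuple] = []
    for sid in sorted(per_set_pools):
        for rep in range(spec.replications):
            rng = child_rng(spec.master_seed, "diversity", sid, "rep", rep)
            sample = sample_training_set(per_set_pools[sid], budget, rng)
            rows.extend(_fit_eval(detector, sample, benchmark, spec,
                                  "diversity", f"nondiverse:{sid}", rep,
                                  splits=("ood_test",)))
    pooled = list(itertools.chain.from_iterable(
        per_set_pools[sid] for sid in sorted(per_set_pools)))
    for rep in range(spec.replications):
        rng = child_rng(spec.master_seed, "diversity", "pooled", "rep", rep)
        sample = sample_training_set(pooled, budget, rng)
        rows.extend(_fit_eval(detector, sample, benchmark, spec,
                              "diversity", "diverse", rep,
                              splits=("ood_test",)))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def relevance_analysis(diverse_per_set: Sequence[float],
                       nondiverse_per_set: np.ndarray,
                       n_values: Sequence[int],
                       n_resamples: int = 1000,
                       rng: np.random.Generator | None = None,
                       best: str = "per_subset") -> pd.DataFrame:
    """Diversity-vs-relevance resampling analysis.

    For each n, draw ``n_resamples`` subsets of n OOD test sets (uniform,
    without replacement within a subset); per subset compute the difference
    between the diverse model's accuracy and the best-performing non-diverse
    model's accuracy, where subset accuracy is the mean of per-set
    accuracies.  ``best='per_subset'`` takes the max over non-diverse models
    on each subset (default); ``'global'`` fixes the model that is best on
    the full suite.

    Returns a frame with columns (n, mean_diff).
    """
    div = np.asarray(diverse_per_set, dtype=float)
    nd = np.asarray(nondiverse_per_set, dtype=float)
    if nd.ndim != 2 or nd.shape[1] != div.size:
        raise ValueError("nondiverse_per_set must be (n_models, n_sets)")
    k = div.size
    if rng is None:
        rng = np.random.default_rng(0)
    global_best = int(np.argmax(nd.mean(axis=1)))
    out = []
    for n in n_values:
        if not 1 <= n <= k:
            raise ValueError(f"n={n} outside [1, {k}]")
        diffs = np.empty(n_resamples)
        for r in range(n_resamples):
            idx = rng.choice(k, size=n, replace=False)
            d_acc = div[idx].mean()
            if best == "per_subset":
                nd_acc = nd[:, idx].mean(axis=1).max()
            else:
                nd_acc = nd[global_best, idx].mean()
            diffs[r] = d_acc - nd_acc
        out.append((n, float(diffs.mean())))
    return pd.DataFrame(out, columns=["n", "mean_diff"])


def mixed_to_test_split(train_sets: Sequence[ImageSet],
                        ood_sets: Sequence[ImageSet],
                        rng: np.random.Generator,
                        ) -> tuple[list[ImageSet], list[ImageSet]]:
    """Move one random image from each OOD set into training, displacing one
    random image from the paired training set, so total training image count
    is preserved; moved images are excluded from OOD evaluation."""
    if len(train_sets) != len(ood_sets):
        raise ValueError("mixed-to-test pairs train and OOD sets one-to-one")
    new_train, new_ood = [], []
    for ts, os_ in zip(train_sets, ood_sets):
        if len(ts.images) < 2 or len(os_.images) < 2:
            raise ValueError(
                f"sets '{ts.set_id}'/'{os_.set_id}' need >= 2 images each")
        take = int(rng.integers(0, len(os_.images)))
        drop = int(rng.integers(0, len(ts.images)))
        moved = os_.images[take]
        kept_train = [im for i, im in enumerate(ts.images) if i != drop]
        new_train.append(ImageSet(ts.set_id, kept_train + [moved],
                                  ts.params, ts.role))
        new_ood.append(ImageSet(os_.set_id,
                                [im for i, im in enumerate(os_.images)
                                 if i != take],
                                os_.params, os_.role))
    return new_train, new_ood


def run_mixed_to_test(spec: ExperimentSpec, benchmark: BenchmarkLayout,
                      detector, train_size: int | None = None) -> pd.DataFrame:
    """Mixed-to-test comparison: models trained on the original pool vs. a
    pool where OOD images replaced training images, both evaluated on the ID
    split and the reduced OOD split."""
    k = min(len(benchmark.train_sets), len(benchmark.ood_test_sets))
    rng = child_rng(spec.master_seed, "mixed", "split")
    mixed_train, reduced_ood = mixed_to_test_split(
        benchmark.train_sets[:k], benchmark.ood_test_sets[:k], rng)
    pools = {
        "original": training_patch_pool(benchmark.train_sets[:k],
                                        spec.patch_size, spec.keep_fraction),
        "mixed": training_patch_pool(mixed_train, spec.patch_size,
                                     spec.keep_fraction),
    }
    n = train_size or min(len(p) for p in pools.values())
    rows: list[tuple] = []
    for condition, pool in pools.items():
        for rep in range(spec.replications):
            crng = child_rng(spec.master_seed, "mixed", condition, "rep", rep)
            sample = sample_training_set(pool, n, crng)
            rows.extend(_fit_eval(detector, sample, benchmark, spec,
                                  "mixed_to_test", condition, rep,
                                  ood_sets=reduced_ood))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def run_quality_experiment(spec: ExperimentSpec, benchmark: BenchmarkLayout,
                           detector) -> pd.DataFrame:
    """Annotation-quality study.

    For each noise type (dilation N, removal P) and level: corrupt the full
    patch pool, then sample a fixed-size training set from the corrupted
    pool, fit, and evaluate OOD accuracy and count error.
    """
    pool = training_patch_pool(benchmark.train_sets, spec.patch_size,
                               spec.keep_fraction)
    if spec.quality_train_size > len(pool):
        raise ValueError("quality_train_size exceeds pool size")
    rows: list[tuple] = []
    grids = [("dilation", spec.dilation_grid), ("removal", spec.removal_grid)]
    for noise_kind, grid in grids:
        for level in grid:
            cfg = NoiseConfig(
                dilation_max=int(level) if noise_kind == "dilation" else 0,
                removal_prob=float(level) if noise_kind == "removal" else 0.0,
                seed=int(child_rng(spec.master_seed, "quality", noise_kind,
                                   str(level)).integers(0, 2**31)),
            )
            corrupted = corrupt_dataset(pool, cfg)
            for rep in range(spec.replications):
                rng = child_rng(spec.master_seed, "quality", noise_kind,
                                str(level), "rep", rep)
                sample = sample_training_set(corrupted,
                                             spec.quality_train_size, rng)
                rows.extend(_fit_eval(
                    detector, sample, benchmark, spec, "quality",
                    f"{noise_kind}:{level}", rep, splits=("ood_test",),
                    with_count_error=True))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def summarize(values: Sequence[float]) -> tuple[float, float]:
    """Mean and standard error of the mean (SE = sd_{n-1} / sqrt(n); 0 for a
    single value)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no values to summarize")
    if v.size == 1:
        return float(v[0]), 0.0
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))


def split_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Condition x split summary: per replication take the unweighted mean
    over test sets, then mean and SE across replications."""
    per_rep = (results
               .groupby(["experiment", "condition", "replication", "split",
                         "metric"], sort=True)["value"]
               .mean()
               .reset_index())
    rows = []
    for key, g in per_rep.groupby(["experiment", "condition", "split",
                                   "metric"], sort=True):
        mean, se = summarize(g["value"].to_numpy())
        rows.append((*key, mean, se, len(g)))
    return pd.DataFrame(rows, columns=["experiment", "condition", "split",
                                       "metric", "mean", "se", "n"])


def matched_drop_contrast(quality_summary: pd.DataFrame) -> dict:
    """Pair each nonzero removal level with the dilation level whose OOD
    accuracy drop is closest, and compare count errors at the pair with the
    closest-matched drop.  Returns the matched levels, their accuracies and
    count errors."""
    q = quality_summary[quality_summary["experiment"] == "quality"]
    acc = q[q["metric"] == "accuracy"].set_index("condition")["mean"]
    cnt = q[q["metric"] == "count_error"].set_index("condition")["mean"]
    dil = sorted((c for c in acc.index if c.startswith("dilation:")),
                 key=lambda c: float(c.split(":")[1]))
    rem = sorted((c for c in acc.index if c.startswith("removal:")),
                 key=lambda c: float(c.split(":")[1]))
    base = acc[dil[0]]  # dilation:0 == clean baseline
    best = None
    for r in rem:
        if float(r.split(":")[1]) == 0.0:
            continue
        drop_r = base - acc[r]
        if drop_r <= 0:
            continue
        for d in dil:
            if float(d.split(":")[1]) == 0.0:
                continue
            drop_d = base - acc[d]
            if drop_d <= 0:
                continue
            gap = abs(drop_d - drop_r)
            if best is None or gap < best["gap"]:
                best = {"gap": gap, "dilation": d, "removal": r,
                        "dilation_accuracy": float(acc[d]),
                        "removal_accuracy": float(acc[r]),
                        "dilation_count_error": float(cnt[d]),
                        "removal_count_error": float(cnt[r])}
    if best is None:
        raise ValueError("no matched accuracy drops found")
    return best
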
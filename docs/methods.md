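# Methods

`seedbench` studies how the composition of a training set — its size, its
diversity across acquisition sessions, and the quality of its box
annotations — affects an aerial seedling detector's accuracy on test imagery
from seen (in-distribution, ID) and unseen (out-of-distribution, OOD)
visual domains.  Because the full-scale version of this question requires a
large field dataset and GPU-scale detector training, the package ships a
desk-scale instantiation: a synthetic multi-domain crop-field benchmark and
a CPU-trainable reference detector, with every protocol (patching, merging,
metric, noise models, experiment designs) implemented exactly and
full-scale settings available as presets.

## Evaluation metric

Per test image, predictions with confidence > 0.5 are greedily matched to
annotations at IoU ≥ 0.5 (descending confidence; each prediction takes the
unmatched annotation of highest IoU; confidence ties break by input index,
IoU ties by annotation index).  The image score is

    accuracy = TP / (TP + FN + FP),

the single-class detection accuracy popularised by the Global Wheat Head
Detection challenge.  An image with no annotations and no confident
predictions scores 1.0 (the detector made no mistake; the ratio is
otherwise 0/0).  Image scores are averaged within an image set, and set
scores are averaged to the split score, so every domain carries equal
weight regardless of image count.  The matching procedure is not uniquely
determined by the metric's definition ("annotated boxes that can be matched
with a predicted box"); the greedy policy above is the package's choice,
pinned by an independently coded brute-force oracle in the tests.
Hungarian (optimal) assignment was the rejected alternative: on boxes as
compact and well-separated as seedlings the two differ only in contrived
configurations, and greedy matches common challenge practice.

Counting performance is the mean absolute difference between the number of
confident predictions and the number of annotations per image.

## Patching and tiled inference

Detectors consume 416 × 416 patches.  Training patches are non-overlapping
(stride 416); inference patches overlap by 50% (stride 208).  When the
stride does not divide the image dimension, the final patch is shifted
flush to the image edge — duplicated coverage rather than padded synthetic
pixels.  Annotations clipped by a patch boundary are kept when at least
half their area survives (`keep_fraction = 0.5`).

Merging patch predictions back to image level proceeds in three steps:
translate to image coordinates; *ownership filtering* — the image is
partitioned into cells by nearest patch center (ties to the lower row-major
patch index) and a prediction survives only if its center lies in its own
patch's cell; then non-maximum suppression at IoU 0.4.  A literal
"discard boxes whose centers fall inside overlapping areas" rule would
delete an object from *every* patch when its center lies in a mutual
overlap zone; ownership tiling realises the same deduplication intent while
guaranteeing each image point is owned by exactly one patch.  With a
perfect per-patch detector the pipeline returns image ground truth exactly
(accuracy 1.0), which the tests assert.

Training-time augmentation (a 90° clockwise rotation, a horizontal flip
and a vertical flip, applied in that order each with probability 0.5) is
implemented for completeness and exposed to callers; the reference
detector's features are orientation-insensitive, so the experiment drivers
do not enable it by default.

## Annotation-noise models

*Dilation* (loose boxes): each side of each box is pushed outward by an
independent draw from the discrete uniform U{0..N} (order: min_x, min_y,
max_x, max_y), then clipped to the frame.  N ranges over 0–32 px in steps
of 2 at full scale; the desk grid is {0, 8, 16, 24, 32}.  *Removal*
(missing boxes): each box is deleted independently with probability P from
{0, .05, .1, .15, .25, .5, .75, .9} (desk grid {0, .1, .25, .5, .75, .9}).
Noise is applied to the full patch pool before training-set subsampling,
deterministically given the config seed.  Dilated boxes may exceed the
patch; they are clipped to the frame because downstream formats and
detectors assume in-frame boxes.

## Synthetic benchmark

Each domain (image set) draws a parameter vector uniformly from documented
ranges: seedling density and row geometry, cotyledon size, foliage colour,
soil colour and texture, illumination, blur, sensor noise, and rates of two
unannotated distractors (weeds and stubble straw).  Key defaults, chosen
once:

- **Density**: 4–9 expected seedlings per 832² image (≈1.0–2.2 annotations
  per 416² patch), matching the annotation density of real early-season
  canola datasets (~1.5 boxes per patch).
- **Seedling geometry**: two opposed cotyledon ellipses joined by thin
  petioles through a center disc, plus 0–4 leaf ellipses at random angles;
  `cotyledon_length` is the center-to-tip distance, so an unoccluded
  seedling spans ≈ 2 × that length (parameter-recovery tests assert the
  mean annotated box side is within 10% of it).
- **Distractors**: weeds share the seedlings' hue family and are separable
  by shape only — irregular blobs built from random walks of discs, with a
  size distribution independent of the crop's growth stage (weed species do
  not scale with the crop).  Stubble consists of pale straight segments.  Half the stubble lies under the
  canopy, half on top where it occludes; a seedling is annotated only if
  ≥ 30% of its pixels stay visible, emulating what an annotator can still
  identify.  Weeds and stubble are never annotated.
- **Domain shift**: OOD domains are sampled from wider ranges than training
  domains on every axis (e.g. blur to 2.0 px vs 1.5, illumination
  0.65–1.35 vs 0.75–1.25, cotyledon length 6.5–18 px vs 8–16, more weeds
  and stubble).  The shift is deliberately *relevant* — OOD ranges overlap
  the training support — modelling the regime where OOD accuracy improves
  in lockstep with ID accuracy as training data grows, rather than an
  unbridgeable shift no amount of data helps with.  ID test sets reuse the
  training domains' parameter vectors with fresh per-image seeds.
- **Within-domain drift**: illumination, blur and sensor noise jitter
  mildly per image around the domain's values (sun angle, exposure and
  focus change during a flight).

The desk benchmark is 8 training domains × 100 images (3,200 training
patches), plus 6 ID-test and 6 OOD-test images per domain — shaped like the
real dataset's 27/27/27 structure but sized for minute-scale experiments;
27-set layouts are a constructor argument away.  Rendering order is soil →
ground stubble → plants and weeds → surface stubble → illumination → blur →
sensor noise, all driven by hierarchically derived seeds, and bit-identical
under a repeated seed.

What the generator does *not* emulate: perspective and orthomosaic
geometry, soil moisture gradients, specular highlights, wind-blurred
plants, multi-species weed communities, and annotator subjectivity.
Passing tests therefore demonstrate that the pipeline and protocols behave
correctly and that the study's qualitative orderings emerge under
controlled shift — not that any absolute accuracy transfers to real
imagery.

## Reference detector

A classical propose-and-classify detector stands in for the GPU-scale deep
model used at full scale.  It was chosen to be (a) trainable, so data-size
and diversity effects manifest; (b) label-driven, so annotation noise
propagates; and (c) deterministic given a seed.

1. **Vegetation index**: per-pixel excess green, ExG = 2g − r − b on
   chromatic coordinates.
2. **Proposals**: the fitted threshold parameter is a quantile *level* q;
   each patch is thresholded at the q-quantile of its own ExG distribution,
   which transfers across lighting/soil far better than an absolute
   threshold.  The mask is cleaned by a 3×3 closing then opening,
   4-connected components become candidate boxes (grown back to their
   parent extent in the merely-closed mask, recovering thin tips the
   opening erased), filtered to an area band (15–6,000 px).  q is selected
   at fit time by grid search over eight levels in {0.90, …, 0.995}
   maximising proposal-stage F1, scored on up to 400 training patches at
   half resolution — the large subsample keeps the selection stable against
   sampling order, which would otherwise be the dominant replication-noise
   source.
3. **Classification**: seven features per candidate (log area, aspect,
   fill, ExG mean and sd, ring contrast, second-moment elongation),
   z-normalised by training statistics.  Confidence is the sigmoid score of
   a logistic model over a cubic polynomial expansion of the features, fit
   by full-batch gradient descent (1,500 iterations, rate 0.4, L2 10⁻⁴,
   zero init — deterministic).
4. **Labels and box correction**: a candidate is positive if its best-IoU
   annotation reaches 0.5, or — for annotations left unmatched — if it is
   the largest candidate geometrically contained in the annotation.
   Containment is the signature of a dilated (loose) label, which only ever
   expands boxes; this keeps training viable under heavy dilation noise.
   The mean per-side margin between matched candidates and annotations is
   learned and added back at predict time, so dilated training labels
   produce visibly dilated predictions (degrading localization while
   leaving counts intact), exactly the failure mode loose labels induce in
   box-regression detectors.

The detector implements a minimal contract (`fit` on annotated patches,
`predict` scored boxes per patch) used by all experiment drivers; a mock
detector tests the drivers independently of this implementation.

## Experiments

All drivers derive every random choice hierarchically from one master seed
(experiment → condition → replication), making any table reproducible
byte-for-byte and any single cell re-runnable in isolation.  Desk-scale
defaults (full-scale presets in parentheses):

- **Size**: training sets of 100–3,200 patches (250–38,891) sampled without
  replacement from the pooled training sets, 3 replications (5), evaluated
  on ID and OOD splits.
- **Diversity**: every model trains on the same budget — the patch count of
  the smallest training set (630 at full scale) — with 2 replications (5).
  Non-diverse models draw from a single set; diverse models from the pool;
  OOD evaluation only.
  The resampling analysis re-evaluates the models on 1,000 random subsets
  of n OOD sets, comparing the diverse model to the best non-diverse model
  *per subset* (a global-best variant is exposed as an option).
- **Quality**: for each noise type and level, corrupt the full pool, then
  sample an 800-patch (16,000) training set, 2 replications (5), OOD
  accuracy and count error.
- **Mixed-to-test**: one random image moves from each OOD set into the
  paired training set, displacing one random training image (size
  preserved); models trained on the full original vs. full mixed pools are
  compared on the ID split and the reduced OOD split.  At desk scale the
  moved images are only ~1% of training images (vs ~8% at full scale), so
  the OOD delta this comparison measures is expected to be small.

Uncertainty is reported as mean ± standard error (sd/√n across
replications).  Problem sizes were set so the full default experiment suite
(benchmark generation plus all three studies) completes in roughly a
quarter hour on one CPU core.

The full-scale detector selects weights by lowest training loss across
epochs; the reference detector has no epoch trajectory, so its final fit is
used — a documented divergence.

## Known limitations

- Absolute accuracies are not comparable to real-world values; only the
  qualitative orderings (size monotonicity, ID ≥ OOD, diverse > typical
  non-diverse, the dilation/removal contrast) are claimed, and those only
  under the shipped benchmark's conditions.
- The reference detector is colour-cue-dependent at the proposal stage; a
  domain whose foliage-soil contrast vanishes would break it in ways a
  learned detector might survive.
- The removal-noise response is steeper around the probability level where
  mislabeled candidates flip the confidence cut, rather than strictly
  proportional to P as reported at full scale.
- `zenodo_adapter` maps the real deposited dataset on a best-effort basis
  and is quarantined from the test suite; it never downloads anything.
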
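"""CPU-trainable reference seedling detector.

The benchmark treats the detector as a pluggable contract — ``fit`` on
annotated training patches, ``predict`` scored boxes on a patch — so that
the training-set size / diversity / quality studies are detector-agnostic.
:class:`SeedlingDetector` is the reference implementation: a classical
propose-and-classify pipeline chosen to be (a) trainable, so data-size and
diversity effects manifest; (b) label-driven, so annotation noise
propagates; and (c) deterministic given a seed.

Pipeline
--------
1. **Vegetation index**: per-pixel excess-green index ExG = 2g - r - b on
   chromatic coordinates, the standard colour cue for separating green
   vegetation from soil.
2. **Proposals**: threshold ExG adaptively — the fitted parameter is a
   quantile *level* q, and each patch is thresholded at the q-quantile of
   its own ExG distribution, which transfers across domains with different
   soil colour, lighting and blur far better than one absolute threshold —
   then clean the mask with a 3x3 closing + opening, take 4-connected
   components, and keep components within an area band.  q is chosen at fit
   time by a grid search over ExG quantile levels maximising proposal-stage
   F1 against the training annotations.
3. **Classification**: each proposal is described by shape/contrast features
   (area, aspect, fill, index statistics, ring contrast, elongation) and
   scored by a logistic model over a polynomial expansion of the normalised
   features, fit by full-batch gradient descent (fixed iterations, fixed
   learning rate, zero init — deterministic).  Confidence is the sigmoid
   score.
4. **Box correction**: the mean signed margin between matched proposals and
   their annotations, learned at fit time, is added back to predicted boxes.
   Training on dilated annotations therefore yields visibly dilated
   predictions, mirroring how a box-regression detector absorbs loose
   labels.

The estimator follows scikit-learn conventions (``get_params`` /
``set_params``, fitted attributes with trailing underscores, ``clone``
compatibility).
"""

from __future__ import annotations

import json
from typing import Protocol, Sequence

import numpy as np
from scipy import ndimage as ndi
from sklearn.base import BaseEstimator

from .geometry import Box, EvalThresholds, iou, match_detections
from .patching import PatchRecord

__all__ = [
    "DetectorContract",
    "SeedlingDetector",
    "MockDetector",
    "exg_index",
    "propose_candidates",
    "candidate_features",
    "fit",
    "predict",
    "FEATURE_NAMES",
]

FEATURE_NAMES = ("log_area", "aspect_ratio", "fill_ratio", "index_mean",
                 "index_sd", "ring_contrast", "elongation")

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


class DetectorContract(Protocol):
    """Minimal detector interface the experiment drivers rely on."""

    def fit(self, patches: Sequence[PatchRecord]) -> "DetectorContract": ...

    def predict(self, pixels: np.ndarray) -> list[Box]: ...


def exg_index(pixels: np.ndarray) -> np.ndarray:
    """Excess-green index 2g - r - b on chromatic coordinates, in [-1, 2].

    Pixels with R+G+B = 0 map to 0.  (2g - r - b with r+g+b = 1 equals
    (3G - S) / S for S = R+G+B.)
    """
    rgb = np.asarray(pixels, dtype=np.float32)
    total = rgb[..., 0] + rgb[..., 1] + rgb[..., 2]
    safe = np.where(total > 0, total, 1.0)
    return (3.0 * rgb[..., 1] - total) / safe


def _dilate3(m: np.ndarray) -> np.ndarray:
    """3x3 binary dilation (separable max, zero-padded borders)."""
    v = m.copy()
    v[:-1] |= m[1:]
    v[1:] |= m[:-1]
    h = v.copy()
    h[:, :-1] |= v[:, 1:]
    h[:, 1:] |= v[:, :-1]
    return h


def _erode3(m: np.ndarray) -> np.ndarray:
    """3x3 binary erosion (separable min, zero-padded borders)."""
    v = m.copy()
    v[:-1] &= m[1:]
    v[1:] &= m[:-1]
    v[0] = False
    v[-1] = False
    h = v.copy()
    h[:, :-1] &= v[:, 1:]
    h[:, 1:] &= v[:, :-1]
    h[:, 0] = False
    h[:, -1] = False
    return h


def _segment(index: np.ndarray, tau: float, tau_low: float | None = None):
    """Hysteresis segmentation: components are detected at the strict
    threshold ``tau`` (closing + opening to bridge gaps and drop speckle);
    the returned support mask uses the permissive ``tau_low``, whose
    connected extents recover dim structures (cotyledon tips, thin leaves)
    attached to a detected core."""
    mask = index > tau
    closed = _erode3(_dilate3(mask))
    opened = _dilate3(_erode3(closed))
    labels, n = ndi.label(opened, structure=_FOUR_CONN)
    if tau_low is None or tau_low >= tau:
        support = closed
    else:
        support = _erode3(_dilate3(index > tau_low))
    return labels, n, support


def propose_candidates(index: np.ndarray, tau: float,
                       min_area: int = 15, max_area: int = 6000,
                       tau_low: float | None = None) -> list[Box]:
    """Candidate boxes from 4-connected vegetation components.

    A 3x3 opening decides which components count (speckle removed, pixel
    count within [min_area, max_area]); each surviving component's box is
    then grown to the extent of its parent component in the permissive
    hysteresis mask (``tau_low``; the closed strict mask when not given),
    recovering thin structures the strict threshold or opening erased.
    """
    boxes, _ = _propose(index, tau, min_area, max_area, tau_low)
    return boxes


def _propose(index: np.ndarray, tau: float, min_area: int, max_area: int,
             tau_low: float | None = None):
    """Returns (boxes, per-candidate (slice, component mask, npix)) pairs."""
    labels, n, support = _segment(index, tau, tau_low)
    boxes: list[Box] = []
    comps = []
    if n == 0:
        return boxes, comps
    objects = ndi.find_objects(labels)
    closed_labels, _ = ndi.label(support, structure=_FOUR_CONN)
    closed_objects = ndi.find_objects(closed_labels)
    kept = []
    parent_count: dict[int, int] = {}
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        comp = labels[sl] == lab
        npix = int(comp.sum())
        if npix < min_area or npix > max_area:
            continue
        ys, xs = np.nonzero(comp)
        parent = int(closed_labels[sl[0].start + ys[0], sl[1].start + xs[0]])
        parent_count[parent] = parent_count.get(parent, 0) + 1
        kept.append((sl, comp, npix, parent))
    for sl, comp, npix, parent in kept:
        box = Box(float(sl[1].start), float(sl[0].start),
                  float(sl[1].stop), float(sl[0].stop))
        # grow to the parent extent in the closed mask (recovers thin tips)
        # unless the parent spans several candidates or is implausibly large
        if parent > 0 and parent_count[parent] == 1:
            psl = closed_objects[parent - 1]
            grown = Box(float(psl[1].start), float(psl[0].start),
                        float(psl[1].stop), float(psl[0].stop))
            if grown.area <= 3.0 * box.area:
                box = grown
        boxes.append(box)
        comps.append((sl, comp, npix))
    return boxes, comps


def _features_one(index: np.ndarray, box: Box, sl, comp: np.ndarray,
                  npix: int) -> np.ndarray:
    h, w = index.shape
    bw = box.max_x - box.min_x
    bh = box.max_y - box.min_y
    inside = index[sl]
    # 4-pixel ring around the box for local contrast
    y0, y1 = max(int(box.min_y) - 4, 0), min(int(box.max_y) + 4, h)
    x0, x1 = max(int(box.min_x) - 4, 0), min(int(box.max_x) + 4, w)
    ring = index[y0:y1, x0:x1]
    ring_sum = ring.sum() - inside.sum()
    ring_n = ring.size - inside.size
    ring_mean = ring_sum / ring_n if ring_n > 0 else 0.0
    comp_vals = inside[comp]
    # second moments of the component -> elongation in [0, 1)
    ys, xs = np.nonzero(comp)
    yc, xc = ys.mean(), xs.mean()
    cyy = ((ys - yc) ** 2).mean()
    cxx = ((xs - xc) ** 2).mean()
    cxy = ((ys - yc) * (xs - xc)).mean()
    tr, det = cxx + cyy, cxx * cyy - cxy * cxy
    disc = max(tr * tr / 4.0 - det, 0.0) ** 0.5
    l1, l2 = tr / 2.0 + disc, max(tr / 2.0 - disc, 1e-9)
    return np.array([
        np.log(npix),
        bw / bh,
        npix / (bw * bh),
        comp_vals.mean(),
        comp_vals.std(),
        comp_vals.mean() - ring_mean,
        1.0 - l2 / l1,
    ], dtype=float)


def candidate_features(pixels: np.ndarray, candidate: Box,
                       tau: float) -> np.ndarray:
    """Unnormalised feature vector for one candidate box (fixed order, see
    FEATURE_NAMES).  The component is re-derived by thresholding at ``tau``
    inside the box."""
    h, w = pixels.shape[:2]
    if (candidate.min_x < 0 or candidate.min_y < 0
            or candidate.max_x > w or candidate.max_y > h):
        raise ValueError("candidate lies outside the patch")
    index = exg_index(pixels)
    sl = (slice(int(candidate.min_y), int(round(candidate.max_y))),
          slice(int(candidate.min_x), int(round(candidate.max_x))))
    comp = index[sl] > tau
    if not comp.any():
        comp = np.ones_like(comp, dtype=bool)
    return _features_one(index, candidate, sl, comp, int(comp.sum()))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -40, 40)))


def _expand(Xn: np.ndarray) -> np.ndarray:
    """Polynomial expansion of normalised features: degree-2 and degree-3
    interaction terms.  The capacity is deliberately generous for the sample
    sizes studied, so the classifier's variance — and hence the benefit of
    more training data — is realistic rather than saturating immediately."""
    n, d = Xn.shape
    iu, ju = np.triu_indices(d)
    quad = Xn[:, iu] * Xn[:, ju]
    cubic = quad[:, :, None] * Xn[:, None, :]
    return np.concatenate([Xn, quad, cubic.reshape(n, -1)], axis=1)


def _contained(inner: Box, outer: Box, tol: float = 1.5) -> bool:
    return (inner.min_x >= outer.min_x - tol and inner.min_y >= outer.min_y - tol
            and inner.max_x <= outer.max_x + tol and inner.max_y <= outer.max_y + tol)


def _label_candidates(cand, comps, annos, iou_positive):
    """Positive (candidate, annotation) pairs for training.

    A candidate is positive when its best-IoU annotation passes the IoU
    threshold.  For annotations left unmatched (typically because they were
    dilated far beyond the tight vegetation extent — dilation only ever
    expands a box), the largest contained candidate is positive; smaller
    contained fragments stay negative.
    """
    pairs: list[tuple[int, int]] = []
    if not annos:
        return pairs
    matched_ann: set[int] = set()
    unmatched_cand: list[int] = []
    for ci, box in enumerate(cand):
        ious = [iou(box, a) for a in annos]
        j = int(np.argmax(ious))
        if ious[j] >= iou_positive:
            pairs.append((ci, j))
            matched_ann.add(j)
        else:
            unmatched_cand.append(ci)
    for aj, a in enumerate(annos):
        if aj in matched_ann:
            continue
        inside = [ci for ci in unmatched_cand if _contained(cand[ci], a)]
        if inside:
            biggest = max(inside, key=lambda ci: comps[ci][2])
            pairs.append((biggest, aj))
            unmatched_cand.remove(biggest)
    return pairs


class SeedlingDetector(BaseEstimator):
    """Propose-and-classify reference detector (see module docstring).

    Parameters
    ----------
    tau_quantiles : grid of ExG quantile *levels* searched for the adaptive
        vegetation threshold at fit time; the fitted ``tau_`` is the level,
        and each patch is thresholded at that quantile of its own index
        distribution.
    min_area, max_area : proposal component area band, in pixels.
    learning_rate, n_iter, l2 : logistic-model gradient-descent settings
        (full batch, fixed iteration count, zero init — deterministic).
    tau_search_patches : at most this many training patches are used to
        score the tau grid (a uniform subsample of the pool).
    iou_positive : IoU at which a proposal matched to an annotation is
        labeled positive.  Proposals geometrically contained in their
        best-overlapping annotation are also positive — the signature of a
        dilated (loose) label, which only ever expands boxes.
    random_state : accepted for API symmetry; the fit is deterministic.
    """

    def __init__(self, tau_quantiles=(0.90, 0.95, 0.97, 0.98, 0.985,
                                      0.99, 0.9925, 0.995),
                 min_area: int = 15, max_area: int = 6000,
                 learning_rate: float = 0.4, n_iter: int = 1500,
                 l2: float = 1e-4, tau_search_patches: int = 400,
                 iou_positive: float = 0.5,
                 hysteresis_drop: float = 0.0, random_state=None):
        self.tau_quantiles = tau_quantiles
        self.min_area = min_area
        self.max_area = max_area
        self.learning_rate = learning_rate
        self.n_iter = n_iter
        self.l2 = l2
        self.tau_search_patches = tau_search_patches
        self.iou_positive = iou_positive
        self.hysteresis_drop = hysteresis_drop
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------

    @staticmethod
    def _patch_tau(index: np.ndarray, level: float) -> float:
        """Per-patch adaptive threshold: the ``level`` quantile of the
        patch's own (subsampled) ExG distribution."""
        return float(np.quantile(index[::3, ::3], level))

    def _patch_taus(self, index: np.ndarray,
                    level: float) -> tuple[float, float]:
        """(strict, permissive) hysteresis thresholds for one patch."""
        low_level = max(level - self.hysteresis_drop, 0.5)
        strict, low = np.quantile(index[::3, ::3], [level, low_level])
        return float(strict), float(low)

    def _search_tau_level(self, patches: Sequence[PatchRecord],
                          indices: list[np.ndarray]) -> float:
        """Grid search for the threshold quantile level.

        Proposal F1 is scored on up to ``tau_search_patches`` patches at
        half resolution (areas scale by 4, coordinates by 2): ranking the
        levels is robust to the resolution, and the cheaper evaluation buys
        a larger subsample, which stabilises the argmax against sampling
        luck.  Ties within half a point of F1 resolve to the higher level
        (fewer, cleaner proposals).
        """
        k = min(len(patches), self.tau_search_patches)
        step = max(1, len(patches) // k)
        subset = list(range(0, len(patches), step))[:k]
        proposal_thresholds = EvalThresholds(iou_min=self.iou_positive,
                                             conf_min=0.0, exclusive_conf=False)
        best_level, best_f1 = float(self.tau_quantiles[0]), -1.0
        for level in self.tau_quantiles:
            tp = fp = fn = 0
            for i in subset:
                half = indices[i][::2, ::2]
                tau, tau_low = self._patch_taus(half, level)
                cand, _ = _propose(half, tau, self.min_area // 4,
                                   self.max_area // 4, tau_low)
                scored = [Box(2 * b.min_x, 2 * b.min_y,
                              2 * b.max_x, 2 * b.max_y, 1.0) for b in cand]
                m = match_detections(scored, list(patches[i].annotations),
                                     proposal_thresholds)
                tp += m.tp
                fp += m.fp
                fn += m.fn
            f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
            if f1 > best_f1 - 0.005:
                best_level, best_f1 = float(level), max(f1, best_f1)
        return best_level

    def fit(self, patches: Sequence[PatchRecord], y=None,
            rng: np.random.Generator | None = None) -> "SeedlingDetector":
        """Fit on annotated training patches.

        Raises if the pool carries no annotations at all (nothing to label
        candidates against).
        """
        patches = list(patches)
        n_annos = sum(len(p.annotations) for p in patches)
        if not patches or n_annos == 0:
            raise ValueError("training pool has no annotations")
        indices = [exg_index(p.pixels) for p in patches]
        self.tau_ = self._search_tau_level(patches, indices)

        feats, labels, margins = [], [], []
        for patch, index in zip(patches, indices):
            tau, tau_low = self._patch_taus(index, self.tau_)
            cand, comps = _propose(index, tau, self.min_area, self.max_area,
                                   tau_low)
            annos = list(patch.annotations)
            for box, (sl, comp, npix) in zip(cand, comps):
                feats.append(_features_one(index, box, sl, comp, npix))
            pos_pairs = _label_candidates(cand, comps, annos,
                                          self.iou_positive)
            base = len(labels)
            labels.extend([0.0] * len(cand))
            for ci, aj in pos_pairs:
                labels[base + ci] = 1.0
                box, best = cand[ci], annos[aj]
                margins.append([box.min_x - best.min_x,
                                box.min_y - best.min_y,
                                best.max_x - box.max_x,
                                best.max_y - box.max_y])

        X = np.array(feats) if feats else np.empty((0, len(FEATURE_NAMES)))
        yv = np.array(labels)
        self.feature_mean_ = X.mean(axis=0) if len(X) else np.zeros(X.shape[1])
        std = X.std(axis=0) if len(X) else np.ones(X.shape[1])
        self.feature_std_ = np.where(std > 1e-6, std, 1.0)
        Xn = _expand((X - self.feature_mean_) / self.feature_std_)

        w = np.zeros(Xn.shape[1])
        b = 0.0
        n = max(len(Xn), 1)
        for _ in range(self.n_iter):
            p = _sigmoid(Xn @ w + b)
            err = p - yv
            w -= self.learning_rate * (Xn.T @ err / n + self.l2 * w)
            b -= self.learning_rate * float(err.mean())
        self.coef_ = w
        self.intercept_ = b
        # mean across matched pairs; the largest-contained-candidate rule
        # keeps fragments out, so the mean tracks the systematic offset
        # (including the N/2 inflation induced by dilated labels)
        self.box_margins_ = (np.mean(margins, axis=0) if margins
                             else np.zeros(4))
        self.n_patches_ = len(patches)
        self.n_annotations_ = n_annos
        return self

    # -- inference ---------------------------------------------------------

    def predict(self, pixels: np.ndarray) -> list[Box]:
        """Scored boxes for one patch; deterministic, confidences in [0, 1]."""
        if not hasattr(self, "coef_"):
            raise RuntimeError("detector is not fitted")
        h, w = pixels.shape[:2]
        index = exg_index(pixels)
        tau, tau_low = self._patch_taus(index, self.tau_)
        cand, comps = _propose(index, tau, self.min_area, self.max_area,
                               tau_low)
        out: list[Box] = []
        m = self.box_margins_
        for box, (sl, comp, npix) in zip(cand, comps):
            f = _features_one(index, box, sl, comp, npix)
            base = (f - self.feature_mean_) / self.feature_std_
            fn = _expand(base[None, :])[0]
            conf = float(_sigmoid(np.array([fn @ self.coef_
                                            + self.intercept_]))[0])
            x0 = max(box.min_x - m[0], 0.0)
            y0 = max(box.min_y - m[1], 0.0)
            x1 = min(box.max_x + m[2], float(w))
            y1 = min(box.max_y + m[3], float(h))
            if x1 > x0 and y1 > y0:
                out.append(Box(x0, y0, x1, y1, conf))
        return out

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        state = {
            "format": "seedbench-detector/1",
            "params": self.get_params(),
            "tau": self.tau_,
            "coef": self.coef_.tolist(),
            "intercept": self.intercept_,
            "feature_mean": self.feature_mean_.tolist(),
            "feature_std": self.feature_std_.tolist(),
            "box_margins": self.box_margins_.tolist(),
            "n_patches": self.n_patches_,
            "n_annotations": self.n_annotations_,
        }
        return json.dumps(state, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SeedlingDetector":
        state = json.loads(text)
        if state.get("format") != "seedbench-detector/1":
            raise ValueError("unrecognised model format")
        params = state["params"]
        params["tau_quantiles"] = tuple(params["tau_quantiles"])
        det = cls(**params)
        det.tau_ = state["tau"]
        det.coef_ = np.array(state["coef"])
        det.intercept_ = state["intercept"]
        det.feature_mean_ = np.array(state["feature_mean"])
        det.feature_std_ = np.array(state["feature_std"])
        det.box_margins_ = np.array(state["box_margins"])
        det.n_patches_ = state["n_patches"]
        det.n_annotations_ = state["n_annotations"]
        return det


class MockDetector(BaseEstimator):
    """Contract-compliance stand-in: predicts a fixed box list regardless of
    pixels.  Used to test experiment drivers independently of the reference
    implementation."""

    def __init__(self, boxes: tuple = ()):
        self.boxes = boxes

    def fit(self, patches: Sequence[PatchRecord], y=None,
            rng=None) -> "MockDetector":
        self.fitted_ = True
        return self

    def predict(self, pixels: np.ndarray) -> list[Box]:
        return list(self.boxes)


def fit(patches: Sequence[PatchRecord], config: dict | None = None,
        rng: np.random.Generator | None = None) -> SeedlingDetector:
    """Functional wrapper: fit a :class:`SeedlingDetector`."""
    det = SeedlingDetector(**(config or {}))
    return det.fit(patches, rng=rng)


def predict(model: SeedlingDetector, pixels: np.ndarray) -> list[Box]:
    """Functional wrapper over :meth:`SeedlingDetector.predict`."""
    return model.predict(pixels)
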
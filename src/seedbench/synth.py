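"""Synthetic multi-domain aerial field images with ground-truth seedling boxes.

Each *image set* plays the role of one drone acquisition session over one
field, i.e. one visual **domain**.  A :class:`DomainParams` vector fixes the
domain's appearance: seedling density and row geometry, cotyledon size,
foliage colour, soil colour and texture, illumination, sharpness (blur),
sensor noise, and the rates of two unannotated distractors — green weeds
(irregular blobs, distinguishable from seedlings by shape, not colour) and
pale stubble straw (straight segments that can occlude seedlings).

A seedling is rendered as a pair of opposed cotyledon ellipses about a small
center disc, plus 0-4 true leaves at random angles.  ``cotyledon_length`` is
the center-to-tip distance of one cotyledon, so an unoccluded seedling spans
about twice that value.  Its annotation is the tight bounding box of its
painted pixels; a seedling is annotated only if at least 30% of those pixels
remain visible under surface stubble (emulating what a human annotator can
still identify).  Weeds and stubble are never annotated.

Rendering order: soil -> ground stubble -> plants and weeds -> surface
stubble (occluding) -> illumination scaling -> Gaussian blur -> sensor
noise.  Everything is deterministic given the seeds.

Benchmark layout mirrors the real dataset's structure: k_train domains each
contribute a training split and a held-out in-distribution (ID) test split;
k_ood freshly sampled domains form the out-of-distribution (OOD) test split.
OOD domains are drawn from wider parameter ranges than training domains
(smaller/larger plants, stronger blur, harsher lighting, more distractors),
so OOD evaluation genuinely probes generalisation under domain shift.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
import numpy as np
from scipy import ndimage as ndi
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from .geometry import Box
from ._rng import child_rng

__all__ = [
    "DomainParams",
    "DomainRanges",
    "ImageRecord",
    "ImageSet",
    "BenchmarkLayout",
    "TRAIN_RANGES",
    "OOD_RANGES",
    "sample_domain_params",
    "render_field_image",
    "generate_image_set",
    "build_benchmark",
]


@dataclass(frozen=True)
class DomainParams:
    """Generative parameters for one domain (units in comments)."""

    seed: int = 0
    plant_rate: float = 12.0         # expected seedlings per image (Poisson mean)
    row_spacing: float = 85.0        # px between crop rows
    row_jitter: float = 5.0          # px sd of in-row lateral scatter
    cotyledon_len_mean: float = 12.0  # px, center-to-tip of one cotyledon
    cotyledon_len_sd: float = 1.8    # px
    leaf_max: int = 3                # true leaves drawn ~ U{0..leaf_max}
    hue_center: float = 0.30         # HSV hue of foliage (0..1)
    sat_center: float = 0.6          # HSV saturation of foliage
    soil_r: float = 125.0            # soil base colour, 8-bit scale
    soil_g: float = 100.0
    soil_b: float = 75.0
    soil_roughness: float = 4.0      # px, correlation length of soil texture
    illumination: float = 1.0        # multiplicative brightness
    blur_sigma: float = 0.6          # px, Gaussian PSF sigma
    noise_sd: float = 4.0            # 8-bit counts, additive sensor noise
    weed_rate: float = 6.0           # expected weeds per image (never annotated)
    stubble_rate: float = 8.0        # expected straw segments per image

    def __post_init__(self) -> None:
        for name in ("plant_rate", "weed_rate", "stubble_rate", "blur_sigma",
                     "noise_sd", "row_jitter", "cotyledon_len_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.illumination <= 0:
            raise ValueError("illumination must be > 0")
        if self.cotyledon_len_mean <= 0:
            raise ValueError("cotyledon_len_mean must be > 0")


# (low, high) per sampled field; leaf_max is integer-valued
_RangeT = tuple[float, float]


@dataclass(frozen=True)
class DomainRanges:
    # plant_rate chosen so annotation density is ~1.0-2.2 per 416x416 patch
    # of an 832x832 image, matching early-season field datasets
    plant_rate: _RangeT = (4.0, 9.0)
    row_spacing: _RangeT = (60.0, 110.0)
    row_jitter: _RangeT = (2.0, 8.0)
    cotyledon_len_mean: _RangeT = (8.0, 16.0)
    cotyledon_len_sd: _RangeT = (1.0, 2.5)
    leaf_max: _RangeT = (0, 4)
    hue_center: _RangeT = (0.22, 0.38)
    sat_center: _RangeT = (0.45, 0.80)
    soil_r: _RangeT = (100.0, 150.0)
    soil_g: _RangeT = (80.0, 120.0)
    soil_b: _RangeT = (55.0, 95.0)
    soil_roughness: _RangeT = (2.0, 6.0)
    illumination: _RangeT = (0.75, 1.25)
    blur_sigma: _RangeT = (0.0, 1.5)
    noise_sd: _RangeT = (2.0, 8.0)
    weed_rate: _RangeT = (0.0, 12.0)
    stubble_rate: _RangeT = (0.0, 18.0)


#: ranges used for training (and hence ID-test) domains
TRAIN_RANGES = DomainRanges()

#: wider ranges for OOD test domains — the distribution shift of the benchmark
OOD_RANGES = DomainRanges(
    plant_rate=(3.0, 11.0),
    row_spacing=(55.0, 120.0),
    row_jitter=(2.0, 10.0),
    cotyledon_len_mean=(6.5, 18.0),
    cotyledon_len_sd=(1.0, 3.0),
    leaf_max=(0, 4),
    hue_center=(0.21, 0.40),
    sat_center=(0.40, 0.82),
    soil_r=(95.0, 158.0),
    soil_g=(75.0, 126.0),
    soil_b=(50.0, 100.0),
    soil_roughness=(1.8, 7.0),
    illumination=(0.65, 1.35),
    blur_sigma=(0.0, 2.0),
    noise_sd=(2.0, 10.0),
    weed_rate=(0.0, 18.0),
    stubble_rate=(0.0, 24.0),
)


@dataclass(frozen=True)
class ImageRecord:
    image_id: str
    pixels: np.ndarray                 # (H, W, 3) uint8
    annotations: tuple[Box, ...]
    domain_id: str = ""


@dataclass
class ImageSet:
    """All images from one acquisition session (= one domain)."""

    set_id: str
    images: list[ImageRecord]
    params: DomainParams | None = None
    role: str = ""


@dataclass
class BenchmarkLayout:
    train_sets: list[ImageSet]
    id_test_sets: list[ImageSet]
    ood_test_sets: list[ImageSet]

    def all_sets(self) -> list[ImageSet]:
        return self.train_sets + self.id_test_sets + self.ood_test_sets


def sample_domain_params(rng: np.random.Generator,
                         ranges: DomainRanges = TRAIN_RANGES,
                         seed: int | None = None) -> DomainParams:
    """Draw each domain parameter independently and uniformly from its range.

    Draw order follows DomainRanges field order (stable across calls).
    """
    values = {}
    for f in dc_fields(ranges):
        low, high = getattr(ranges, f.name)
        if high < low:
            raise ValueError(f"malformed range for {f.name}: {low} > {high}")
        if f.name == "leaf_max":
            values[f.name] = int(rng.integers(int(low), int(high) + 1))
        else:
            values[f.name] = float(low) if low == high else float(rng.uniform(low, high))
    if seed is None:
        seed = int(rng.integers(0, 2**31))
    return DomainParams(seed=seed, **values)


def _hsv_to_rgb(h: float, s: float, v: float) -> np.ndarray:
    i = int(h * 6.0) % 6
    f = h * 6.0 - int(h * 6.0)
    p, q, t = v * (1 - s), v * (1 - s * f), v * (1 - s * (1 - f))
    rgb = [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)][i]
    return np.array(rgb) * 255.0


def _paint_blob(img: np.ndarray, mask_rows: np.ndarray, mask_cols: np.ndarray,
                color: np.ndarray, rng: np.random.Generator) -> None:
    jitter = rng.normal(0.0, 6.0, size=(mask_rows.size, 3))
    img[mask_rows, mask_cols] = color[None, :] + jitter


def _draw_seedling(params: DomainParams, cx: float, cy: float,
                   shape: tuple[int, int], rng: np.random.Generator,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Rasterise one seedling; returns (rows, cols) of its painted pixels."""
    L = max(2.5, rng.normal(params.cotyledon_len_mean, params.cotyledon_len_sd))
    theta = rng.uniform(0.0, np.pi)
    # cotyledon: ellipse with semi-major 0.36 L, centered 0.70 L from the
    # plant center, so the tip sits at ~distance L (center-to-tip ~= L)
    d, semi_a, semi_b = 0.70 * L, 0.36 * L, 0.22 * L
    rr_all, cc_all = [], []
    for sgn in (+1.0, -1.0):
        ecx = cx + sgn * d * np.cos(theta)
        ecy = cy + sgn * d * np.sin(theta)
        rr, cc = draw_ellipse(ecy, ecx, semi_b, semi_a,
                              shape=shape, rotation=-theta)
        rr_all.append(rr)
        cc_all.append(cc)
    rr, cc = draw_disk((cy, cx), max(1.5, 0.22 * L), shape=shape)
    rr_all.append(rr)
    cc_all.append(cc)
    # petioles: thin connector from the center to each cotyledon base,
    # keeping the rendered seedling one connected component
    for sgn in (+1.0, -1.0):
        pcx = cx + sgn * 0.5 * d * np.cos(theta)
        pcy = cy + sgn * 0.5 * d * np.sin(theta)
        rr, cc = draw_ellipse(pcy, pcx, max(1.2, 0.10 * L), 0.5 * d,
                              shape=shape, rotation=-theta)
        rr_all.append(rr)
        cc_all.append(cc)
    n_leaves = int(rng.integers(0, params.leaf_max + 1))
    for _ in range(n_leaves):
        phi = rng.uniform(0.0, 2 * np.pi)
        lcx = cx + 0.35 * L * np.cos(phi)
        lcy = cy + 0.35 * L * np.sin(phi)
        rr, cc = draw_ellipse(lcy, lcx, 0.14 * L, 0.28 * L,
                              shape=shape, rotation=-phi)
        rr_all.append(rr)
        cc_all.append(cc)
    return np.concatenate(rr_all), np.concatenate(cc_all)


def _draw_weed(cx: float, cy: float, size: float, shape: tuple[int, int],
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Unannotated green distractor: an irregular blob built from a short
    random walk of overlapping discs — same hue family as the crop, so
    separation relies on shape, not colour."""
    rr_all, cc_all = [], []
    x, y = cx, cy
    for _ in range(int(rng.integers(4, 9))):
        r = rng.uniform(0.12 * size, 0.3 * size)
        rr, cc = draw_disk((y, x), max(1.0, r), shape=shape)
        rr_all.append(rr)
        cc_all.append(cc)
        step = rng.uniform(0.15 * size, 0.4 * size)
        ang = rng.uniform(0, 2 * np.pi)
        x += step * np.cos(ang)
        y += step * np.sin(ang)
    return np.concatenate(rr_all), np.concatenate(cc_all)


def _stubble_segment(width: int, height: int, rng: np.random.Generator,
                     ) -> tuple[np.ndarray, np.ndarray]:
    cx, cy = rng.uniform(0, width), rng.uniform(0, height)
    ang = rng.uniform(0, np.pi)
    length = rng.uniform(40.0, 160.0)
    half_w = rng.uniform(0.8, 2.0)
    dx, dy = np.cos(ang), np.sin(ang)
    px, py = -dy, dx
    xs = [cx - dx * length / 2 + px * half_w, cx + dx * length / 2 + px * half_w,
          cx + dx * length / 2 - px * half_w, cx - dx * length / 2 - px * half_w]
    ys = [cy - dy * length / 2 + py * half_w, cy + dy * length / 2 + py * half_w,
          cy + dy * length / 2 - py * half_w, cy - dy * length / 2 - py * half_w]
    return draw_polygon(ys, xs, shape=(height, width))


VISIBILITY_MIN = 0.30  # annotate a seedling iff this fraction of it stays visible


def render_field_image(params: DomainParams, width: int, height: int,
                       rng: np.random.Generator,
                       image_id: str = "", domain_id: str = "") -> ImageRecord:
    """Render one field image and its ground-truth annotations."""
    if min(width, height) < 64:
        raise ValueError("image dimensions too small (< 64 px)")
    shape = (height, width)
    img = np.empty((height, width, 3), dtype=np.float32)

    # per-image realisation: conditions drift mildly within an acquisition
    # session (sun angle, exposure, focus change between frames)
    illumination = params.illumination * float(rng.uniform(0.92, 1.08))
    blur_sigma = max(0.0, params.blur_sigma + float(rng.uniform(-0.15, 0.15)))
    noise_sd = params.noise_sd * float(rng.uniform(0.9, 1.1))

    # soil: base colour modulated by low-frequency texture
    texture = ndi.gaussian_filter(
        rng.standard_normal(shape, dtype=np.float32), params.soil_roughness)
    sd = texture.std()
    if sd > 0:
        texture /= sd
    base = np.array([params.soil_r, params.soil_g, params.soil_b], np.float32)
    img[:] = base[None, None, :] * (1.0 + 0.12 * texture[:, :, None])

    straw_color = np.array([205.0, 192.0, 158.0])
    n_stubble = rng.poisson(params.stubble_rate)
    surface_segments = []  # drawn after plants, can occlude
    for _ in range(n_stubble):
        rr, cc = _stubble_segment(width, height, rng)
        if rng.random() < 0.5:
            surface_segments.append((rr, cc))
        elif rr.size:
            _paint_blob(img, rr, cc, straw_color, rng)

    # plants on jittered rows
    n_plants = rng.poisson(params.plant_rate)
    margin = min(2.5 * params.cotyledon_len_mean, width / 2 - 1, height / 2 - 1)
    x0 = rng.uniform(0, params.row_spacing)
    rows = np.arange(x0, width, params.row_spacing)
    plant_pixels = []  # (rows, cols) per seedling
    for _ in range(n_plants):
        rx = rows[rng.integers(0, len(rows))] if len(rows) else rng.uniform(0, width)
        cx = float(np.clip(rx + rng.normal(0.0, params.row_jitter), margin,
                           width - margin))
        cy = float(rng.uniform(margin, height - margin))
        rr, cc = _draw_seedling(params, cx, cy, shape, rng)
        plant_pixels.append((rr, cc))
        color = _hsv_to_rgb(
            params.hue_center + rng.uniform(-0.02, 0.02),
            float(np.clip(params.sat_center + rng.uniform(-0.08, 0.08), 0, 1)),
            rng.uniform(0.45, 0.65))
        if rr.size:
            _paint_blob(img, rr, cc, color, rng)

    n_weeds = rng.poisson(params.weed_rate)
    for _ in range(n_weeds):
        wx, wy = rng.uniform(0, width), rng.uniform(0, height)
        # weed size is independent of the crop's growth stage
        wsize = rng.uniform(8.0, 18.0)
        rr, cc = _draw_weed(wx, wy, wsize, shape, rng)
        color = _hsv_to_rgb(
            params.hue_center + rng.uniform(-0.03, 0.03),
            float(np.clip(params.sat_center + rng.uniform(-0.1, 0.1), 0, 1)),
            rng.uniform(0.40, 0.62))
        if rr.size:
            _paint_blob(img, rr, cc, color, rng)

    # surface stubble occludes whatever lies beneath it
    occluded = np.zeros(shape, dtype=bool)
    for rr, cc in surface_segments:
        if rr.size:
            _paint_blob(img, rr, cc, straw_color, rng)
            occluded[rr, cc] = True

    annotations = []
    for rr, cc in plant_pixels:
        if rr.size == 0:
            continue
        visible = 1.0 - occluded[rr, cc].mean()
        if visible < VISIBILITY_MIN:
            continue
        annotations.append(Box(float(cc.min()), float(rr.min()),
                               float(cc.max() + 1), float(rr.max() + 1)))

    img *= illumination
    if blur_sigma > 0.05:
        img = ndi.gaussian_filter(img, (blur_sigma, blur_sigma, 0))
    if noise_sd > 0:
        img += noise_sd * rng.standard_normal(img.shape, dtype=np.float32)
    pixels = np.clip(img, 0, 255).astype(np.uint8)
    return ImageRecord(image_id=image_id, pixels=pixels,
                       annotations=tuple(annotations), domain_id=domain_id)


def generate_image_set(params: DomainParams, n_images: int,
                       dims: tuple[int, int], set_id: str = "set",
                       role: str = "") -> ImageSet:
    """Render ``n_images`` from one domain, each under a per-image sub-seed
    derived from ``params.seed``."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    width, height = dims
    images = []
    for i in range(n_images):
        rng = child_rng(params.seed, "image", i)
        images.append(render_field_image(
            params, width, height, rng,
            image_id=f"{set_id}/img{i:03d}", domain_id=set_id))
    return ImageSet(set_id=set_id, images=images, params=params, role=role)


def build_benchmark(k_train: int = 8, k_ood: int = 8,
                    images_per_set: int = 100,
                    dims: tuple[int, int] = (832, 832),
                    seed: int = 0,
                    n_test_images: int = 6,
                    train_ranges: DomainRanges = TRAIN_RANGES,
                    ood_ranges: DomainRanges = OOD_RANGES) -> BenchmarkLayout:
    """Build the desk-scale benchmark.

    Each of ``k_train`` domains contributes ``images_per_set`` training
    images and ``n_test_images`` held-out ID-test images (same DomainParams,
    disjoint per-image seeds).  ``k_ood`` freshly sampled domains (from the
    wider ``ood_ranges``) each contribute ``n_test_images`` OOD-test images.
    """
    if k_train < 1 or k_ood < 1:
        raise ValueError("k_train and k_ood must be >= 1")
    train_sets, id_sets, ood_sets = [], [], []
    for i in range(k_train):
        rng = child_rng(seed, "domain", "train", i)
        params = sample_domain_params(rng, train_ranges,
                                      seed=int(rng.integers(0, 2**31)))
        sid = f"train{i:02d}"
        train_sets.append(generate_image_set(
            params, images_per_set, dims, set_id=sid, role="train"))
        # held-out split of the same domain: new seed, same appearance regime
        id_params = DomainParams(**{**_params_dict(params),
                                    "seed": int(rng.integers(0, 2**31))})
        id_sets.append(generate_image_set(
            id_params, n_test_images, dims, set_id=f"id{i:02d}",
            role="id_test"))
    for i in range(k_ood):
        rng = child_rng(seed, "domain", "ood", i)
        params = sample_domain_params(rng, ood_ranges,
                                      seed=int(rng.integers(0, 2**31)))
        ood_sets.append(generate_image_set(
            params, n_test_images, dims, set_id=f"ood{i:02d}",
            role="ood_test"))
    return BenchmarkLayout(train_sets, id_sets, ood_sets)


def _params_dict(p: DomainParams) -> dict:
    return {f.name: getattr(p, f.name) for f in dc_fields(p)}
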
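import numpy as np
import pytest

from seedbench.geometry import (Box, EvalThresholds, image_accuracy, iou,
                                match_detections)
from seedbench.patching import (PatchRecord, augment_patch, extract_patches,
                                merge_patch_predictions, plan_grid)
from seedbench.synth import ImageRecord


def make_image(width, height, annotations, fill=30):
    pixels = np.full((height, width, 3), fill, dtype=np.uint8)
    return ImageRecord("img", pixels, tuple(annotations))


class TestPlanGrid:
    @pytest.mark.parametrize("dims, patch, overlap, axis_origins", [
        ((832, 832), 416, 0.0, (0, 416)),
        ((1000, 1000), 416, 0.0, (0, 416, 584)),
        ((832, 832), 416, 0.5, (0, 208, 416)),
    ])
    def test_origin_layouts(self, dims, patch, overlap, axis_origins):
        grid = plan_grid(*dims, patch, overlap)
        xs = sorted({o[0] for o in grid.origins})
        ys = sorted({o[1] for o in grid.origins})
        assert tuple(xs) == axis_origins
        assert tuple(ys) == axis_origins
        assert grid.n_patches == len(axis_origins) ** 2

    def test_full_coverage_and_in_bounds(self, rng):
        for _ in range(50):
            w = int(rng.integers(416, 1500))
            h = int(rng.integers(416, 1500))
            overlap = float(rng.choice([0.0, 0.25, 0.5]))
            grid = plan_grid(w, h, 416, overlap)
            covered = np.zeros((h, w), dtype=bool)
            for ox, oy in grid.origins:
                assert ox + 416 <= w and oy + 416 <= h
                covered[oy:oy + 416, ox:ox + 416] = True
            assert covered.all()

    def test_patch_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            plan_grid(400, 900, 416, 0.0)


class TestExtractPatches:
    def test_interior_box_appears_once_unclipped(self):
        img = make_image(832, 832, [Box(100, 100, 140, 130)])
        grid = plan_grid(832, 832, 416, 0.0)
        recs = extract_patches(img, grid)
        found = [(r.origin, b) for r in recs for b in r.annotations]
        assert len(found) == 1
        (origin, b) = found[0]
        assert origin == (0, 0)
        assert (b.min_x, b.min_y, b.max_x, b.max_y) == (100, 100, 140, 130)

    def test_straddling_box_kept_by_majority_side(self):
        # 30% of the box is left of x=416, 70% right
        img = make_image(832, 832, [Box(410, 100, 430, 120)])
        grid = plan_grid(832, 832, 416, 0.0)
        recs = {r.origin: r for r in extract_patches(img, grid, 0.5)}
        assert recs[(0, 0)].annotations == ()
        right = recs[(416, 0)].annotations
        assert len(right) == 1
        b = right[0]
        assert (b.min_x, b.min_y, b.max_x, b.max_y) == (0, 100, 14, 120)

    def test_keep_fraction_zero_retains_all_intersections(self):
        img = make_image(832, 832, [Box(410, 100, 430, 120)])
        grid = plan_grid(832, 832, 416, 0.0)
        recs = extract_patches(img, grid, keep_fraction=0.0)
        assert sum(len(r.annotations) for r in recs) == 2

    def test_interior_count_conserved_without_clipping(self, rng):
        boxes = []
        for _ in range(30):
            # keep boxes clear of the x/y = 416 boundary
            qx, qy = rng.integers(0, 2, size=2)
            x0 = float(rng.integers(qx * 416 + 5, qx * 416 + 350))
            y0 = float(rng.integers(qy * 416 + 5, qy * 416 + 350))
            boxes.append(Box(x0, y0, x0 + 30, y0 + 20))
        img = make_image(832, 832, boxes)
        grid = plan_grid(832, 832, 416, 0.0)
        recs = extract_patches(img, grid, keep_fraction=0.0)
        assert sum(len(r.annotations) for r in recs) == 30
        for r in recs:
            for b in r.annotations:
                assert 0 <= b.min_x < b.max_x <= 416
                assert 0 <= b.min_y < b.max_y <= 416


class _SeqRng:
    """Deterministic stand-in yielding a fixed sequence of uniforms."""

    def __init__(self, seq):
        self.seq = list(seq)

    def random(self, n):
        out, self.seq = self.seq[:n], self.seq[n:]
        return np.array(out)


class TestAugmentPatch:
    def patch(self, boxes=()):
        rng = np.random.default_rng(0)
        pixels = rng.integers(0, 255, size=(416, 416, 3), dtype=np.uint8)
        return PatchRecord("img", (0, 0), pixels, tuple(boxes))

    def test_identity_when_all_draws_high(self):
        p = self.patch([Box(10, 20, 30, 40)])
        out = augment_patch(p, _SeqRng([0.9, 0.9, 0.9]))
        assert np.array_equal(out.pixels, p.pixels)
        assert out.annotations == p.annotations

    def test_horizontal_flip_coordinates(self):
        p = self.patch([Box(10, 20, 30, 40)])
        out = augment_patch(p, _SeqRng([0.9, 0.1, 0.9]))  # flip h only
        b = out.annotations[0]
        assert (b.min_x, b.min_y, b.max_x, b.max_y) == (386, 20, 406, 40)
        assert np.array_equal(out.pixels, p.pixels[:, ::-1])

    def test_flip_twice_is_identity(self):
        p = self.patch([Box(10, 20, 30, 40), Box(100, 5, 150, 80)])
        once = augment_patch(p, _SeqRng([0.9, 0.1, 0.9]))
        twice = augment_patch(once, _SeqRng([0.9, 0.1, 0.9]))
        assert np.array_equal(twice.pixels, p.pixels)
        assert twice.annotations == p.annotations

    def test_rotation_moves_pixels_with_boxes(self):
        p = self.patch([Box(10, 20, 30, 40)])
        out = augment_patch(p, _SeqRng([0.1, 0.9, 0.9]))  # rotate only
        b = out.annotations[0]
        assert (b.min_x, b.min_y, b.max_x, b.max_y) == (376, 10, 396, 30)
        # the pixel block inside the box moved with the box
        src = p.pixels[20:40, 10:30]
        dst = out.pixels[10:30, 376:396]
        assert np.array_equal(np.rot90(src, k=-1), dst)

    def test_preserves_count_and_areas(self, rng):
        boxes = [Box(float(x), float(y), float(x + w), float(y + h))
                 for x, y, w, h in rng.integers(1, 100, size=(20, 4))]
        p = self.patch(boxes)
        for seed in range(8):
            out = augment_patch(p, np.random.default_rng(seed))
            assert len(out.annotations) == len(boxes)
            assert sorted(round(b.area, 6) for b in out.annotations) == \
                   sorted(round(b.area, 6) for b in boxes)

    def test_rejects_non_square(self):
        p = PatchRecord("img", (0, 0), np.zeros((10, 20, 3), np.uint8))
        with pytest.raises(ValueError):
            augment_patch(p, np.random.default_rng(0))


class TestMerge:
    def test_single_patch_keeps_everything(self):
        grid = plan_grid(416, 416, 416, 0.0)
        preds = [Box(10, 10, 50, 50, 0.9), Box(100, 100, 130, 140, 0.6)]
        out = merge_patch_predictions([preds], grid)
        assert sorted((b.min_x for b in out)) == [10, 100]

    def test_ownership_midline(self):
        # patches at x-origins 0 and 208 -> centers x=208, 416; midline x=312
        grid = plan_grid(624, 416, 416, 0.5)
        assert [o[0] for o in grid.origins] == [0, 208]
        box_a = Box(280, 100, 320, 140, 0.8)            # center x=300 < 312
        box_b = box_a.translate(-208, 0)                # same object, patch B
        out = merge_patch_predictions([[box_a], [box_b]], grid)
        assert len(out) == 1
        assert out[0].min_x == 280  # patch A's copy survived

    def test_nms_removes_cross_midline_duplicates(self):
        grid = plan_grid(624, 416, 416, 0.5)
        a = Box(271, 100, 351, 180, 0.9)        # center x=311, owned by patch 0
        b_local = Box(65, 102, 145, 182, 0.7)   # image x 273..353, center 313
        out = merge_patch_predictions([[a], [b_local]], grid)  # IoU ~0.91
        assert len(out) == 1 and out[0].confidence == 0.9

    def test_rejects_out_of_patch_prediction(self):
        grid = plan_grid(624, 416, 416, 0.5)
        with pytest.raises(ValueError):
            merge_patch_predictions([[Box(400, 0, 430, 20, 0.5)], []], grid)

    def test_ownership_cells_partition_image(self, rng):
        grid = plan_grid(1000, 840, 416, 0.5)
        centers = grid.centers()
        for _ in range(500):
            x, y = rng.uniform(0, 1000), rng.uniform(0, 840)
            d2 = (centers[:, 0] - x) ** 2 + (centers[:, 1] - y) ** 2
            owners = np.flatnonzero(d2 == d2.min())
            assert owners.size >= 1  # argmin picks owners[0]: unique owner

    def test_perfect_detector_round_trip(self, rng):
        """Ground-truth patch predictions merge back to image ground truth:
        pipeline accuracy is exactly 1.0."""
        boxes = []
        for gy in range(5):
            for gx in range(5):
                x0 = 60 + gx * 150 + float(rng.integers(-20, 20))
                y0 = 60 + gy * 150 + float(rng.integers(-20, 20))
                boxes.append(Box(x0, y0, x0 + 36, y0 + 28))
        img = make_image(832, 832, boxes)
        grid = plan_grid(832, 832, 416, 0.5)
        recs = extract_patches(img, grid, keep_fraction=0.5)
        patch_preds = [[b.with_confidence(1.0) for b in r.annotations]
                       for r in recs]
        merged = merge_patch_predictions(patch_preds, grid, nms_iou=0.4)
        m = match_detections(merged, boxes, EvalThresholds())
        assert image_accuracy(m) == 1.0
        for (pi, aj) in m.pairs:
            assert iou(merged[pi], boxes[aj]) >= 0.9
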
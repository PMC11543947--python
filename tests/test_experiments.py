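from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from seedbench.detector import MockDetector
from seedbench.experiments import (ExperimentSpec, evaluate_sets,
                                   mixed_to_test_split, relevance_analysis,
                                   run_size_series, sample_training_set,
                                   split_summary, summarize,
                                   training_patch_pool)
from seedbench.geometry import Box
from seedbench.patching import PatchRecord
from seedbench.synth import (BenchmarkLayout, DomainParams, ImageRecord,
                             ImageSet, generate_image_set)


def tiny_pool(n):
    pixels = np.zeros((416, 416, 3), dtype=np.uint8)
    return [PatchRecord(f"img{i}", (0, 0), pixels,
                        (Box(5, 5, 25, 25),)) for i in range(n)]


class TestSampleTrainingSet:
    def test_full_pool_is_permutation(self, rng):
        pool = tiny_pool(10)
        out = sample_training_set(pool, 10, rng)
        assert sorted(p.image_id for p in out) == \
               sorted(p.image_id for p in pool)

    def test_empty_and_oversized(self, rng):
        pool = tiny_pool(4)
        assert sample_training_set(pool, 0, rng) == []
        with pytest.raises(ValueError):
            sample_training_set(pool, 5, rng)

    def test_without_replacement(self, rng):
        pool = tiny_pool(50)
        out = sample_training_set(pool, 30, rng)
        ids = [p.image_id for p in out]
        assert len(ids) == len(set(ids))

    def test_deterministic_given_seed(self):
        pool = tiny_pool(20)
        a = sample_training_set(pool, 7, np.random.default_rng(5))
        b = sample_training_set(pool, 7, np.random.default_rng(5))
        assert [p.image_id for p in a] == [p.image_id for p in b]


class TestSummarize:
    def test_closed_forms(self):
        mean, se = summarize([1.0, 2.0, 3.0])
        assert mean == 2.0
        assert se == pytest.approx(1.0 / np.sqrt(3))
        assert summarize([5.0]) == (5.0, 0.0)
        assert summarize([2.0, 2.0, 2.0])[1] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


class TestRelevanceAnalysis:
    def test_exhaustive_case_equals_full_difference(self):
        div = [0.8, 0.7, 0.9]
        nd = np.array([[0.6, 0.9, 0.5], [0.7, 0.6, 0.7]])
        out = relevance_analysis(div, nd, [3], n_resamples=50,
                                 rng=np.random.default_rng(0))
        best_full = max(nd.mean(axis=1))
        assert out["mean_diff"].iloc[0] == pytest.approx(
            np.mean(div) - best_full)

    def test_matches_exhaustive_enumeration(self):
        """Resampled means agree with exact enumeration over all C(K, n)
        subsets within Monte-Carlo error."""
        rng = np.random.default_rng(42)
        k, m = 5, 4
        div = rng.uniform(0.5, 0.9, size=k)
        nd = rng.uniform(0.3, 0.9, size=(m, k))
        for n in (1, 2, 3):
            exact_diffs = []
            for idx in combinations(range(k), n):
                idx = list(idx)
                exact_diffs.append(div[idx].mean()
                                   - nd[:, idx].mean(axis=1).max())
            exact_diffs = np.array(exact_diffs)
            out = relevance_analysis(div, nd, [n], n_resamples=4000,
                                     rng=np.random.default_rng(n))
            se = exact_diffs.std(ddof=1) / np.sqrt(4000)
            assert abs(out["mean_diff"].iloc[0] - exact_diffs.mean()) < 3 * se

    def test_specialist_wins_small_n_loses_large_n(self):
        """A non-diverse specialist that excels on one domain can beat the
        diverse model at n=1 yet lose over the full suite (the crossover
        shape of the diversity-relevance trade-off)."""
        div = [0.75] * 8
        specialist = [0.95] + [0.40] * 7
        generalists = np.vstack([specialist,
                                 [0.55] * 8])
        out = relevance_analysis(div, generalists, [1, 8], n_resamples=2000,
                                 rng=np.random.default_rng(0))
        d1 = out.set_index("n")["mean_diff"]
        assert d1.loc[8] > 0          # diverse wins on the full suite
        assert d1.loc[1] < d1.loc[8]  # and its edge shrinks (negative) at n=1

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            relevance_analysis([0.5], np.array([[0.5]]), [2])


def mini_sets(prefix, n_sets, n_images, seed0=0):
    out = []
    for i in range(n_sets):
        params = DomainParams(seed=seed0 + i, plant_rate=3.0, weed_rate=0.0,
                              stubble_rate=0.0, noise_sd=0.0, blur_sigma=0.0)
        out.append(generate_image_set(params, n_images, (416, 416),
                                      f"{prefix}{i}", prefix))
    return out


class TestMixedToTest:
    def test_counts_preserved_and_bookkeeping(self, rng):
        train = mini_sets("train", 2, 2)
        ood = mini_sets("ood", 2, 2, seed0=50)
        new_train, new_ood = mixed_to_test_split(train, ood, rng)
        assert sum(len(s.images) for s in new_train) == 4  # size preserved
        assert sum(len(s.images) for s in new_ood) == 2   # one removed each
        moved = {img.image_id for s in new_train for img in s.images
                 if img.image_id.startswith("ood")}
        assert len(moved) == 2
        remaining = {img.image_id for s in new_ood for img in s.images}
        assert moved.isdisjoint(remaining)

    def test_small_sets_rejected(self, rng):
        train = mini_sets("train", 1, 1)
        ood = mini_sets("ood", 1, 2, seed0=9)
        with pytest.raises(ValueError):
            mixed_to_test_split(train, ood, rng)

    def test_originals_not_mutated(self, rng):
        train = mini_sets("train", 2, 2)
        ood = mini_sets("ood", 2, 2, seed0=50)
        before = [len(s.images) for s in train + ood]
        mixed_to_test_split(train, ood, rng)
        assert [len(s.images) for s in train + ood] == before


@pytest.fixture(scope="module")
def mock_benchmark():
    """Tiny benchmark evaluated with a MockDetector: exercises the drivers
    without the cost of real fits."""
    return BenchmarkLayout(mini_sets("train", 2, 2),
                           mini_sets("id", 2, 1, seed0=20),
                           mini_sets("ood", 2, 1, seed0=40))


class TestDrivers:
    def spec(self, **kw):
        kw.setdefault("sizes", (2, 4))
        kw.setdefault("replications", 2)
        kw.setdefault("master_seed", 3)
        return ExperimentSpec(**kw)

    def test_size_series_table_shape(self, mock_benchmark):
        rt = run_size_series(self.spec(), mock_benchmark, MockDetector())
        # sizes x reps x splits x sets rows, accuracy metric only
        assert len(rt) == 2 * 2 * 2 * 2
        assert set(rt["split"]) == {"id_test", "ood_test"}
        assert ((rt["value"] >= 0) & (rt["value"] <= 1)).all()
        assert {(c, r) for c, r in zip(rt.condition, rt.replication)} == \
               {(s, r) for s in (2, 4) for r in (0, 1)}

    def test_size_series_byte_identical_reruns(self, mock_benchmark):
        a = run_size_series(self.spec(), mock_benchmark, MockDetector())
        b = run_size_series(self.spec(), mock_benchmark, MockDetector())
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_oversized_request_fails_fast(self, mock_benchmark):
        spec = self.spec(sizes=(10_000,))
        with pytest.raises(ValueError, match="exceeds pool"):
            run_size_series(spec, mock_benchmark, MockDetector())

    def test_split_summary_reduces_correctly(self):
        rt = pd.DataFrame(
            [("e", "c", 0, "ood_test", "s1", "accuracy", 0.6),
             ("e", "c", 0, "ood_test", "s2", "accuracy", 0.8),
             ("e", "c", 1, "ood_test", "s1", "accuracy", 0.4),
             ("e", "c", 1, "ood_test", "s2", "accuracy", 0.6)],
            columns=["experiment", "condition", "replication", "split",
                     "set_id", "metric", "value"])
        out = split_summary(rt)
        assert out["mean"].iloc[0] == pytest.approx(0.6)  # mean of 0.7, 0.5
        assert out["se"].iloc[0] == pytest.approx(0.1)
        assert out["n"].iloc[0] == 2


class TestEvaluateSets:
    def test_ground_truth_patch_predictions_score_one(self):
        """Feeding each patch's ground truth through the tiled merge yields
        image accuracy 1.0 on rendered field images."""
        from seedbench.geometry import image_accuracy, match_detections
        from seedbench.patching import (extract_patches,
                                        merge_patch_predictions, plan_grid)

        img = mini_sets("val", 1, 2)[0].images[0]
        h, w = img.pixels.shape[:2]
        grid = plan_grid(w, h, 416, 0.5)
        recs = extract_patches(img, grid, 0.5)
        preds = [[b.with_confidence(1.0) for b in r.annotations] for r in recs]
        merged = merge_patch_predictions(preds, grid)
        assert image_accuracy(match_detections(
            merged, list(img.annotations))) == 1.0

    def test_counts_reflect_confidence_filter(self):
        sets = mini_sets("val", 1, 1)
        n_annos = len(sets[0].images[0].annotations)
        det = MockDetector(boxes=(Box(1, 1, 30, 30, 0.45),))  # below 0.5
        per = evaluate_sets(det, sets)
        assert per["n_pred"].iloc[0] == 0
        assert per["n_anno"].iloc[0] == n_annos
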
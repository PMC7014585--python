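"""Balanced forest, geographic split, repeated validation, agreement metrics."""

import numpy as np
import pandas as pd
import pytest

from vegspec.classify import (
    ConfusionMatrix,
    ForestConfig,
    SpectraError,
    _capped_bootstrap,
    accuracy,
    balanced_forest_fit,
    evaluate,
    geographic_split,
    kappa,
    oob_accuracy,
    per_class_oob_error,
)
from vegspec.spectra import SpectralDataset, WavelengthGrid


def gaussian_clouds(sizes, shift=3.0, p=10, seed=0):
    """Well-separated Gaussian covariate clouds, one per class."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for k, n in enumerate(sizes):
        mean = np.zeros(p)
        mean[k % p] = shift * k if k else 0.0
        mean[:3] += shift * k
        X.append(rng.standard_normal((n, p)) + mean)
        y.extend([f"c{k}"] * n)
    return np.vstack(X), np.array(y)


class TestMetrics:
    def _cm(self, counts):
        counts = np.asarray(counts)
        return ConfusionMatrix(tuple(f"c{i}" for i in range(counts.shape[0])),
                               counts)

    def test_accuracy_hand_value(self):
        assert accuracy(self._cm([[40, 10], [10, 40]])) == pytest.approx(0.8)

    def test_accuracy_limits(self):
        assert accuracy(self._cm([[7, 0], [0, 3]])) == 1.0
        assert accuracy(self._cm([[0, 7], [3, 0]])) == 0.0

    def test_kappa_hand_value(self):
        # (100*80 - 5000) / (10000 - 5000) = 0.6
        assert kappa(self._cm([[40, 10], [10, 40]])) == pytest.approx(0.6)

    def test_kappa_perfect_diagonal(self):
        assert kappa(self._cm([[12, 0, 0], [0, 5, 0], [0, 0, 9]])) == 1.0

    def test_kappa_chance_matrix_is_zero(self):
        # x_ij = x_i+ * x_+j / N has vanishing numerator
        row = np.array([60.0, 40.0])
        col = np.array([30.0, 70.0])
        counts = np.round(np.outer(row, col) / 100.0).astype(int)
        assert kappa(self._cm(counts)) == pytest.approx(0.0, abs=1e-12)

    def test_kappa_undefined_on_saturated_chance(self):
        assert np.isnan(kappa(self._cm([[5]])))

    def test_kappa_one_iff_diagonal(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            counts = rng.integers(0, 30, (3, 3))
            counts[np.diag_indices(3)] += 1
            k = kappa(self._cm(counts))
            if np.isnan(k):
                continue
            is_diag = counts.sum() == np.trace(counts)
            assert (k == pytest.approx(1.0)) == is_diag

    def test_kappa_near_zero_under_label_permutation(self):
        rng = np.random.default_rng(1)
        ref = np.repeat(["a", "b", "c", "d"], 100)
        vals = []
        for _ in range(60):
            pred = rng.permutation(ref)
            vals.append(kappa(ConfusionMatrix.from_labels(ref, pred)))
        assert abs(np.mean(vals)) < 0.05

    def test_matrix_must_be_square_nonnegative(self):
        with pytest.raises(SpectraError):
            ConfusionMatrix(("a",), np.array([[1, 2]]))
        with pytest.raises(SpectraError):
            ConfusionMatrix(("a", "b"), np.array([[1, -2], [0, 1]]))


class TestBalancedForest:
    def test_capped_bootstrap_caps_large_categories(self):
        y = np.array([0] * 50 + [1] * 3)
        rng = np.random.default_rng(0)
        draw = _capped_bootstrap(y, cap=10, rng=rng)
        counts = np.bincount(y[draw])
        assert counts[0] == 10 and counts[1] == 3

    def test_no_cap_keeps_category_sizes(self):
        y = np.array([0] * 20 + [1] * 5)
        draw = _capped_bootstrap(y, cap=None, rng=np.random.default_rng(0))
        counts = np.bincount(y[draw])
        assert counts[0] == 20 and counts[1] == 5

    def test_separable_clouds_high_oob_accuracy(self):
        X, y = gaussian_clouds([150, 150], shift=4.0, seed=1)
        model = balanced_forest_fit(X, y, ForestConfig(ntree=200, seed=0))
        assert oob_accuracy(model) > 0.95

    def test_shuffled_labels_give_chance_oob(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((400, 8))
        y = np.repeat(["a", "b", "c", "d"], 100)
        accs = [oob_accuracy(balanced_forest_fit(
            X, rng.permutation(y), ForestConfig(ntree=100, seed=s)))
            for s in range(3)]
        assert abs(np.mean(accs) - 0.25) < 0.1

    def test_perfectly_confusable_classes_near_half(self):
        # covariates carry no class information at all: OOB accuracy can do
        # no better than the balanced-class base rate
        X = np.zeros((200, 4))
        y = np.array(["a"] * 100 + ["b"] * 100)
        model = balanced_forest_fit(X, y, ForestConfig(ntree=100, seed=0))
        assert oob_accuracy(model) == pytest.approx(0.5, abs=0.1)

    def test_single_category_rejected(self):
        X = np.zeros((10, 3))
        with pytest.raises(SpectraError):
            balanced_forest_fit(X, ["a"] * 10, ForestConfig(ntree=5))

    def test_downsampling_balances_per_class_errors(self):
        # imbalanced but equally separable classes: capping the majority
        # narrows the gap between per-class OOB error rates
        wins = 0
        seeds = range(5)
        for seed in seeds:
            X, y = gaussian_clouds([400, 40], shift=1.2, seed=seed)
            gap = {}
            for cap in (None, 40):
                model = balanced_forest_fit(
                    X, y, ForestConfig(ntree=150, downsample_target=cap,
                                       seed=seed))
                err = per_class_oob_error(model)
                gap[cap] = abs(err["c0"] - err["c1"])
            wins += gap[40] < gap[None]
        assert wins > len(seeds) / 2

    def test_seed_determinism(self):
        X, y = gaussian_clouds([50, 50], seed=4)
        m1 = balanced_forest_fit(X, y, ForestConfig(ntree=30, seed=9))
        m2 = balanced_forest_fit(X, y, ForestConfig(ntree=30, seed=9))
        np.testing.assert_array_equal(m1.oob_votes, m2.oob_votes)
        np.testing.assert_array_equal(m1.predict(X), m2.predict(X))


def _geo_dataset(patch_x, patch_y=None, types=None, px_per_patch=3):
    n_patches = len(patch_x)
    patch_y = patch_y if patch_y is not None else [0.0] * n_patches
    types = types if types is not None else ["t1"] * n_patches
    rows = []
    for p in range(n_patches):
        for i in range(px_per_patch):
            rows.append({
                "sample_id": f"p{p}_s{i}",
                "patch_id": f"p{p}",
                "type_id": types[p],
                "x": patch_x[p] + 0.1 * i,
                "y": patch_y[p],
                "label_default": types[p],
            })
    meta = pd.DataFrame(rows)
    grid = WavelengthGrid(np.array([400.0, 500.0]))
    return SpectralDataset(grid, np.full((len(meta), 2), 0.2), meta)


class TestGeographicSplit:
    def test_obvious_two_cluster_layout(self):
        ds = _geo_dataset([0.0, 10.0, 1000.0, 1010.0])
        plan = geographic_split(ds)
        assert plan.train_patches["t1"] == {"p0", "p1"}
        assert plan.val_patches["t1"] == {"p2", "p3"}

    def test_collinear_six_patches_split_three_three(self):
        ds = _geo_dataset([0.0, 10.0, 20.0, 30.0, 40.0, 50.0])
        plan = geographic_split(ds)
        assert len(plan.train_patches["t1"]) == 3
        assert len(plan.val_patches["t1"]) == 3
        # contiguous: training is the western block
        assert plan.train_patches["t1"] == {"p0", "p1", "p2"}

    def test_halves_disjoint_and_separable_over_random_layouts(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            xs = rng.uniform(0, 1000, 8)
            ys = rng.uniform(0, 1000, 8)
            ds = _geo_dataset(list(xs), list(ys))
            plan = geographic_split(ds)
            train = plan.train_patches["t1"]
            val = plan.val_patches["t1"]
            assert not train & val
            assert train | val == {f"p{i}" for i in range(8)}
            # projections onto the principal axis separate linearly
            from vegspec.classify import _principal_axis
            pts = np.column_stack([xs, ys])
            proj = pts @ _principal_axis(pts)
            tr = [proj[int(p[1:])] for p in train]
            va = [proj[int(p[1:])] for p in val]
            assert max(tr) <= min(va) or max(va) <= min(tr)

    def test_single_patch_type_split_by_pixels(self):
        ds = _geo_dataset([5.0], px_per_patch=8)
        plan = geographic_split(ds)
        assign = plan.assignment
        assert (assign == "train").sum() >= 2
        assert (assign == "val").sum() >= 2

    def test_tiny_type_excluded(self):
        ds = _geo_dataset([0.0, 100.0, 50.0], types=["a", "a", "b"],
                          px_per_patch=1)
        # type b has a single sample -> excluded
        plan = geographic_split(_geo_dataset([0.0, 100.0], types=["a", "a"]))
        assert "b" not in plan.train_patches
        plan2 = geographic_split(ds)
        assert "b" in plan2.excluded_types


class TestEvaluate:
    def _perfect_setup(self):
        X, y = gaussian_clouds([120, 120], shift=8.0, seed=5)
        model = balanced_forest_fit(X[:160], y[:160],
                                    ForestConfig(ntree=100, seed=0))
        return model, pd.DataFrame(X, columns=model.feature_names), y

    def test_perfect_classifier_scores_one(self):
        model, df, y = self._perfect_setup()
        res = evaluate(model, df, y, downsample_target=50, repeats=5, seed=0)
        assert res.accuracies == [1.0] * 5
        assert res.kappas == pytest.approx([1.0] * 5)

    def test_same_seed_identical_repeats(self):
        model, df, y = self._perfect_setup()
        r1 = evaluate(model, df, y, downsample_target=30, repeats=3, seed=11)
        r2 = evaluate(model, df, y, downsample_target=30, repeats=3, seed=11)
        for (a1, k1, c1), (a2, k2, c2) in zip(r1.repeats, r2.repeats):
            assert a1 == a2 and (k1 == k2 or (np.isnan(k1) and np.isnan(k2)))
            np.testing.assert_array_equal(c1.counts, c2.counts)

    def test_per_category_caps_respected(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((550, 4))
        y = np.array(["A"] * 500 + ["B"] * 50)
        model = balanced_forest_fit(X, y, ForestConfig(ntree=20, seed=0))
        res = evaluate(model, pd.DataFrame(X, columns=model.feature_names), y,
                       downsample_target=100, repeats=5, seed=0)
        for _, _, cm in res.repeats:
            sums = dict(zip(cm.categories, cm.counts.sum(axis=1)))
            assert sums["A"] == 100 and sums["B"] == 50

    def test_exactly_requested_repeat_count(self):
        model, df, y = self._perfect_setup()
        res = evaluate(model, df, y, downsample_target=20, repeats=5, seed=3)
        assert len(res.repeats) == 5
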
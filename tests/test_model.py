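import numpy as np
import pytest

import lianasep as ls
from lianasep import (
    FoldGeometry,
    LianaForestModel,
    PointCloud,
    RFParams,
    TrainedClassifier,
    ValidationError,
    grid_search,
    make_spatial_folds,
    predict,
    train,
    undersample_majority,
)


class TestUndersampleMajority:
    def test_ten_percent_of_majority_kept(self):
        labels = np.array([1] * 10 + [2] * 100)
        kept = undersample_majority(labels, 0.10, seed=1)
        assert np.sum(labels[kept] == 1) == 10
        assert np.sum(labels[kept] == 2) == 10

    def test_fraction_one_is_identity(self):
        labels = np.array([1, 2, 2, 1, 2])
        assert np.array_equal(undersample_majority(labels, 1.0, 0), np.arange(5))

    def test_deterministic_given_seed(self):
        labels = np.array([1] * 5 + [2] * 200)
        a = undersample_majority(labels, 0.3, seed=9)
        b = undersample_majority(labels, 0.3, seed=9)
        assert np.array_equal(a, b)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            undersample_majority(np.full(10, 2), 0.1, 0)

    def test_minority_never_dropped_and_retention_matches(self, rng):
        labels = rng.choice([1, 2], size=500, p=[0.05, 0.95])
        n_major = int(np.sum(labels == 2))
        fracs = []
        for seed in range(30):
            kept = undersample_majority(labels, 0.2, seed)
            assert np.sum(labels[kept] == 1) == np.sum(labels == 1)
            fracs.append(np.sum(labels[kept] == 2) / n_major)
        assert np.allclose(fracs, 0.2, atol=0.01)


def square_plot(n_side, extent=15.0, seed=0, source="plot"):
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, extent, size=(n_side, 3))
    coords[:, 2] = rng.uniform(0, 5, size=n_side)
    labels = rng.choice([1, 2], size=n_side, p=[0.1, 0.9])
    return PointCloud(coords, labels=labels, source_id=source)


class TestSpatialFolds:
    def test_two_square_plots_quadrant_split_gives_eight_folds(self):
        clouds = [square_plot(400, seed=i) for i in range(2)]
        plan = make_spatial_folds(clouds, "self_site", FoldGeometry(split=(2, 2)))
        assert len(plan) == 8
        total = sum(len(c) for c in clouds)
        validated = np.concatenate([v for _, v in plan.folds])
        # every point validated exactly once, train/val always disjoint
        assert np.array_equal(np.sort(validated), np.arange(total))
        for tr, va in plan.folds:
            assert np.intersect1d(tr, va).size == 0
            assert len(tr) + len(va) == total

    def test_leave_one_plot_out(self):
        clouds = [square_plot(100, seed=i) for i in range(6)]
        plan = make_spatial_folds(clouds, "self_site")
        assert len(plan) == 6
        for i, (tr, va) in enumerate(plan.folds):
            assert len(va) == 100
            assert np.intersect1d(tr, va).size == 0

    def test_cross_site_two_folds(self):
        clouds = [square_plot(100, seed=i) for i in range(4)]
        geometry = FoldGeometry(sites=["A", "A", "B", "B"])
        plan = make_spatial_folds(clouds, "cross_site", geometry)
        assert len(plan) == 2
        (tr0, va0), (tr1, va1) = plan.folds
        assert np.array_equal(np.sort(np.concatenate([tr0, va0])), np.arange(400))
        assert np.array_equal(tr0, va1) and np.array_equal(va0, tr1)

    def test_mixed_site_pairs_subareas_with_whole_plots(self):
        a_plots = [square_plot(600, seed=i, source=f"A{i}") for i in range(2)]
        b_plots = [square_plot(80, seed=10 + i, source=f"B{i}") for i in range(6)]
        geometry = FoldGeometry(split=(2, 3), sites=["A"] * 2 + ["B"] * 6, split_site="A")
        plan = make_spatial_folds(a_plots + b_plots, "mixed_site", geometry)
        assert len(plan) == 6
        validated = np.concatenate([v for _, v in plan.folds])
        assert np.array_equal(np.sort(validated), np.arange(600 * 2 + 80 * 6))

    def test_plot_too_small_reports_minimum_extent(self):
        tiny = PointCloud(np.random.default_rng(0).uniform(0, 0.5, size=(50, 3)))
        with pytest.raises(ValidationError, match="minimum extent"):
            make_spatial_folds([tiny], "self_site", FoldGeometry(split=(2, 2)))

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValidationError, match="scheme"):
            make_spatial_folds([square_plot(10)], "random_kfold")


class TestTrainPredict:
    def test_in_sample_f1_on_separable_problem(self, separable_features):
        X, y, scales = separable_features
        model = train(X, y, RFParams(seed=0), scales)
        pred, probs = predict(model, X)
        report = ls.evaluate_predictions(pred, y, probs)
        assert report.f1 >= 0.95

    def test_same_seed_identical_predictions(self, separable_features):
        X, y, scales = separable_features
        preds = [predict(train(X, y, RFParams(seed=3), scales), X)[0] for _ in range(2)]
        assert np.array_equal(preds[0], preds[1])

    def test_single_class_training_rejected(self, separable_features):
        X, y, scales = separable_features
        with pytest.raises(ValidationError):
            train(X, np.full_like(y, 2), RFParams(), scales)

    def test_threshold_monotonicity_and_extremes(self, separable_features):
        X, y, scales = separable_features
        model = train(X, y, RFParams(seed=0), scales)
        counts = []
        for thr in (0.001, 0.25, 0.5, 0.75, 0.999):
            labels, probs = predict(model, X, thr)
            counts.append(int(np.sum(labels == 1)))
            assert np.array_equal(labels == 1, probs >= thr)
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_schema_mismatch_names_expected_scales(self, separable_features):
        X, y, scales = separable_features
        model = train(X, y, RFParams(), scales)
        with pytest.raises(ValidationError, match="0.25"):
            predict(model, X[:, :6])

    def test_ensemble_not_worse_than_single_tree_out_of_fold(self, rng):
        # noisy, overlapping feature distributions; the 50-tree forest's
        # held-out F1 never falls materially below a single tree's
        n = 600
        lin = np.tile([0.8, 0.15, 0.05], (n // 2, 5))
        iso = np.tile([0.6, 0.25, 0.15], (n // 2, 5))
        X = np.vstack([lin, iso]) + rng.normal(0, 0.12, size=(n, 15))
        y = np.array([1] * (n // 2) + [2] * (n // 2))
        perm = rng.permutation(n)
        X, y = X[perm], y[perm]
        half = n // 2
        for seed in range(5):
            f1 = {}
            for n_trees in (1, 50):
                model = train(X[:half], y[:half], RFParams(n_trees=n_trees, seed=seed))
                pred, _ = predict(model, X[half:])
                f1[n_trees] = ls.evaluate_predictions(pred, y[half:]).f1
            assert f1[50] >= f1[1] - 0.02

    def test_persistence_round_trip(self, separable_features, tmp_path):
        X, y, scales = separable_features
        model = train(X, y, RFParams(seed=5), scales)
        model.save(tmp_path / "model.joblib")
        loaded = TrainedClassifier.load(tmp_path / "model.joblib")
        assert loaded.params == model.params
        assert loaded.feature_schema == scales
        assert np.array_equal(predict(loaded, X)[0], predict(model, X)[0])


class TestGridSearch:
    def _folds(self, n):
        idx = np.arange(n)
        half = n // 2
        return ls.SpatialFoldPlan(
            scheme="self_site",
            folds=[(idx[:half], idx[half:]), (idx[half:], idx[:half])],
            offsets=np.array([0]),
            geometry="two halves",
        )

    def test_single_cell_grid_returns_that_cell(self, separable_features):
        X, y, scales = separable_features
        best, table = grid_search(X, y, self._folds(len(y)), [20], [3], scales=scales)
        assert best.n_trees == 20 and best.n_features_per_split == 3
        assert table.shape == (1, 1)

    def test_table_shape_matches_grids(self, separable_features):
        X, y, scales = separable_features
        _, table = grid_search(
            X, y, self._folds(len(y)), [10, 50], [2, 8], scales=scales
        )
        assert table.shape == (2, 2)
        assert table.notna().to_numpy().all()

    def test_ties_break_toward_fewer_trees_then_features(self, separable_features):
        # perfectly separable: every cell scores 1.0, so the smallest wins
        X, y, scales = separable_features
        best, table = grid_search(
            X, y, self._folds(len(y)), [50, 10], [8, 2], scales=scales
        )
        assert float(table.to_numpy().min()) == float(table.to_numpy().max())
        assert best.n_trees == 10 and best.n_features_per_split == 2

    def test_empty_grid_rejected(self, separable_features):
        X, y, scales = separable_features
        with pytest.raises(ValidationError):
            grid_search(X, y, self._folds(len(y)), [], [2], scales=scales)

    def test_reduced_grid_scores_are_stable_on_pooled_plots(self, five_scene_cv):
        """With several plots pooled, hyperparameters barely move the
        spatially cross-validated F1 (the score surface is nearly flat)."""
        m = five_scene_cv["model"]
        _, table = grid_search(
            m.features, m.labels, five_scene_cv["plan"], [10, 50], [2, 8]
        )
        vals = table.to_numpy()
        assert table.shape == (2, 2)
        assert vals.max() - vals.min() <= 0.05


class TestModelResultsFrontEnd:
    def test_fit_summary_and_importances(self, separable_features):
        X, y, scales = separable_features
        results = LianaForestModel(
            X, y, scales=scales, params=RFParams(seed=0), undersample_fraction=1.0
        ).fit()
        text = results.summary()
        assert "random forest" in text.lower()
        assert "precision" in text
        imp = results.feature_importances
        assert len(imp) == scales.n_features
        assert imp["importance"].sum() == pytest.approx(1.0, abs=1e-6)

    def test_from_clouds_requires_labels(self):
        cloud = PointCloud(np.random.default_rng(0).uniform(0, 1, (50, 3)))
        with pytest.raises(ValidationError, match="labels"):
            LianaForestModel.from_clouds([cloud], voxel_size=None)
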
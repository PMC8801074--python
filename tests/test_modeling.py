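"""Leave-lot-out CV machinery, learners, metrics and LASSO reporting."""

import numpy as np
import pandas as pd
import pytest
from sklearn.neighbors import KNeighborsClassifier

from mscmorph.benchmark import regression_benchmark
from mscmorph.modeling import (
    DesignMatrix,
    GrowthRegressor,
    PotencyClassifier,
    _knn_predict,
    build_design_matrix,
    cross_validate_lots,
    lasso_report,
    leave_lot_out_splits,
    score_classification,
    standardize,
    sweep,
)


def _toy_dm(n_lots=4, rows_per_lot=3, p=6, seed=0):
    rng = np.random.default_rng(seed)
    n = n_lots * rows_per_lot
    X = pd.DataFrame(rng.normal(size=(n, p)))
    lots = np.repeat([f"lot{i}" for i in range(n_lots)], rows_per_lot)
    y = np.repeat(np.arange(n_lots) % 2, rows_per_lot)
    return DesignMatrix(X=X, y=y, lots=lots)


class TestSplits:
    def test_one_fold_per_lot_no_straddling(self):
        dm = _toy_dm(n_lots=5)
        splits = leave_lot_out_splits(dm)
        assert len(splits) == 5
        for train, test in splits:
            assert set(dm.lots[train]) & set(dm.lots[test]) == set()
            assert len(set(dm.lots[test])) == 1
            assert len(train) + len(test) == dm.n_samples

    def test_two_lots_complementary(self):
        dm = _toy_dm(n_lots=2)
        (tr1, te1), (tr2, te2) = leave_lot_out_splits(dm)
        assert sorted(te1) == sorted(tr2)
        assert sorted(te2) == sorted(tr1)

    def test_single_lot_rejected(self):
        dm = _toy_dm(n_lots=1)
        with pytest.raises(ValueError):
            leave_lot_out_splits(dm)

    def test_default_panel_fold_sizes(self, panel_seed1):
        dm = build_design_matrix(
            panel_seed1.fov_profiles, panel_seed1.labels, mode="only_SD", window_end=96.0
        )
        assert dm.n_samples == 132  # 11 lots x 3 wells x 4 FOVs
        splits = leave_lot_out_splits(dm)
        assert len(splits) == 11
        assert all(len(test) == 12 for _, test in splits)


class TestStandardize:
    def test_train_transformed_to_zero_mean_unit_sd(self):
        X = np.random.default_rng(0).normal(3, 2, (50, 4))
        Xt, _ = standardize(X, X)
        np.testing.assert_allclose(Xt.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(Xt.std(axis=0), 1, atol=1e-12)

    def test_constant_feature_passes_through_centered(self):
        X = np.ones((10, 2))
        X[:, 1] = np.arange(10)
        Xt, _ = standardize(X, X)
        np.testing.assert_allclose(Xt[:, 0], 0)

    def test_no_leakage_from_test_rows(self):
        rng = np.random.default_rng(1)
        X_train = rng.normal(0, 1, (40, 3))
        X_test = rng.normal(5, 1, (10, 3))  # strongly shifted
        _, Xt_test = standardize(X_train, X_test)
        pooled = np.vstack([X_train, X_test])
        Xp = (pooled - pooled.mean(0)) / pooled.std(0)
        # train-only statistics leave the shift visible; pooled stats hide it
        assert abs(Xt_test.mean()) > abs(Xp[40:].mean()) + 1

    def test_train_statistics_applied_to_test(self):
        X_train = np.array([[0.0], [2.0]])
        X_test = np.array([[4.0]])
        _, Xt = standardize(X_train, X_test)
        assert Xt[0, 0] == pytest.approx(3.0)  # (4 - 1) / 1


class TestKNN:
    def test_duplicate_training_point_k1(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        y = (np.arange(20) % 2).astype(int)
        pred = _knn_predict(X, y, X[7:8], k=1)
        assert pred[0] == y[7]

    def test_agrees_with_exhaustive_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 4))
        y = rng.integers(0, 2, 50)
        T = rng.normal(size=(20, 4))
        pred = _knn_predict(X, y, T, k=5)
        for i, t in enumerate(T):
            d = np.sqrt(((X - t) ** 2).sum(axis=1))
            nearest = np.argsort(d, kind="stable")[:5]
            votes = np.bincount(y[nearest], minlength=2)
            assert pred[i] == votes.argmax()

    def test_agrees_with_sklearn_on_continuous_data(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 5))
        y = rng.integers(0, 2, 60)
        T = rng.normal(size=(25, 5))
        ours = _knn_predict(X, y, T, k=5)
        ref = KNeighborsClassifier(n_neighbors=5).fit(X, y).predict(T)
        np.testing.assert_array_equal(ours, ref)


class TestLearners:
    def test_lasso_classifier_separates_linear_classes(self):
        rng = np.random.default_rng(4)
        n = 60
        X = rng.normal(size=(n, 5))
        y = (X[:, 0] > 0).astype(int)
        X[:, 0] += np.where(y == 1, 2.0, -2.0)  # wide margin
        lots = np.repeat([f"l{i}" for i in range(6)], 10)
        est = PotencyClassifier(method="lasso").fit(X, y, groups=lots)
        assert np.mean(est.predict(X) == y) == 1.0
        assert hasattr(est, "coef_")

    def test_single_class_training_fold_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError):
            PotencyClassifier(method="knn").fit(X, np.zeros(10))

    def test_unknown_methods_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError):
            PotencyClassifier(method="svm").fit(X, np.array([0, 1, 0, 1]))
        with pytest.raises(ValueError):
            GrowthRegressor(method="knn").fit(X, np.zeros(4))

    def test_constant_target_predicts_constant(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 4))
        y = np.full(30, 3.7)
        lots = np.repeat([f"l{i}" for i in range(6)], 5)
        est = GrowthRegressor(method="lasso").fit(X, y, groups=lots)
        np.testing.assert_allclose(est.predict(X), 3.7, atol=1e-6)

    def test_exact_linear_target_recovered(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(60, 5))
        y = 2.0 * X[:, 1] + 1.0
        lots = np.repeat([f"l{i}" for i in range(6)], 10)
        est = GrowthRegressor(method="lasso").fit(X, y, groups=lots)
        rmse = np.sqrt(np.mean((est.predict(X) - y) ** 2))
        assert rmse < 0.05

    def test_lasso_sparse_support_recovery(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(400, 5))
        beta = np.array([1.5, 0.0, -2.0, 0.0, 0.0])
        y = X @ beta + rng.normal(0, 0.05, 400)
        lots = np.repeat([f"l{i}" for i in range(8)], 50)
        est = GrowthRegressor(method="lasso").fit(X, y, groups=lots)
        support = np.flatnonzero(np.abs(est.coef_) > 0.05)
        np.testing.assert_array_equal(support, [0, 2])

    def test_rf_estimators_are_seeded(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 4))
        y = rng.integers(0, 2, 40)
        p1 = PotencyClassifier(method="rf", n_trees=50, random_state=3).fit(X, y).predict(X)
        p2 = PotencyClassifier(method="rf", n_trees=50, random_state=3).fit(X, y).predict(X)
        np.testing.assert_array_equal(p1, p2)


class TestMetrics:
    def test_perfect_predictions(self):
        m = score_classification([1, 0, 1, 0], [1, 0, 1, 0])
        assert m["accuracy"] == m["precision"] == m["specificity"] == 1.0

    def test_all_predicted_low_risk_on_7_4_panel(self):
        y_true = np.array([1] * 84 + [0] * 48)
        y_pred = np.ones(132, dtype=int)
        m = score_classification(y_true, y_pred)
        assert m["accuracy"] == pytest.approx(84 / 132)
        assert m["specificity"] == 0.0
        assert m["confusion"] == {"TP": 84, "FP": 48, "TN": 0, "FN": 0}

    def test_confusion_matrix_arithmetic(self):
        y_true = np.array([1] * 84 + [0] * 48)
        y_pred = y_true.copy()
        y_pred[:4] = 0  # 4 FN
        y_pred[84:88] = 1  # 4 FP
        m = score_classification(y_true, y_pred)
        assert m["confusion"] == {"TP": 80, "FP": 4, "TN": 44, "FN": 4}
        assert m["accuracy"] == pytest.approx(124 / 132)

    def test_empty_predictions_rejected(self):
        with pytest.raises(ValueError):
            score_classification([], [])


@pytest.fixture(scope="module")
def tiny_panel():
    from mscmorph.benchmark import simulate_panel
    from mscmorph.synthgen import Schedule

    return simulate_panel(
        3, n_low=2, n_high=2, n_wells=1, n0_cells=400,
        schedule=Schedule(12.0, 36.0, 6.0), min_cells=50,
    )


class TestSweepAndReport:
    def test_factorial_sweep_counts(self, tiny_panel):
        ends = [12.0, 24.0, 36.0]
        reports = sweep(
            tiny_panel.fov_profiles, tiny_panel.labels, "classification",
            methods=["knn", "lasso"], modes=["only_SD", "without_SD"],
            window_ends=ends, seed=0,
        )
        assert len(reports) == 2 * 2 * 3
        assert {(r.method, r.parameter_mode, r.window_end_h) for r in reports} == {
            (m, mo, e) for m in ("knn", "lasso") for mo in ("only_SD", "without_SD")
            for e in ends
        }

    def test_single_timepoint_only_sd_has_16_features(self, tiny_panel):
        dm = build_design_matrix(
            tiny_panel.fov_profiles, tiny_panel.labels, mode="only_SD", window_end=12.0
        )
        assert dm.X.shape[1] == 16

    def test_lasso_selection_counts_and_ordering(self, tiny_panel):
        dm = build_design_matrix(
            tiny_panel.well_profiles, tiny_panel.growth, mode="only_SD", window_end=36.0
        )
        rep = cross_validate_lots(dm, GrowthRegressor(method="lasso"), "regression")
        tab = lasso_report(rep, top=0)
        n_folds = len(rep.fold_lots)
        assert tab["n_selected"].between(0, n_folds).all()
        # sorted by count desc, ties by |mean weight| desc
        for a, b in zip(tab.itertuples(), list(tab.itertuples())[1:]):
            assert (a.n_selected, abs(a.mean_weight)) >= (b.n_selected, abs(b.mean_weight))
        assert len(lasso_report(rep, top=15)) <= 15

    def test_lasso_report_requires_lasso(self, tiny_panel):
        dm = build_design_matrix(
            tiny_panel.fov_profiles, tiny_panel.labels, mode="only_SD", window_end=24.0
        )
        rep = cross_validate_lots(dm, PotencyClassifier(method="knn"), "classification")
        with pytest.raises(ValueError):
            lasso_report(rep)


class TestBenchmarkProperties:
    def test_no_leakage_lotwise_label_permutation(self, panel_seed1):
        """With lot-wise permuted labels the pipeline cannot beat the base
        rate by much; with true labels it is near-perfect (no leakage
        through standardisation or pseudo-sample placement)."""
        dm = build_design_matrix(
            panel_seed1.fov_profiles, panel_seed1.labels, mode="only_SD", window_end=96.0
        )
        real = cross_validate_lots(dm, PotencyClassifier(method="knn"), "classification")
        assert real.metrics["accuracy"] >= 0.95
        rng = np.random.default_rng(0)
        lot_ids = sorted(panel_seed1.labels)
        true_labels = np.array([panel_seed1.labels[l] for l in lot_ids])
        accs = []
        for _ in range(10):
            perm = dict(zip(lot_ids, true_labels[rng.permutation(len(lot_ids))]))
            y_perm = np.array([perm[l] for l in dm.lots])
            dmp = DesignMatrix(X=dm.X, y=y_perm, lots=dm.lots)
            rep = cross_validate_lots(dmp, PotencyClassifier(method="knn"), "classification")
            accs.append(rep.metrics["accuracy"])
        assert np.mean(accs) < 0.80  # indistinguishable from chance-level pooling

    def test_growth_rate_recovery_within_ten_percent_of_range(self, panel_seed1):
        rep = regression_benchmark(panel_seed1, mode="mean+SD", window_end=138.0, seed=1)
        y = rep.y_true
        assert rep.metrics["rmse"] <= 0.10 * (y.max() - y.min())

    def test_longer_window_does_not_hurt_accuracy(self, benchmark_results):
        assert benchmark_results["acc96"].mean() >= benchmark_results["acc24"].mean()
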
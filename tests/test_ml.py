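"""Scaling, SMOTE, the model zoo, evaluation metrics and importances."""

import numpy as np
import pytest

from sigspec.ml import (
    EvalMetrics,
    FeatureTable,
    ModelSpec,
    evaluate,
    f1_from_precision_recall,
    feature_importance,
    train_model,
)
from sigspec.preprocess import SmoteError, minmax_apply, minmax_fit, smote_resample


class TestMinMax:
    def test_train_range_maps_to_unit_interval(self):
        scaler = minmax_fit(np.array([[2.0], [6.0]]))
        np.testing.assert_allclose(
            minmax_apply(scaler, np.array([[2.0], [6.0]])), [[0.0], [1.0]]
        )

    def test_out_of_range_test_values_clipped(self):
        scaler = minmax_fit(np.array([[2.0], [6.0]]))
        out = minmax_apply(scaler, np.array([[8.0], [0.0]]))
        np.testing.assert_allclose(out, [[1.0], [0.0]])

    def test_constant_training_feature_maps_to_zero(self):
        scaler = minmax_fit(np.full((5, 2), 3.0))
        out = minmax_apply(scaler, np.array([[3.0, 3.0], [4.0, 2.0]]))
        assert (out[0] == 0).all()


class TestSmote:
    def test_balanced_input_unchanged(self):
        rng = np.random.default_rng(0)
        X, y = rng.random((10, 3)), np.array([0] * 5 + [1] * 5)
        Xb, yb = smote_resample(X, y, seed=1)
        np.testing.assert_array_equal(Xb, X)
        np.testing.assert_array_equal(yb, y)

    def test_two_minority_points_synthesize_on_segment(self):
        X = np.vstack([np.zeros((8, 2)), [[0.0, 0.0], [1.0, 1.0]]])
        y = np.array([0] * 8 + [1] * 2)
        Xb, yb = smote_resample(X, y, k=1, seed=2)
        synth = Xb[len(y):]
        # every synthetic point lies on the segment between (0,0) and (1,1)
        assert np.allclose(synth[:, 0], synth[:, 1])
        assert ((synth >= 0) & (synth <= 1)).all()

    def test_counts_balanced_and_convex_membership(self):
        rng = np.random.default_rng(3)
        X_min = rng.random((10, 4))
        X_maj = rng.random((100, 4)) + 5
        X = np.vstack([X_min, X_maj])
        y = np.array([1] * 10 + [0] * 100)
        Xb, yb = smote_resample(X, y, k=5, seed=4)
        assert (yb == 1).sum() == 100 and (yb == 0).sum() == 100
        synth = Xb[110:]
        # convex-combination oracle: each synthetic row must be expressible as
        # x_i + u (x_j - x_i) for some minority pair (i, j), u in [0, 1]
        for s in synth:
            ok = False
            for i in range(10):
                d = X_min - X_min[i]
                rel = s - X_min[i]
                for j in range(10):
                    if i == j:
                        continue
                    denom = d[j] @ d[j]
                    if denom == 0:
                        continue
                    u = (rel @ d[j]) / denom
                    if -1e-9 <= u <= 1 + 1e-9 and np.allclose(rel, u * d[j], atol=1e-9):
                        ok = True
                        break
                if ok:
                    break
            assert ok

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        X, y = rng.random((30, 3)), np.array([1] * 5 + [0] * 25)
        a = smote_resample(X, y, seed=9)
        b = smote_resample(X, y, seed=9)
        np.testing.assert_array_equal(a[0], b[0])

    def test_minority_of_one_errors(self):
        X, y = np.random.default_rng(6).random((6, 2)), np.array([1, 0, 0, 0, 0, 0])
        with pytest.raises(SmoteError, match="drop"):
            smote_resample(X, y)


class TestTrainAndEvaluate:
    @pytest.mark.parametrize("method", ["RF", "XGB", "MLP"])
    def test_separable_training_accuracy(self, method, separable_table):
        model = train_model(ModelSpec(method, seed=0), separable_table)
        m = evaluate(model, separable_table)
        assert m.accuracy == pytest.approx(1.0)

    def test_dnn_learns_separable_toy(self, separable_table):
        model = train_model(ModelSpec("DNN", seed=0), separable_table)
        m = evaluate(model, separable_table)
        assert m.f1 == pytest.approx(1.0)

    @pytest.mark.parametrize("method", ["RF", "XGB", "MLP", "DNN"])
    def test_no_signal_auc_near_half(self, method):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(240, 5))
        y = np.array([0, 1] * 120)
        ids = [f"s{i}" for i in range(240)]
        feats = [f"f{i}" for i in range(5)]
        ft_train = FeatureTable(X[:160], y[:160], ids[:160], feats)
        ft_test = FeatureTable(X[160:], y[160:], ids[160:], feats)
        model = train_model(ModelSpec(method, seed=2), ft_train)
        m = evaluate(model, ft_test)
        assert 0.35 <= m.auc <= 0.65

    def test_single_class_labels_error(self, separable_table):
        ft = separable_table.relabel(np.zeros_like(separable_table.y))
        with pytest.raises(ValueError, match="single class"):
            train_model(ModelSpec("RF", seed=0), ft)

    def test_gbt_alias_maps_to_xgb(self):
        assert ModelSpec("GBT").method == "XGB"

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("SVM")

    def test_determinism_under_seed(self, separable_table):
        a = train_model(ModelSpec("DNN", seed=7), separable_table)
        b = train_model(ModelSpec("DNN", seed=7), separable_table)
        np.testing.assert_array_equal(
            a.predict_score(separable_table.X), b.predict_score(separable_table.X)
        )


class TestMetricsArithmetic:
    @pytest.mark.parametrize(
        "precision,recall,f1_2dp",
        [
            (0.9, 0.58, 0.71),
            (0.92, 0.77, 0.84),
            (0.99, 0.80, 0.88),
            (0.9, 0.8, 0.85),
        ],
    )
    def test_f1_is_harmonic_mean(self, precision, recall, f1_2dp):
        assert round(f1_from_precision_recall(precision, recall), 2) == f1_2dp

    def test_zero_precision_recall_gives_zero(self):
        assert f1_from_precision_recall(0.0, 0.0) == 0.0

    def test_evaluate_consistency_and_extremes(self, separable_table):
        model = train_model(ModelSpec("RF", seed=0), separable_table)
        m = evaluate(model, separable_table)
        assert m.f1 == pytest.approx(f1_from_precision_recall(m.precision, m.recall))
        assert m.auc == pytest.approx(1.0)
        assert m.n_positive == int(separable_table.y.sum())

    def test_all_negative_predictions_zero_precision(self, separable_table):
        class AllNegative:
            method = "RF"

            def predict_score(self, X):
                return np.zeros(len(X))

        from sigspec.ml import TrainedModel

        model = TrainedModel.__new__(TrainedModel)
        model.method = "RF"
        model.inner = None
        model.feature_ids = separable_table.feature_ids
        model.predict_score = lambda X: np.zeros(len(X))
        with pytest.warns(UserWarning, match="no predicted positives"):
            m = evaluate(model, separable_table)
        assert m.precision == 0.0 and m.f1 == 0.0

    def test_no_positive_test_samples_errors(self, separable_table):
        model = train_model(ModelSpec("RF", seed=0), separable_table)
        ft = separable_table.relabel(np.zeros_like(separable_table.y))
        with pytest.raises(ValueError, match="no positive"):
            evaluate(model, ft)

    def test_rank_auc_matches_sklearn(self, separable_table):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(4)
        scores = rng.random(separable_table.y.size)
        from sigspec.ml import _rank_auc

        assert _rank_auc(scores, separable_table.y) == pytest.approx(
            roc_auc_score(separable_table.y, scores)
        )


class TestFeatureImportance:
    @pytest.mark.parametrize("method", ["RF", "XGB"])
    def test_impurity_importances_sum_to_one(self, method, separable_table):
        model = train_model(ModelSpec(method, seed=0), separable_table)
        imp = feature_importance(model, separable_table, seed=0)
        assert sum(v for _, v in imp) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("method", ["RF", "XGB", "MLP", "DNN"])
    def test_separating_feature_ranks_first(self, method, separable_table):
        model = train_model(ModelSpec(method, seed=0), separable_table)
        imp = feature_importance(model, separable_table, seed=0)
        assert imp[0][0] == "f0"

    def test_noise_feature_near_zero_permutation_importance(self, separable_table):
        model = train_model(ModelSpec("MLP", seed=0), separable_table)
        imp = dict(feature_importance(model, separable_table, seed=0))
        for fid in ("f1", "f2", "f3", "f4", "f5"):
            assert abs(imp[fid]) < 0.05
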
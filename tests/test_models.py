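"""Model fitting, cross-validation and the self-implemented metrics,
cross-checked against brute-force and library oracles."""

import numpy as np
import pytest

from qsdar.models import (ConfusionMatrix, ModelConfig, QSDARModel,
                          confusion_metrics, cross_val_predictions,
                          cross_validate, fit_model, regression_metrics,
                          roc_auc, roc_curve_points, select_top_k)


def brute_force_auc(scores, labels):
    """Concordant-pair oracle: P(pos > neg) with ties counting one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusionMetrics:
    def test_external_test_counts(self):
        # printed external-validation counts of the screening classifier
        m = confusion_metrics(ConfusionMatrix(tp=365, tn=574, fp=137, fn=126))
        assert round(m.se, 3) == 0.743
        assert round(m.sp, 3) == 0.807
        assert round(m.q, 3) == 0.781
        assert round(m.mcc, 3) == 0.549

    def test_training_cv_counts(self):
        m = confusion_metrics(ConfusionMatrix(tp=33333, tn=57268, fp=15515,
                                              fn=13617))
        assert round(m.se, 3) == 0.710
        assert round(m.sp, 3) == 0.787
        assert round(m.q, 3) == 0.757
        assert round(m.mcc, 3) == 0.494

    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionMatrix(10, 10, 0, 0))
        assert (m.se, m.sp, m.q, m.mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_zero_denominator_convention(self):
        m = confusion_metrics(ConfusionMatrix(tp=5, tn=0, fp=0, fn=5))
        assert m.mcc == 0.0

    def test_mcc_symmetric_under_class_swap(self, rng):
        for _ in range(20):
            tp, tn, fp, fn = rng.integers(0, 100, size=4)
            if tp + tn + fp + fn == 0:
                continue
            a = confusion_metrics(ConfusionMatrix(int(tp), int(tn), int(fp), int(fn)))
            b = confusion_metrics(ConfusionMatrix(int(tn), int(tp), int(fn), int(fp)))
            assert a.mcc == pytest.approx(b.mcc)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(ConfusionMatrix(0, 0, 0, 0))
        with pytest.raises(ValueError):
            ConfusionMatrix(-1, 0, 0, 0)

    def test_additivity(self):
        a = ConfusionMatrix(1, 2, 3, 4)
        b = ConfusionMatrix(10, 20, 30, 40)
        assert (a + b) == ConfusionMatrix(11, 22, 33, 44)


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        m = regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (m.r2, m.mae, m.rmse) == (1.0, 0.0, 0.0)

    def test_mean_predictor_has_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = regression_metrics(y, np.full(4, y.mean()))
        assert m.r2 == pytest.approx(0.0)

    def test_hand_computed_case(self):
        m = regression_metrics([0.0, 1.0, 2.0], [0.0, 1.0, 3.0])
        assert m.mae == pytest.approx(1 / 3)
        assert m.rmse == pytest.approx(np.sqrt(1 / 3))
        assert m.r2 == pytest.approx(0.5)  # SS_res = 1, SS_tot = 2

    def test_constant_target_flagged(self):
        m = regression_metrics([2.0, 2.0, 2.0], [2.0, 2.1, 1.9])
        assert m.r2 is None and not m.r2_defined
        assert m.mae == pytest.approx(0.2 / 3)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import mean_absolute_error, r2_score
        y, yhat = rng.normal(size=50), rng.normal(size=50)
        m = regression_metrics(y, yhat)
        assert m.r2 == pytest.approx(r2_score(y, yhat))
        assert m.mae == pytest.approx(mean_absolute_error(y, yhat))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_hand_case(self):
        assert roc_auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == 0.75

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 50))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            scores = np.round(rng.uniform(0, 1, size=n), 2)  # force ties
            assert roc_auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_curve_endpoints_and_trapezoid(self, rng):
        scores = rng.uniform(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[0], labels[1] = 0, 1
        fpr, tpr = roc_curve_points(scores, labels)
        assert fpr[0] == tpr[0] == 0.0
        assert fpr[-1] == tpr[-1] == 1.0
        assert np.trapezoid(tpr, fpr) == pytest.approx(roc_auc(scores, labels))


class TestSelectTopK:
    def test_ordering(self):
        assert list(select_top_k([0.5, 0.3, 0.2], 2)) == [0, 1]

    def test_tie_break_by_lower_index(self):
        assert list(select_top_k([0.25, 0.25, 0.25, 0.25], 2)) == [0, 1]

    def test_unordered_importances(self):
        assert list(select_top_k([0.1, 0.9, 0.05, 0.9], 2)) == [1, 3]

    def test_k_equals_all_is_identity(self):
        assert list(select_top_k([0.2, 0.1, 0.7], 3)) == [0, 1, 2]

    @pytest.mark.parametrize("k", [0, 4])
    def test_k_out_of_range(self, k):
        with pytest.raises(ValueError):
            select_top_k([0.1, 0.2, 0.3], k)


def _threshold_dataset(rng, n=300, p=8):
    """Class is a noiseless threshold on feature 0 -> trivially separable."""
    X = rng.normal(size=(n, p))
    y = np.where(X[:, 0] > 0, "active", "inactive")
    return X, y


class TestFitModel:
    @pytest.mark.parametrize("algo", ["rf", "gbm", "svm"])
    def test_separable_training_mcc_is_one(self, algo, rng):
        X, y = _threshold_dataset(rng)
        cfg = ModelConfig(algo=algo, task="classification", n_trees=50, seed=0)
        est = fit_model(X, y, cfg)
        assert np.array_equal(est.predict(X), y) or (
            np.mean(est.predict(X) == y) > 0.99)

    def test_probabilities_are_normalised(self, rng):
        X, y = _threshold_dataset(rng)
        est = fit_model(X, y, ModelConfig(algo="gbm", n_trees=50, seed=0))
        proba = est.predict_proba(X)
        assert proba.shape == (len(y), 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert proba.min() >= 0 and proba.max() <= 1

    def test_seed_determinism(self, rng):
        X, y = _threshold_dataset(rng)
        cfg = ModelConfig(algo="rf", n_trees=30, seed=5)
        a = fit_model(X, y, cfg).predict(X)
        b = fit_model(X, y, cfg).predict(X)
        assert np.array_equal(a, b)

    def test_shape_and_class_validation(self, rng):
        X, y = _threshold_dataset(rng, n=20)
        with pytest.raises(ValueError):
            fit_model(X[:10], y, ModelConfig())
        with pytest.raises(ValueError):
            fit_model(X, np.repeat("active", 20), ModelConfig())
        Xbad = X.copy()
        Xbad[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_model(Xbad, y, ModelConfig())

    def test_default_tree_counts(self):
        assert ModelConfig(algo="rf", task="regression").effective_n_trees == 1000
        assert ModelConfig(algo="gbm", task="regression").effective_n_trees == 500
        assert ModelConfig(algo="gbm", task="classification").effective_n_trees == 1000

    def test_mlp_default_layout(self):
        from qsdar.models import _make_estimator
        est = _make_estimator(ModelConfig(algo="mlp", task="classification"))
        assert est.hidden_layer_sizes == (150, 150, 150, 150)
        assert est.activation == "relu"
        assert est.batch_size == 128
        assert est.max_iter == 500


class TestCrossValidate:
    def test_identity_feature_recovers_target(self, rng):
        y = rng.normal(size=200)
        X = np.column_stack([y, rng.normal(size=200)])
        rep = cross_validate(X, y, ModelConfig(algo="rf", task="regression",
                                               n_trees=100, seed=0))
        assert rep.metrics.r2 >= 0.99

    def test_oob_scheme_for_forest(self, rng):
        X, y = _threshold_dataset(rng, n=400)
        rep = cross_validate(X, y, ModelConfig(algo="rf", n_trees=100, seed=0),
                             scheme="oob")
        assert rep.scheme == "oob"
        assert rep.metrics.mcc > 0.8

    def test_oob_rejected_for_boosting(self, rng):
        X, y = _threshold_dataset(rng, n=50)
        with pytest.raises(ValueError, match="bagging"):
            cross_validate(X, y, ModelConfig(algo="gbm"), scheme="oob")

    def test_constant_regression_target_flagged(self, rng):
        X = rng.normal(size=(50, 3))
        rep = cross_validate(X, np.full(50, 3.14),
                             ModelConfig(algo="rf", task="regression",
                                         n_trees=20, seed=0))
        assert rep.metrics.r2 is None
        assert rep.metrics.mae < 1e-6

    def test_deterministic_reports(self, rng):
        X, y = _threshold_dataset(rng, n=120)
        cfg = ModelConfig(algo="gbm", n_trees=40, seed=3)
        assert cross_validate(X, y, cfg) == cross_validate(X, y, cfg)

    def test_out_of_fold_predictions_cover_every_row(self, rng):
        X, y = _threshold_dataset(rng, n=100)
        yhat, scores = cross_val_predictions(
            X, y, ModelConfig(algo="gbm", n_trees=30, seed=0))
        assert len(yhat) == len(scores) == 100
        assert set(np.unique(yhat)) <= {"active", "inactive"}


class TestModelResultsObjects:
    def test_fit_evaluate_summary(self, rng):
        X, y = _threshold_dataset(rng, n=200)
        model = QSDARModel(X, y, ModelConfig(algo="gbm", n_trees=50, seed=0))
        res = model.fit()
        rep = res.evaluate(X, y, scheme="training")
        assert rep.metrics.q > 0.99
        text = res.summary([rep])
        assert "MCC=" in text and "training" in text

    def test_from_dataframe(self, rng):
        import pandas as pd
        X, y = _threshold_dataset(rng, n=60, p=3)
        frame = pd.DataFrame(X, columns=["a", "b", "c"])
        frame["class"] = y
        frame["id"] = [f"m{i}" for i in range(60)]
        model = QSDARModel.from_dataframe(frame, target="class")
        assert model.X.shape == (60, 3)
        assert model.feature_names == ("a", "b", "c")

    def test_select_all_features_matches_full_model(self, rng):
        X, y = _threshold_dataset(rng, n=150, p=5)
        cfg = ModelConfig(algo="gbm", n_trees=40, seed=1)
        model = QSDARModel(X, y, cfg)
        idx, reduced = model.select_features(5)
        assert list(idx) == [0, 1, 2, 3, 4]
        full_pred = model.fit().predict(X)
        red_pred = reduced.fit().predict(X)
        assert np.array_equal(full_pred, red_pred)

    def test_permuted_labels_have_no_signal(self, rng):
        # permutation null on a modest problem: MCC concentrates near zero
        X = rng.normal(size=(600, 20))
        y = rng.permutation(np.repeat(["active", "inactive"], 300))
        mccs = [cross_validate(X, np.random.default_rng(s).permutation(y),
                               ModelConfig(algo="gbm", n_trees=60, seed=s)
                               ).metrics.mcc
                for s in range(5)]
        assert abs(float(np.mean(mccs))) < 0.08
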
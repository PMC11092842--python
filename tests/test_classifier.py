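"""Training protocol: architecture selection, hyperparameter search,
isotonic calibration, prediction contract and determinism."""

import numpy as np
import pandas as pd
import pytest

from cnvsig import classifier as clf
from cnvsig.classifier import (
    CLASS_ORDER,
    calibrate_and_fit,
    label_from_probabilities,
    select_architecture,
    train_model,
    tune_hyperparameters,
)


@pytest.fixture(scope="module")
def separable_data():
    """3-class data whose labels are a noiseless function of two features."""
    rng = np.random.default_rng(0)
    X = rng.random((240, 5))
    y = np.where(X[:, 0] > 0.6, "pathogenic", np.where(X[:, 2] > 0.5, "VUS", "benign"))
    return X, y


class TestSelectArchitecture:
    def test_tree_beats_prior_baseline_on_separable_data(self, separable_data):
        """A tree must outscore the closed-form macro F1 of always predicting
        the majority class (F1 = 2p/(1+p) for the majority, 0 elsewhere)."""
        X, y = separable_data
        ranking = select_architecture(X, y, roster=("decision_tree",), k=5, seed=1)
        _, counts = np.unique(y, return_counts=True)
        p = counts.max() / counts.sum()
        baseline_macro_f1 = (2 * p / (1 + p)) / 3
        assert ranking[0][1] > baseline_macro_f1

    def test_tree_ranks_above_weak_learner(self, separable_data):
        X, y = separable_data
        ranking = select_architecture(
            X, y, roster=("gaussian_nb", "random_forest"), k=5, seed=1
        )
        assert ranking[0][0] == "random_forest"

    def test_single_architecture_roster(self, separable_data):
        X, y = separable_data
        ranking = select_architecture(X, y, roster=("knn",), k=5, seed=1)
        assert len(ranking) == 1 and ranking[0][0] == "knn"

    def test_same_seed_identical_ranking(self, separable_data):
        X, y = separable_data
        roster = ("decision_tree", "knn", "gaussian_nb")
        a = select_architecture(X, y, roster=roster, k=5, seed=7)
        b = select_architecture(X, y, roster=roster, k=5, seed=7)
        assert a == b

    def test_small_class_rejected(self):
        X = np.random.default_rng(0).random((12, 3))
        y = np.array(["benign"] * 9 + ["VUS"] * 2 + ["pathogenic"])
        with pytest.raises(ValueError, match="smaller k"):
            select_architecture(X, y, roster=("knn",), k=5, seed=0)


class TestTuneHyperparameters:
    def test_single_draw_returned(self, separable_data):
        X, y = separable_data
        params, score = tune_hyperparameters(
            X, y, "decision_tree", n_draws=1, k=3, seed=2
        )
        assert params and np.isfinite(score)

    def test_adequate_setting_beats_degenerate(self, separable_data):
        X, y = separable_data
        space = {"max_depth": [1, 8]}  # a depth-1 stump cannot separate 3 classes
        params, _ = tune_hyperparameters(
            X, y, "decision_tree", n_draws=10, space=space, k=3, seed=2
        )
        assert params["max_depth"] == 8

    def test_fixed_seed_reproducible(self, separable_data):
        X, y = separable_data
        a = tune_hyperparameters(X, y, "decision_tree", n_draws=5, k=3, seed=4)
        b = tune_hyperparameters(X, y, "decision_tree", n_draws=5, k=3, seed=4)
        assert a == b

    def test_empty_space_returns_defaults(self, separable_data):
        X, y = separable_data
        params, score = tune_hyperparameters(X, y, "decision_tree", space={}, k=3, seed=0)
        assert params == {} and np.isnan(score)


class TestCalibration:
    def test_probabilities_on_simplex_and_monotone_calibrators(self, separable_data):
        X, y = separable_data
        frame = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
        model = calibrate_and_fit(frame, y, "DEL", "random_forest",
                                  {"n_estimators": 50}, k=5, seed=0)
        proba = model.predict_proba(frame)
        assert (proba >= 0).all()
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        # each per-class isotonic map is non-decreasing in the raw score
        for calibrator in model.estimator.calibrated_classifiers_[0].calibrators:
            assert np.all(np.diff(calibrator.y_thresholds_) >= 0)

    def test_calibration_does_not_worsen_reliability(self):
        """On held-out data with known posteriors, 10-bin calibration error
        must not increase relative to the uncalibrated estimator."""
        rng = np.random.default_rng(1)
        n = 3000
        X = rng.random((n, 2))
        p_patho = X[:, 0]  # true P(pathogenic | x)
        y = np.where(rng.random(n) < p_patho, "pathogenic",
                     np.where(X[:, 1] > 0.5, "VUS", "benign"))
        train, test = slice(0, n // 2), slice(n // 2, n)
        frame = pd.DataFrame(X, columns=["a", "b"])
        from sklearn.ensemble import RandomForestClassifier

        raw = RandomForestClassifier(n_estimators=100, random_state=0).fit(X[train], y[train])
        model = calibrate_and_fit(frame.iloc[train], y[train], "DEL", "random_forest",
                                  {"n_estimators": 100}, k=5, seed=0)

        y_test = y[test]

        def ece(prob_patho):
            bins = np.clip((prob_patho * 10).astype(int), 0, 9)
            err = 0.0
            for b in range(10):
                m = bins == b
                if m.sum():
                    err += m.sum() * abs(
                        prob_patho[m].mean() - (y_test[m] == "pathogenic").mean()
                    )
            return err / len(y_test)

        raw_p = raw.predict_proba(X[test])[:, list(raw.classes_).index("pathogenic")]
        cal_p = model.predict_proba(frame.iloc[test])[:, 2]
        assert ece(cal_p) <= ece(raw_p) + 1e-9


class TestPredictionContract:
    @pytest.mark.parametrize(
        "probs, expected",
        [
            ((0.2, 0.3, 0.5), "pathogenic"),
            ((1 / 3, 1 / 3, 1 / 3), "pathogenic"),  # tie: conservative priority
            ((0.4, 0.4, 0.2), "VUS"),  # benign/VUS tie -> VUS
            ((0.7, 0.2, 0.1), "benign"),
        ],
    )
    def test_argmax_with_priority_tie_break(self, probs, expected):
        assert label_from_probabilities(probs) == expected

    def test_simplex_on_random_inputs(self, study):
        model = study["models"]["DEL"]
        rng = np.random.default_rng(8)
        n = 10_000
        frame = pd.DataFrame(
            rng.random((n, len(model.feature_names))) * 10, columns=model.feature_names
        )
        proba = model.predict_proba(frame)
        assert (proba >= 0).all()
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_class_order_is_recorded(self, study):
        assert study["models"]["DUP"].class_order == CLASS_ORDER


class TestEndToEnd:
    def test_parameter_recovery_on_study(self, study):
        """Trained per-type models recover the noiseless generative rule."""
        from cnvsig.evaluation import multiclass_summary

        preds, truth = [], []
        for cnv_type, model in study["models"].items():
            rows = [r for r in study["test_records"] if r.cnv_type == cnv_type]
            results = model.predict(study["X_test"].loc[[r.id for r in rows]])
            preds += [r.label for r in results]
            truth += [r.collapsed_label for r in rows]
        assert multiclass_summary(preds, truth).macro_f1 >= 0.95

    def test_training_determinism(self, study):
        """Retraining with identical seed reproduces metadata and predictions."""
        cnv_type = "DEL"
        rows = [r for r in study["train_records"] if r.cnv_type == cnv_type]
        X = study["X_train"].loc[[r.id for r in rows]]
        y = [r.collapsed_label for r in rows]
        again = train_model(X, y, cnv_type, roster=study["roster"], k=study["folds"],
                            n_draws=study["draws"], seed=study["seed"])
        first = study["models"][cnv_type]
        assert again.architecture == first.architecture
        assert again.hyperparameters == first.hyperparameters
        assert again.cv_summary == first.cv_summary
        np.testing.assert_array_equal(
            again.predict_proba(study["X_test"]), first.predict_proba(study["X_test"])
        )

    def test_save_load_round_trip(self, study, tmp_path):
        model = study["models"]["DEL"]
        model.save(tmp_path / "m")
        back = clf.TrainedModel.load(tmp_path / "m")
        np.testing.assert_allclose(
            back.predict_proba(study["X_test"]), model.predict_proba(study["X_test"])
        )
        assert back.architecture == model.architecture
        assert back.seed == model.seed
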
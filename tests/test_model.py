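"""Metrics, learners, stacking ensembles and the model/results surface."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import matthews_corrcoef, roc_auc_score, roc_curve

from saaspred.dataset import LabeledDataset
from saaspred.metrics import (
    ConfusionCounts,
    compute_metrics,
    full_report,
    roc_auc,
)
from saaspred.model import (
    ALGORITHMS,
    CvConfig,
    LearnerSpec,
    ModelBundle,
    SubstitutionEffectModel,
    build_estimator,
    stacking_subsets,
    tune_hyperparameters,
)
from saaspred.records import SaasError
from saaspred.synthetic import make_labeled_table


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(50, 50, 0, 0))
        assert all(m[k] == 1.0 for k in ("SEN", "SPE", "PRE", "ACC", "MCC"))

    def test_hand_worked_counts(self):
        m = compute_metrics(ConfusionCounts(tp=40, tn=45, fp=5, fn=10))
        assert m["ACC"] == pytest.approx(0.85)
        assert m["SEN"] == pytest.approx(0.8)
        assert m["SPE"] == pytest.approx(0.9)
        assert m["PRE"] == pytest.approx(0.888888, abs=1e-4)
        assert m["MCC"] == pytest.approx(0.7035, abs=1e-4)

    def test_single_class_predictions_mcc_zero(self):
        with pytest.warns(UserWarning):
            m = compute_metrics(ConfusionCounts(tp=10, tn=0, fp=5, fn=0))
        assert m["MCC"] == 0.0

    def test_all_zero_counts_error(self):
        with pytest.raises(SaasError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_mcc_equals_pearson_correlation(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(10, 60))
            yt = rng.integers(0, 2, n)
            yp = rng.integers(0, 2, n)
            if yt.min() == yt.max() or yp.min() == yp.max():
                continue
            m = compute_metrics(ConfusionCounts.from_predictions(yt, yp))
            assert m["MCC"] == pytest.approx(np.corrcoef(yt, yp)[0, 1],
                                             abs=1e-12)
            assert m["MCC"] == pytest.approx(matthews_corrcoef(yt, yp),
                                             abs=1e-12)


class TestRocAuc:
    def test_separated_scores(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores(self):
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_three_of_four_concordant(self):
        assert roc_auc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0]) == 0.75

    def test_single_class_errors(self):
        with pytest.raises(SaasError):
            roc_auc([0.1, 0.9], [1, 1])

    def test_matches_trapezoidal_integration(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = int(rng.integers(6, 50))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            s = np.round(rng.random(n), 1)  # coarse grid forces ties
            ours = roc_auc(s, y)
            fpr, tpr, _ = roc_curve(y, s)
            assert ours == pytest.approx(np.trapezoid(tpr, fpr), abs=1e-12)
            assert ours == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_score_reversal_complements(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 40)
        y[0], y[1] = 0, 1
        s = rng.random(40)
        assert roc_auc(-s, y) == pytest.approx(1.0 - roc_auc(s, y), abs=1e-12)


class TestStackingEnumeration:
    def test_four_learners_eleven_ensembles(self):
        assert len(stacking_subsets(list(ALGORITHMS))) == 11

    @pytest.mark.parametrize("k,expected", [(2, 1), (3, 4), (4, 11)])
    def test_combination_counts(self, k, expected):
        assert len(stacking_subsets(list(ALGORITHMS)[:k])) == expected


class TestTuning:
    def test_single_point_grid(self):
        ds = make_labeled_table(n=120, n_features=4, informative_idx=(0,),
                                seed=1)
        spec = LearnerSpec("random_forest",
                           grid=({"ntree": 20, "nodesize": 5},))
        params, fitness = tune_hyperparameters(spec, ds,
                                               CvConfig(repeats=1, seed=0))
        assert params == {"ntree": 20, "nodesize": 5}
        assert -1.0 <= fitness <= 1.0

    def test_deterministic_choice(self):
        ds = make_labeled_table(n=150, n_features=4, informative_idx=(0, 1),
                                seed=2)
        spec = LearnerSpec("random_forest",
                           grid=({"ntree": 15}, {"ntree": 30}))
        r1 = tune_hyperparameters(spec, ds, CvConfig(repeats=1, seed=5))
        r2 = tune_hyperparameters(spec, ds, CvConfig(repeats=1, seed=5))
        assert r1 == r2

    def test_interaction_target_needs_depth(self):
        # XOR-style label: depth-1 stumps cannot express it, deep trees can
        rng = np.random.default_rng(3)
        X = rng.standard_normal((600, 2))
        y = ((X[:, 0] > 0) ^ (X[:, 1] > 0)).astype(int)
        ds = LabeledDataset(features=pd.DataFrame(X, columns=["a", "b"]),
                            labels=y)
        spec = LearnerSpec("gradient_boosted_trees",
                           grid=({"nrounds": 30, "max_depth": 1},
                                 {"nrounds": 30, "max_depth": 4}))
        params, _ = tune_hyperparameters(spec, ds, CvConfig(repeats=1, seed=0))
        assert params["max_depth"] == 4

    def test_too_small_dataset_errors(self):
        ds = make_labeled_table(n=6, n_features=2, informative_idx=(0,),
                                seed=4)
        with pytest.raises(SaasError):
            tune_hyperparameters(LearnerSpec("svm"), ds, CvConfig())

    def test_unknown_algorithm_errors(self):
        with pytest.raises(SaasError):
            LearnerSpec("decision_stump")
        with pytest.raises(SaasError):
            build_estimator("decision_stump", {})


@pytest.fixture(scope="module")
def fitted_results():
    ds = make_labeled_table(n=300, n_features=6, informative_idx=(0, 1),
                            coefficients=[3.0, 3.0], seed=6)
    specs = [LearnerSpec("random_forest", grid=({"ntree": 30},)),
             LearnerSpec("gradient_boosted_trees",
                         grid=({"nrounds": 30, "max_depth": 3},))]
    model = SubstitutionEffectModel(ds, specs=specs)
    return ds, model.fit(CvConfig(repeats=1, seed=0), seed=0)


class TestModelResults:
    def test_two_learners_one_ensemble(self, fitted_results):
        _, res = fitted_results
        assert len(res.bundle.base_models) == 2
        assert len(res.bundle.meta_models) == 1
        assert len(res.bundle.model_names) == 3

    def test_scores_in_unit_interval(self, fitted_results):
        ds, res = fitted_results
        for name in res.bundle.model_names:
            s = res.bundle.score(ds.features, name)
            assert np.all((0.0 <= s) & (s <= 1.0))

    def test_threshold_rule_inclusive(self, fitted_results):
        ds, res = fitted_results
        scores, classes = res.predict(ds.features)
        for s, c in zip(scores, classes):
            assert c == ("functional" if s >= 0.5 else "neutral")

    def test_feature_mismatch_errors(self, fitted_results):
        _, res = fitted_results
        with pytest.raises(SaasError, match="F000"):
            res.bundle.score(pd.DataFrame({"other": [1.0]}))

    def test_evaluate_columns_ordered(self, fitted_results):
        ds, res = fitted_results
        table = res.evaluate(ds)
        assert list(table.columns) == ["MCC", "ACC", "SEN", "SPE", "PRE", "AUC"]
        assert len(table) == 3

    def test_summary_mentions_learners(self, fitted_results):
        _, res = fitted_results
        text = res.summary()
        assert "random_forest" in text and "Stacking ensembles: 1" in text

    def test_bundle_roundtrip(self, fitted_results, tmp_path):
        ds, res = fitted_results
        res.bundle.save(tmp_path / "bundle")
        back = ModelBundle.load(tmp_path / "bundle")
        s0 = res.bundle.score(ds.features)
        s1 = back.score(ds.features)
        assert np.allclose(s0, s1)
        assert back.threshold == 0.5
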
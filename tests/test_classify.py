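import numpy as np
import pandas as pd
import pytest

from pupilvalence import (
    feature_attribution,
    fit_predict_fold,
    grid_run,
    group_kfold_split,
    run_cv,
    smote_oversample,
)
from pupilvalence.classify import make_classifier
from pupilvalence.features import FEATURE_NAMES
from pupilvalence.types import CLASSIFIER_NAMES, RunConfig, ValidationError


def _records(n_participants=20, per_class=5, sep=3.0, seed=0):
    """Separable synthetic feature table with participant grouping."""
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_participants):
        for c, valence in ((0, "negative"), (1, "positive")):
            for _ in range(per_class):
                feats = rng.normal(c * sep, 1.0, size=45)
                row = {"participant_id": f"p{p:02d}", "stimulus_id": "sX",
                       "valence": valence, "arousal_level": "mid", "sf_level": 3}
                row.update(dict(zip(FEATURE_NAMES, feats)))
                rows.append(row)
    return pd.DataFrame(rows)


class TestGroupKFold:
    def test_forty_participants_five_folds(self):
        plan = group_kfold_split(_records(40), k=5, seed=1004)
        for train, test in plan.folds:
            assert len(test) == 8
            assert not train & test
        all_test = [p for _, test in plan.folds for p in test]
        assert len(all_test) == len(set(all_test)) == 40

    @pytest.mark.parametrize("k", [3, 5, 7])
    def test_supported_fold_counts(self, k):
        plan = group_kfold_split(_records(21), k=k, seed=1)
        assert len(plan.folds) == k

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValidationError):
            group_kfold_split(_records(3), k=5, seed=1)


class TestSMOTE:
    def test_balanced_input_unchanged(self, rng):
        X = rng.normal(size=(10, 4))
        y = np.array([0] * 5 + [1] * 5)
        X2, y2, src, synth = smote_oversample(X, y, k_neighbors=3, seed=1)
        np.testing.assert_array_equal(X2, X)
        assert not synth.any()

    def test_counts_balanced_after_oversampling(self, rng):
        X = rng.normal(size=(14, 4))
        y = np.array([0] * 10 + [1] * 4)
        X2, y2, src, synth = smote_oversample(X, y, k_neighbors=2, seed=1)
        assert (y2 == 0).sum() == (y2 == 1).sum() == 10
        assert synth.sum() == 6
        assert len(X2) == 20

    def test_synthetic_points_on_minority_segments(self):
        # minority of two points with k=1: every synthetic sample must lie
        # on the segment between them
        X = np.array([[0.0, 0.0], [1.0, 1.0]] + [[10 + i, 0] for i in range(6)])
        y = np.array([1, 1, 0, 0, 0, 0, 0, 0])
        X2, y2, src, synth = smote_oversample(X, y, k_neighbors=1, seed=3)
        new = X2[synth]
        assert len(new) == 4
        for p in new:
            assert p[0] == pytest.approx(p[1], abs=1e-12)  # on the diagonal
            assert -1e-12 <= p[0] <= 1 + 1e-12

    def test_provenance_points_at_minority_sources(self, rng):
        X = rng.normal(size=(15, 3))
        y = np.array([0] * 10 + [1] * 5)
        X2, y2, src, synth = smote_oversample(X, y, k_neighbors=2, seed=1)
        assert np.all(src[synth] >= 10)  # synthetic rows derive from minority
        assert np.all(src[~synth] == np.arange(15))

    def test_minority_too_small_for_k_rejected(self, rng):
        X = rng.normal(size=(12, 3))
        y = np.array([0] * 10 + [1] * 2)
        with pytest.raises(ValidationError, match="smaller k"):
            smote_oversample(X, y, k_neighbors=3, seed=1)

    def test_determinism(self, rng):
        X = rng.normal(size=(14, 4))
        y = np.array([0] * 10 + [1] * 4)
        a = smote_oversample(X, y, k_neighbors=2, seed=9)[0]
        b = smote_oversample(X, y, k_neighbors=2, seed=9)[0]
        np.testing.assert_array_equal(a, b)


class TestClassifiers:
    def test_all_eleven_identifiers_accepted(self):
        assert len(CLASSIFIER_NAMES) == 11
        for name in CLASSIFIER_NAMES:
            assert make_classifier(name, seed=1) is not None
        with pytest.raises(ValidationError):
            make_classifier("perceptron")

    @pytest.mark.parametrize("name", CLASSIFIER_NAMES)
    def test_fit_predict_on_separable_data(self, name, rng):
        X = np.vstack([rng.normal(0, 1, (30, 5)), rng.normal(5, 1, (30, 5))])
        y = np.array([0] * 30 + [1] * 30)
        pred, scores, model = fit_predict_fold(X, y, X, name, seed=1004)
        assert (pred == y).mean() == 1.0  # training accuracy on separable data
        assert scores.shape == (60,)

    def test_single_class_train_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValidationError):
            fit_predict_fold(X, np.zeros(10), X, "logistic")

    def test_determinism(self, rng):
        X = np.vstack([rng.normal(0, 1, (30, 5)), rng.normal(1.5, 1, (30, 5))])
        y = np.array([0] * 30 + [1] * 30)
        p1, s1, _ = fit_predict_fold(X, y, X, "random_forest", seed=1004)
        p2, s2, _ = fit_predict_fold(X, y, X, "random_forest", seed=1004)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(s1, s2)


class TestRunCV:
    def test_separable_data_high_auc(self):
        res = run_cv(_records(sep=3.0), RunConfig(cv_folds=5))
        assert res.mean["auc"] > 0.95

    def test_label_shuffle_near_chance(self, rng):
        records = _records(sep=3.0)
        records["valence"] = rng.permutation(records["valence"].to_numpy())
        res = run_cv(records, RunConfig(cv_folds=5))
        assert 0.4 <= res.mean["auc"] <= 0.6

    def test_smote_changes_training_only(self, rng):
        # the test folds must be identical with and without SMOTE;
        # compare per-fold test confusion totals row counts
        records = _records(per_class=5)
        drop = records[records["valence"] == "positive"].sample(60, random_state=0)
        records = records.drop(drop.index)  # induce imbalance
        res_plain = run_cv(records, RunConfig(cv_folds=5, smote_k_neighbors=None))
        res_smote = run_cv(records, RunConfig(cv_folds=5, smote_k_neighbors=2))
        for a, b in zip(res_plain.per_fold, res_smote.per_fold):
            assert a.tp + a.fp + a.tn + a.fn == b.tp + b.fp + b.tn + b.fn

    def test_fold_plan_has_no_leakage(self):
        res = run_cv(_records(), RunConfig(cv_folds=5))
        for train, test in res.fold_plan.folds:
            assert not train & test


class TestGridRun:
    def test_cells_and_absences(self, rng):
        records = _records(n_participants=12, per_class=4)
        # two strata: one balanced cell, one single-class cell (reported absent)
        records["arousal_level"] = "low"
        records.loc[records.index[-20:], "arousal_level"] = "high"
        records.loc[records.index[-20:], "valence"] = "negative"
        cells, absent, table = grid_run(
            records, RunConfig(), classifiers=["logistic"],
            smote_values=(None,), folds_values=(3,),
        )
        keys = {(c.arousal_level, c.sf_level) for c in cells}
        assert ("low", 3) in keys
        assert ("high", 3) in absent

    def test_best_selection_both_conventions(self):
        records = _records(n_participants=12, per_class=4, sep=2.0)
        cells, absent, table = grid_run(
            records, RunConfig(), classifiers=["logistic", "decision_tree"],
            smote_values=(None,), folds_values=(3,),
        )
        cell = cells[0]
        assert cell.best_by_auc["auc_mean"] == cell.results["auc_mean"].max()
        assert cell.best_by_p4["p4_mean"] == cell.results["p4_mean"].max()

    def test_determinism(self):
        records = _records(n_participants=10, per_class=3)
        kw = dict(classifiers=["logistic"], smote_values=(None, 2),
                  folds_values=(3,))
        _, _, t1 = grid_run(records, RunConfig(), **kw)
        _, _, t2 = grid_run(records, RunConfig(), **kw)
        pd.testing.assert_frame_equal(t1, t2)


class TestAttribution:
    def test_zero_coefficient_zero_contribution(self, rng):
        X = rng.normal(size=(200, 3))
        y = (X[:, 0] > 0).astype(int)
        _, _, model = fit_predict_fold(X, y, X, "logistic", seed=1)
        clf = model.named_steps["clf"]
        clf.coef_[0, 1] = 0.0  # pin feature b's weight to exactly zero
        clf.coef_[0, 2] = 0.0
        rep = feature_attribution(model, X, feature_names=["a", "b", "c"])
        assert rep.method == "linear"
        assert rep.ranking[0] == "a"
        assert rep.per_sample is not None
        np.testing.assert_allclose(rep.per_sample[:, 1:], 0.0, atol=1e-15)

    def test_duplicated_feature_splits_attribution(self, rng):
        x = rng.normal(size=(300, 1))
        y = (x[:, 0] + rng.normal(0, 0.5, 300) > 0).astype(int)
        _, _, m_single = fit_predict_fold(x, y, x, "logistic", seed=1)
        X2 = np.hstack([x, x])
        _, _, m_dup = fit_predict_fold(X2, y, X2, "logistic", seed=1)
        rep1 = feature_attribution(m_single, x, feature_names=["a"])
        rep2 = feature_attribution(m_dup, X2, feature_names=["a", "a2"])
        combined = rep2.per_sample.sum(axis=1)
        single = rep1.per_sample[:, 0]
        # L2 splits the weight over the two copies; the summed contribution
        # matches the single-feature attribution
        assert np.abs(combined - single).mean() < 0.15 * np.abs(single).mean()

    def test_permutation_fallback_for_trees(self, rng):
        X = rng.normal(size=(100, 3))
        X[:, 2] = 0.0
        y = (X[:, 0] > 0).astype(int)
        _, _, model = fit_predict_fold(X, y, X, "random_forest", seed=1)
        rep = feature_attribution(model, X, feature_names=list("abc"), y=y)
        assert rep.method == "permutation"
        assert rep.ranking[0] == "a"
        assert rep.per_sample is None

    def test_permutation_without_labels_rejected(self, rng):
        X = rng.normal(size=(50, 3))
        y = (X[:, 0] > 0).astype(int)
        _, _, model = fit_predict_fold(X, y, X, "random_forest", seed=1)
        with pytest.raises(ValidationError):
            feature_attribution(model, X, feature_names=list("abc"))
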
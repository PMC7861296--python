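"""Rule-set classification, evaluation metrics, and the CV harness."""

import numpy as np
import pandas as pd
import pytest

from forestrules import (Condition, Direction, EvaluationReport, PipelineConfig,
                         PreferenceProfile, Rule, RuleSet, cross_validate,
                         evaluate, extract_rules, predict, predict_all,
                         ruleset_size_sweep, simplify_ruleset)
from forestrules.fixtures import make_tabular
from forestrules.forest_shrink import majority_vote, tree_predictions


def rs_from(rules, n_features=2, classes=("A", "B"), fallback="A"):
    return RuleSet(rules, [f"feature{i}" for i in range(n_features)],
                   list(classes), fallback)


class TestPredict:
    def test_single_matching_rule_decides(self):
        rs = rs_from([Rule([Condition(0, Direction.LE, 0.5)], "B")])
        assert predict(rs, [0.0, 0.0]) == "B"

    def test_no_match_falls_back_to_majority_class(self):
        rs = rs_from([Rule([Condition(0, Direction.LE, 0.5)], "B")])
        assert predict(rs, [1.0, 0.0]) == "A"

    def test_majority_of_matching_rules(self):
        match_all = lambda c: Rule([Condition(0, Direction.LE, 10.0)], c)
        rs = rs_from([match_all("A"), match_all("A"), match_all("B")])
        assert predict(rs, [0.0, 0.0]) == "A"

    def test_vote_tie_broken_by_summed_score(self):
        a = Rule([Condition(0, Direction.LE, 10.0)], "A", score=1.0)
        b = Rule([Condition(0, Direction.LE, 10.0)], "B", score=5.0)
        assert predict(rs_from([a, b]), [0.0, 0.0]) == "B"

    def test_full_tie_broken_by_lowest_class_index(self):
        a = Rule([Condition(0, Direction.LE, 10.0)], "B", score=1.0)
        b = Rule([Condition(0, Direction.LE, 10.0)], "A", score=1.0)
        assert predict(rs_from([a, b]), [0.0, 0.0]) == "A"

    def test_missing_value_raises_with_imputation_hint(self):
        rs = rs_from([Rule([Condition(0, Direction.LE, 0.5)], "B")])
        with pytest.raises(ValueError, match="imput"):
            predict(rs, [np.nan, 0.0])

    def test_best_rule_vote(self):
        a = Rule([Condition(0, Direction.LE, 10.0)], "A", score=1.0)
        b = Rule([Condition(0, Direction.LE, 10.0)], "B", score=9.0)
        c = Rule([Condition(0, Direction.LE, 10.0)], "A", score=2.0)
        assert predict(rs_from([a, b, c]), [0.0, 0.0], vote="best_rule") == "B"


class TestEvaluate:
    def test_perfect_predictions(self):
        rs = rs_from([Rule([Condition(0, Direction.LE, 0.5)], "B"),
                      Rule([Condition(0, Direction.GT, 0.5)], "A")])
        X = np.array([[0.0, 0], [1.0, 0]])
        rep = evaluate(rs, X, ["B", "A"], positive_class="B")
        assert rep.accuracy == rep.sensitivity == rep.specificity == 1.0
        assert rep.coverage == 1.0

    def test_hand_confusion_table(self):
        # predictions: pos for feature0 <= 4.5 (rows 0-4), neg otherwise
        rs = rs_from([Rule([Condition(0, Direction.LE, 4.5)], "pos"),
                      Rule([Condition(0, Direction.GT, 4.5)], "neg")],
                     classes=("neg", "pos"), fallback="neg")
        X = np.arange(10.0).reshape(-1, 1)
        X = np.hstack([X, np.zeros((10, 1))])
        #        TP TP TP FP FP          FN TN TN TN TN
        y = ["pos", "pos", "pos", "neg", "neg", "pos", "neg", "neg", "neg", "neg"]
        rep = evaluate(rs, X, y, positive_class="pos")
        assert rep.sensitivity == pytest.approx(0.75)
        assert rep.specificity == pytest.approx(2 / 3)
        assert rep.accuracy == pytest.approx(0.7)

    def test_all_one_class_predictor_on_balanced_data(self):
        rs = rs_from([Rule([Condition(0, Direction.LE, 100.0)], "A")])
        X = np.zeros((10, 2))
        y = ["A"] * 5 + ["B"] * 5
        assert evaluate(rs, X, y, positive_class="A").accuracy == 0.5

    def test_no_positive_samples_gives_undefined_sensitivity(self):
        rs = rs_from([Rule([Condition(0, Direction.LE, 100.0)], "A")])
        rep = evaluate(rs, np.zeros((4, 2)), ["A"] * 4, positive_class="B")
        assert rep.sensitivity is None
        assert rep.specificity == 1.0

    def test_accuracy_cross_checked_against_sklearn_confusion(self):
        from sklearn.metrics import confusion_matrix

        rng = np.random.default_rng(4)
        rs = rs_from([Rule([Condition(0, Direction.LE, 0.0)], "A"),
                      Rule([Condition(0, Direction.GT, 0.0)], "B")])
        X = rng.normal(size=(100, 2))
        y = rng.choice(["A", "B"], size=100)
        rep = evaluate(rs, X, y, positive_class="B")
        pred = predict_all(rs, X)
        tn, fp, fn, tp = confusion_matrix(y, pred, labels=["A", "B"]).ravel()
        assert rep.accuracy == pytest.approx((tp + tn) / 100)


class TestForestAgreement:
    def test_full_ruleset_votes_agree_with_forest_majority(self, small_forest):
        forest, X, _ = small_forest
        rs = simplify_ruleset(extract_rules(forest, fallback_class=0))
        rng = np.random.default_rng(8)
        Xq = rng.normal(size=(300, X.shape[1])) + X.mean(axis=0)
        ours = predict_all(rs, Xq)
        theirs = majority_vote(tree_predictions(forest, Xq), list(forest.classes_))
        assert (ours == theirs).mean() >= 0.99

    def test_coverage_is_one_with_a_complete_tree(self, small_forest):
        forest, X, _ = small_forest
        rs = extract_rules(forest)
        one_tree = rs.replace_rules(r for r in rs.rules if r.tree == 0)
        from forestrules.inference import coverage
        assert coverage(one_tree, X) == 1.0


class TestCrossValidation:
    def test_folds_partition_samples(self):
        X, y, _ = make_tabular(n_samples=60, seed=5)
        from forestrules.inference import _fold_indices
        seen = np.zeros(60, dtype=int)
        for train, test in _fold_indices("kfold", y, 5, None, seed=0):
            assert set(train) | set(test) == set(range(60))
            assert not set(train) & set(test)
            seen[test] += 1
        np.testing.assert_array_equal(seen, 1)  # every sample in one test fold

    def test_loso_one_fold_per_subject(self):
        X, y, subjects = make_tabular(n_samples=50, n_subjects=10, seed=6)
        cfg = PipelineConfig(n_trees=5)
        reports, mean = cross_validate(cfg, X, y, scheme="loso",
                                       subject_ids=subjects, seed=0)
        assert len(reports) == 10
        assert sum(r.n_samples for r in reports) == 50
        assert all(r.n_samples == 5 for r in reports)

    def test_kfold_n_equals_leave_one_out(self):
        X, y, _ = make_tabular(n_samples=12, seed=7)
        cfg = PipelineConfig(n_trees=5)
        reports, _ = cross_validate(cfg, X, y, scheme="kfold", k=12, seed=0)
        assert len(reports) == 12
        assert all(r.n_samples == 1 for r in reports)

    def test_k_larger_than_n_rejected(self):
        X, y, _ = make_tabular(n_samples=10, seed=8)
        with pytest.raises(ValueError):
            cross_validate(PipelineConfig(n_trees=3), X, y, k=11, seed=0)

    def test_imputation_fitted_per_fold(self):
        # missing cells in both folds must not break the harness
        X, y, _ = make_tabular(n_samples=60, missing_rate=0.05, seed=9)
        cfg = PipelineConfig(n_trees=5, impute_strategy="median")
        reports, mean = cross_validate(cfg, X, y, scheme="kfold", k=3, seed=0)
        assert len(reports) == 3 and 0 <= mean.accuracy <= 1


class TestSizeSweep:
    def test_sweep_table_shape_and_full_fraction(self):
        X, y, _ = make_tabular(n_samples=120, class_sep=3.0, seed=10)
        cfg = PipelineConfig(n_trees=8)
        profiles = {"baseline": None, "fav0": PreferenceProfile(favorites=[0])}
        table = ruleset_size_sweep(cfg, X, y, fractions=[0.2, 1.0],
                                   profiles=profiles, seed=0, k=3)
        assert len(table) == 2 * 2  # |fractions| x |profiles|
        # the fraction-1.0 baseline row reproduces the unreduced CV accuracy
        _, mean = cross_validate(cfg, X, y, scheme="kfold", k=3, seed=0)
        baseline_full = table[(table.fraction == 1.0) &
                              (table.profile == "baseline")].mean_accuracy.iloc[0]
        assert baseline_full == pytest.approx(mean.accuracy)
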
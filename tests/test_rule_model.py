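"""Rule extraction, DNF rendering, within-rule simplification, JSON I/O."""

import numpy as np
import pytest

from forestrules import (Condition, Direction, Rule, RuleSet, RuleSetSchemaError,
                         UnsupportedModelError, extract_rules, parse_dnf,
                         read_ruleset, rule_to_dnf, simplify_rule,
                         simplify_ruleset, write_ruleset)
from forestrules.fixtures import figure_tree_expected

from conftest import make_stump, random_rule, random_ruleset


def as_triples(rule):
    return [(c.feature, c.direction.value, c.threshold) for c in rule.conditions]


class TestExtraction:
    def test_eight_leaf_tree_yields_eight_rules(self, figure_tree):
        rs = extract_rules([figure_tree])
        exp = figure_tree_expected()
        assert len(rs) == exp["n_leaves"]
        assert as_triples(rs.rules[0]) == exp["outer_left"]
        assert as_triples(rs.rules[5]) == exp["leaf5_raw"]
        assert rs.rules[5].outcome == exp["leaf5_outcome"]

    def test_single_leaf_stump(self):
        # a root-only "tree": one leaf, no splits -> one unconditional rule
        from forestrules.fixtures import ArrayTree
        stump = ArrayTree(np.array([-1]), np.array([-1]), np.array([-2]),
                          np.array([-2.0]), np.array([[1.0, 3.0]]),
                          np.array(["healthy", "sick"], dtype=object))
        rs = extract_rules([stump])
        assert len(rs) == 1
        assert rs.rules[0].conditions == []
        assert rs.rules[0].outcome == "sick"

    def test_rule_count_equals_leaf_count(self, small_forest):
        forest, _, _ = small_forest
        rs = extract_rules(forest)
        # independent oracle: count leaves by scanning the flat arrays
        n_leaves = sum(int((t.tree_.children_left == -1).sum())
                       for t in forest.estimators_)
        assert len(rs) == n_leaves

    def test_rules_partition_space_and_match_tree_votes(self, small_forest):
        forest, X, _ = small_forest
        rs = extract_rules(forest)
        rng = np.random.default_rng(5)
        sample_idx = rng.choice(len(X), size=50, replace=False)
        for t_idx, tree in enumerate(forest.estimators_):
            tree_rules = [r for r in rs.rules if r.tree == t_idx]
            tree_pred = tree.predict(X[sample_idx])
            for row, expected in zip(X[sample_idx], tree_pred):
                matching = [r for r in tree_rules if r.matches(row)]
                assert len(matching) == 1  # paths partition feature space
                assert matching[0].outcome == expected

    def test_unfitted_forest_rejected(self):
        from sklearn.ensemble import RandomForestClassifier

        with pytest.raises(UnsupportedModelError):
            extract_rules(RandomForestClassifier(n_estimators=3))


class TestDnf:
    def test_worked_example_rendering(self):
        rule = Rule([Condition(18, Direction.LE, -6.421),
                     Condition(10, Direction.LE, 0.008),
                     Condition(6, Direction.LE, 0.002)], "healthy")
        assert rule_to_dnf(rule) == \
            "(feature18<=-6.421 ∧ feature10<=0.008 ∧ feature6<=0.002) ⇒ healthy"

    def test_empty_conjunction_is_true(self):
        assert rule_to_dnf(Rule([], "healthy")) == "TRUE ⇒ healthy"

    def test_render_parse_render_idempotent(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            rule = random_rule(rng)
            text = rule_to_dnf(rule)
            assert rule_to_dnf(parse_dnf(text)) == text


class TestSimplify:
    def test_worked_example(self):
        exp = figure_tree_expected()
        raw = Rule([Condition(f, Direction(d), t) for f, d, t in exp["leaf5_raw"]],
                   exp["leaf5_outcome"])
        simplified = simplify_rule(raw)
        assert as_triples(simplified) == exp["leaf5_simplified"]
        assert not simplified.infeasible

    def test_distinct_features_unchanged(self):
        rule = Rule([Condition(0, Direction.LE, 1.0), Condition(1, Direction.GT, 2.0),
                     Condition(2, Direction.LE, 3.0)], "A")
        assert as_triples(simplify_rule(rule)) == as_triples(rule)

    def test_membership_preserved_on_random_rules(self):
        # brute-force oracle: original and simplified rule match the same points
        rng = np.random.default_rng(13)
        X = rng.normal(size=(200, 10))
        for _ in range(200):
            rule = random_rule(rng)
            simplified = simplify_rule(rule)
            assert simplified.rl <= rule.rl
            if simplified.infeasible:
                assert not any(rule.matches(row) for row in X)
            else:
                np.testing.assert_array_equal(rule.matches_matrix(X),
                                              simplified.matches_matrix(X))

    def test_infeasible_rule_flagged_not_deleted(self):
        rule = Rule([Condition(0, Direction.LE, 1.0), Condition(0, Direction.GT, 2.0)], "A")
        out = simplify_rule(rule)
        assert out.infeasible
        assert out.rl == 2  # both bounds retained for auditability
        assert not out.matches(np.array([1.5]))

    def test_ruleset_simplification_preserves_count(self, figure_tree):
        rs = extract_rules([figure_tree])
        out = simplify_ruleset(rs)
        assert len(out) == len(rs)
        # only the redundant-branch rule shrinks
        changed = [i for i in range(len(rs))
                   if as_triples(out.rules[i]) != as_triples(rs.rules[i])]
        assert changed == [5]


class TestJsonRoundTrip:
    def test_random_sets_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        for i in range(5):
            rs = random_ruleset(rng)
            path = tmp_path / f"rules{i}.json"
            write_ruleset(rs, path)
            back = read_ruleset(path)
            assert back.feature_names == rs.feature_names
            assert back.class_labels == rs.class_labels
            assert back.fallback_class == rs.fallback_class
            assert [as_triples(r) for r in back.rules] == [as_triples(r) for r in rs.rules]
            assert [(r.outcome, r.cc, r.ic, r.score) for r in back.rules] == \
                [(r.outcome, r.cc, r.ic, r.score) for r in rs.rules]

    def test_empty_ruleset_round_trips(self, tmp_path):
        rs = RuleSet([], ["f0"], ["A"], fallback_class="A")
        write_ruleset(rs, tmp_path / "empty.json")
        back = read_ruleset(tmp_path / "empty.json")
        assert len(back) == 0 and back.fallback_class == "A"

    def test_unknown_direction_token_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"feature_names": ["f0"], "class_labels": ["A"], '
                        '"fallback_class": "A", "rules": [{"conditions": '
                        '[{"feature": 0, "direction": "lt", "threshold": 1.0}], '
                        '"outcome": "A", "tree": 0, "leaf": 0, "cc": 0, "ic": 0, '
                        '"score": null}]}')
        with pytest.raises(RuleSetSchemaError, match="direction"):
            read_ruleset(path)
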
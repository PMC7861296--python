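import numpy as np
import pytest

from forestrules import Condition, Direction, Rule, RuleSet
from forestrules.fixtures import ArrayTree, example_tree, make_tabular


def random_rule(rng: np.random.Generator, n_features: int = 10,
                max_conditions: int = 6, outcomes=("A", "B")) -> Rule:
    n_cond = int(rng.integers(0, max_conditions + 1))
    conditions = [
        Condition(int(rng.integers(0, n_features)),
                  Direction.LE if rng.random() < 0.5 else Direction.GT,
                  float(np.round(rng.normal(), 3)))
        for _ in range(n_cond)
    ]
    return Rule(conditions, outcomes[int(rng.integers(0, len(outcomes)))],
                cc=int(rng.integers(0, 20)), ic=int(rng.integers(0, 20)))


def random_ruleset(rng: np.random.Generator, n_rules: int = 20,
                   n_features: int = 10) -> RuleSet:
    rules = [random_rule(rng, n_features) for _ in range(n_rules)]
    return RuleSet(rules, [f"feature{i}" for i in range(n_features)], ["A", "B"],
                   fallback_class="A")


def make_stump(feature: int, threshold: float, left_class, right_class,
               classes=(0, 1)) -> ArrayTree:
    """Single-split tree: left (``<= threshold``) predicts ``left_class``."""
    classes = list(classes)
    value = np.zeros((3, len(classes)))
    value[1, classes.index(left_class)] = 1
    value[2, classes.index(right_class)] = 1
    return ArrayTree(np.array([1, -1, -1]), np.array([2, -1, -1]),
                     np.array([feature, -2, -2]),
                     np.array([threshold, -2.0, -2.0]), value,
                     np.asarray(classes, dtype=object))


@pytest.fixture(scope="session")
def figure_tree():
    return example_tree()


@pytest.fixture(scope="session")
def strong_data():
    """Well-separated two-class table (3 informative of 22 features)."""
    return make_tabular(n_samples=300, class_sep=3.0, seed=11)


@pytest.fixture(scope="session")
def small_forest(strong_data):
    """A small fitted forest plus its training data."""
    from sklearn.ensemble import RandomForestClassifier

    X, y, _ = strong_data
    Xv = X.to_numpy(dtype=float)
    forest = RandomForestClassifier(n_estimators=10, random_state=0, n_jobs=1)
    forest.fit(Xv, y)
    return forest, Xv, y
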
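"""Rule domain model: conditions, rules, rule sets, and extraction from tree ensembles.

A trained random forest is turned into an explicit, auditable rule set:
every root-to-leaf branch of every tree becomes one rule, a conjunction of
threshold tests on single features implying a class label.  The rule set is
the inspectable core of the decision-support workflow — it can be rendered
as logical statements, simplified, scored, reduced and serialized to JSON.

Boundary semantics are fixed package-wide: the *left* child of a split node
holds samples with ``feature <= threshold``, the right child those with
``feature > threshold``.  This matches scikit-learn's decision trees, so an
extracted rule set reproduces the originating forest's per-tree votes
exactly.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Direction",
    "Condition",
    "Rule",
    "RuleSet",
    "UnsupportedModelError",
    "RuleSetSchemaError",
    "extract_rules",
    "rule_to_dnf",
    "parse_dnf",
    "simplify_rule",
    "simplify_ruleset",
    "read_ruleset",
    "write_ruleset",
]

AND = "∧"      # logical conjunction symbol
IMPLIES = "⇒"  # implication arrow used when rendering rules


class UnsupportedModelError(TypeError):
    """The supplied model is not a fitted binary-threshold tree ensemble."""


class RuleSetSchemaError(ValueError):
    """A serialized rule set violates the JSON schema."""


class Direction(str, Enum):
    """Side of a threshold test: ``LE`` is the left branch, ``GT`` the right."""

    LE = "le"
    GT = "gt"

    @property
    def symbol(self) -> str:
        return "<=" if self is Direction.LE else ">"


@dataclass(frozen=True)
class Condition:
    """One threshold test on one feature.

    Parameters
    ----------
    feature:
        Column index of the tested feature (canonical identifier; display
        names live on the :class:`RuleSet`).
    direction:
        :attr:`Direction.LE` for ``x[feature] <= threshold`` (left branch),
        :attr:`Direction.GT` for ``x[feature] > threshold`` (right branch).
    threshold:
        Split value in feature units; must be finite.
    """

    feature: int
    direction: Direction
    threshold: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold):
            raise ValueError(f"non-finite threshold {self.threshold!r} on feature {self.feature}")

    def matches(self, value: float) -> bool:
        if self.direction is Direction.LE:
            return value <= self.threshold
        return value > self.threshold


@dataclass
class Rule:
    """A conjunction of conditions implying a class label.

    ``cc``/``ic`` are the counts of covered training samples the rule
    classifies correctly/incorrectly; they are filled by the scoring module.
    ``rl`` (rule length) is always the current number of conditions.
    """

    conditions: list[Condition]
    outcome: object
    tree: int = -1
    leaf: int = -1
    cc: int = 0
    ic: int = 0
    score: float | None = None
    infeasible: bool = False
    zero_coverage: bool = False

    @property
    def rl(self) -> int:
        return len(self.conditions)

    @property
    def features(self) -> set[int]:
        """Set of feature indices the rule tests."""
        return {c.feature for c in self.conditions}

    def matches(self, sample: Sequence[float]) -> bool:
        """Whether ``sample`` satisfies every condition (vacuously true if none)."""
        if self.infeasible:
            return False
        return all(c.matches(sample[c.feature]) for c in self.conditions)

    def matches_matrix(self, X: np.ndarray) -> np.ndarray:
        """Boolean match mask over the rows of a 2-D feature matrix."""
        X = np.asarray(X, dtype=float)
        if self.infeasible:
            return np.zeros(X.shape[0], dtype=bool)
        mask = np.ones(X.shape[0], dtype=bool)
        for c in self.conditions:
            col = X[:, c.feature]
            mask &= (col <= c.threshold) if c.direction is Direction.LE else (col > c.threshold)
        return mask


@dataclass
class RuleSet:
    """An ordered collection of rules over a shared feature/class universe."""

    rules: list[Rule]
    feature_names: list[str]
    class_labels: list[object]
    fallback_class: object = None

    def __post_init__(self) -> None:
        universe = set(self.class_labels)
        for r in self.rules:
            if r.outcome not in universe:
                raise ValueError(f"rule outcome {r.outcome!r} not in class universe {universe}")
            for c in r.conditions:
                if not 0 <= c.feature < len(self.feature_names):
                    raise ValueError(f"feature index {c.feature} outside universe of "
                                     f"{len(self.feature_names)} features")

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)

    @property
    def scored(self) -> bool:
        return all(r.score is not None for r in self.rules)

    def replace_rules(self, rules: Iterable[Rule]) -> "RuleSet":
        """A new rule set with the same universe but different rules."""
        return RuleSet(list(rules), list(self.feature_names), list(self.class_labels),
                       self.fallback_class)


# ---------------------------------------------------------------------------
# Extraction from tree ensembles
# ---------------------------------------------------------------------------

def _tree_arrays(tree):
    """Return (children_left, children_right, feature, threshold, value, classes).

    Accepts a fitted scikit-learn estimator (``.tree_`` + ``.classes_``) or
    any object exposing the same flat-array representation directly.
    """
    src = getattr(tree, "tree_", tree)
    try:
        arrays = (np.asarray(src.children_left), np.asarray(src.children_right),
                  np.asarray(src.feature), np.asarray(src.threshold, dtype=float),
                  np.asarray(src.value))
    except AttributeError as exc:
        raise UnsupportedModelError(
            "model does not expose a binary threshold-split tree structure "
            "(expected children_left/children_right/feature/threshold/value arrays); "
            "is the forest fitted?") from exc
    classes = np.asarray(getattr(tree, "classes_", np.arange(arrays[4].shape[-1])))
    return (*arrays, classes)


def _leaf_outcome(value_row: np.ndarray, classes: np.ndarray):
    # argmax breaks ties toward the lowest class index — deterministic
    counts = np.asarray(value_row, dtype=float).ravel()
    label = classes[int(np.argmax(counts))]
    return label.item() if hasattr(label, "item") else label  # plain python for JSON


def _extract_tree(tree, tree_index: int) -> list[Rule]:
    left, right, feat, thresh, value, classes = _tree_arrays(tree)
    rules: list[Rule] = []

    def walk(node: int, conditions: list[Condition]) -> None:
        if left[node] == -1 and right[node] == -1:  # leaf
            rules.append(Rule(list(conditions), _leaf_outcome(value[node], classes),
                              tree=tree_index, leaf=node))
            return
        f = int(feat[node])
        if f < 0:
            raise UnsupportedModelError(f"node {node} is an internal node without a "
                                        "single-feature threshold split")
        t = float(thresh[node])
        conditions.append(Condition(f, Direction.LE, t))
        walk(int(left[node]), conditions)
        conditions.pop()
        conditions.append(Condition(f, Direction.GT, t))
        walk(int(right[node]), conditions)
        conditions.pop()

    walk(0, [])
    return rules


def extract_rules(forest, feature_names: Sequence[str] | None = None,
                  class_labels: Sequence[object] | None = None,
                  fallback_class: object = None) -> RuleSet:
    """Extract one rule per leaf per tree of a fitted ensemble.

    Each rule's conditions are the threshold tests along the root-to-leaf
    path in root-first order; its outcome is the leaf's majority class.
    The total rule count equals the total leaf count, and for any sample
    exactly one rule per tree matches — the per-tree rules partition
    feature space, so the rule set reproduces the forest's votes.

    Parameters
    ----------
    forest:
        A fitted ``RandomForestClassifier``-like object (anything with
        ``estimators_``), a single fitted decision tree, or a sequence of
        tree-structure objects.
    feature_names, class_labels:
        Display universes; defaulted from the model when omitted.
    fallback_class:
        Class used by inference when no rule matches (typically the
        training-set majority class).
    """
    if hasattr(forest, "estimators_"):
        trees = list(forest.estimators_)
    elif isinstance(forest, (list, tuple)):
        trees = list(forest)
    else:
        trees = [forest]
    if not trees:
        raise UnsupportedModelError("empty ensemble")

    rules: list[Rule] = []
    for i, tree in enumerate(trees):
        rules.extend(_extract_tree(tree, i))

    if class_labels is None:
        classes = getattr(forest, "classes_", None)
        if classes is None:
            classes = _tree_arrays(trees[0])[5]
        class_labels = list(np.asarray(classes).tolist())
    if feature_names is None:
        n_feat = getattr(forest, "n_features_in_", None)
        if n_feat is None:
            n_feat = max((c.feature for r in rules for c in r.conditions), default=-1) + 1
        feature_names = [f"feature{i}" for i in range(int(n_feat))]
    return RuleSet(rules, list(feature_names), list(class_labels), fallback_class)


# ---------------------------------------------------------------------------
# DNF rendering and parsing
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    """Shortest decimal string that round-trips to the same float."""
    return repr(float(x))


def rule_to_dnf(rule: Rule, feature_names: Sequence[str] | None = None) -> str:
    """Render a rule as a conjunctive clause, e.g.

    ``(feature18<=-6.421 ∧ feature10<=0.008 ∧ feature6<=0.002) ⇒ healthy``

    An empty conjunction renders as ``TRUE`` (it matches every sample).
    """
    def name(i: int) -> str:
        return feature_names[i] if feature_names is not None else f"feature{i}"

    if not rule.conditions:
        body = "TRUE"
    else:
        body = "(" + f" {AND} ".join(
            f"{name(c.feature)}{c.direction.symbol}{_fmt(c.threshold)}"
            for c in rule.conditions) + ")"
    return f"{body} {IMPLIES} {rule.outcome}"


_COND_RE = re.compile(r"^\s*(?P<name>.*?)\s*(?P<op><=|>)\s*(?P<thr>[-+0-9.eE]+)\s*$")


def parse_dnf(text: str, feature_names: Sequence[str] | None = None) -> Rule:
    """Inverse of :func:`rule_to_dnf`; feature names resolve to indices via
    ``feature_names`` or the ``feature<i>`` pattern."""
    if IMPLIES not in text:
        raise ValueError(f"not a rule clause (missing {IMPLIES!r}): {text!r}")
    body, outcome = text.rsplit(IMPLIES, 1)
    body, outcome = body.strip(), outcome.strip()
    conditions: list[Condition] = []
    if body != "TRUE":
        body = body.strip()
        if body.startswith("(") and body.endswith(")"):
            body = body[1:-1]
        for part in body.split(AND):
            m = _COND_RE.match(part)
            if m is None:
                raise ValueError(f"cannot parse condition {part!r}")
            name = m.group("name").strip()
            if feature_names is not None and name in feature_names:
                idx = list(feature_names).index(name)
            else:
                fm = re.fullmatch(r"feature(\d+)", name)
                if fm is None:
                    raise ValueError(f"unknown feature name {name!r}")
                idx = int(fm.group(1))
            conditions.append(Condition(idx, Direction.LE if m.group("op") == "<=" else Direction.GT,
                                        float(m.group("thr"))))
    return Rule(conditions, outcome)


# ---------------------------------------------------------------------------
# Within-rule simplification
# ---------------------------------------------------------------------------

def simplify_rule(rule: Rule) -> Rule:
    """Drop redundant conditions within one rule.

    For each feature, all ``>`` tests collapse to the single largest
    threshold and all ``<=`` tests to the single smallest — the tightest
    bounds imply the rest, so the simplified rule matches exactly the same
    points.  The original order of the surviving conditions is preserved.

    A rule whose tightest bounds contradict each other (upper bound at or
    below lower bound, possible only for hand-edited rules — a tree path
    never contradicts itself) is returned with ``infeasible=True`` rather
    than silently dropped: auditability requires that nothing vanish.
    """
    lower: dict[int, float] = {}  # feature -> largest GT threshold
    upper: dict[int, float] = {}  # feature -> smallest LE threshold
    for c in rule.conditions:
        if c.direction is Direction.GT:
            if c.feature not in lower or c.threshold > lower[c.feature]:
                lower[c.feature] = c.threshold
        else:
            if c.feature not in upper or c.threshold < upper[c.feature]:
                upper[c.feature] = c.threshold

    kept: list[Condition] = []
    seen: set[tuple[int, Direction]] = set()
    for c in rule.conditions:
        key = (c.feature, c.direction)
        bound = lower[c.feature] if c.direction is Direction.GT else upper[c.feature]
        if c.threshold == bound and key not in seen:
            kept.append(c)
            seen.add(key)

    infeasible = any(f in upper and upper[f] <= lower[f] for f in lower)
    return replace(rule, conditions=kept, infeasible=infeasible)


def simplify_ruleset(ruleset: RuleSet) -> RuleSet:
    """Apply :func:`simplify_rule` to every rule; the rule count is unchanged."""
    return ruleset.replace_rules(simplify_rule(r) for r in ruleset.rules)


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

def _rule_to_json(rule: Rule) -> dict:
    d = {
        "conditions": [{"feature": c.feature, "direction": c.direction.value,
                        "threshold": c.threshold} for c in rule.conditions],
        "outcome": rule.outcome,
        "tree": rule.tree,
        "leaf": rule.leaf,
        "cc": rule.cc,
        "ic": rule.ic,
        "score": rule.score,
    }
    if rule.infeasible:
        d["infeasible"] = True
    return d


def _rule_from_json(d: dict) -> Rule:
    try:
        conditions = []
        for c in d["conditions"]:
            try:
                direction = Direction(c["direction"])
            except ValueError:
                raise RuleSetSchemaError(
                    f"unknown direction token {c['direction']!r} (expected 'le' or 'gt')")
            conditions.append(Condition(int(c["feature"]), direction, float(c["threshold"])))
        score = d.get("score")
        return Rule(conditions, d["outcome"], tree=int(d.get("tree", -1)),
                    leaf=int(d.get("leaf", -1)), cc=int(d.get("cc", 0)),
                    ic=int(d.get("ic", 0)), score=None if score is None else float(score),
                    infeasible=bool(d.get("infeasible", False)))
    except KeyError as exc:
        raise RuleSetSchemaError(f"rule object missing required field {exc.args[0]!r}") from exc
    except (TypeError, ValueError) as exc:
        if isinstance(exc, RuleSetSchemaError):
            raise
        raise RuleSetSchemaError(f"malformed rule object: {exc}") from exc


def write_ruleset(ruleset: RuleSet, path) -> None:
    """Serialize a rule set to JSON (lossless round trip with :func:`read_ruleset`)."""
    doc = {
        "feature_names": list(ruleset.feature_names),
        "class_labels": list(ruleset.class_labels),
        "fallback_class": ruleset.fallback_class,
        "rules": [_rule_to_json(r) for r in ruleset.rules],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_ruleset(path) -> RuleSet:
    with open(path) as fh:
        doc = json.load(fh)
    for field_name in ("feature_names", "class_labels", "rules"):
        if field_name not in doc:
            raise RuleSetSchemaError(f"rule-set document missing required field {field_name!r}")
    return RuleSet([_rule_from_json(r) for r in doc["rules"]],
                   list(doc["feature_names"]), list(doc["class_labels"]),
                   doc.get("fallback_class"))
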
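"""Classification from rule sets, evaluation metrics, and the
cross-validation harness.

A reduced rule set replaces the forest at prediction time: every rule that
matches a sample casts one vote for its outcome, the majority class wins,
and a sample no rule matches falls back to the stored training-majority
class.  How matching rules are aggregated genuinely matters once rules have
been pruned, so the vote scheme is configuration, not doctrine:

``majority``
    one vote per matching rule (default — closest to the forest's own
    one-tree-one-vote semantics); ties break toward the larger summed rule
    score, then the lowest class index.
``score_weighted``
    each matching rule votes with weight equal to its score.
``best_rule``
    the single highest-scoring matching rule decides alone.

The harness runs the full train → extract → simplify → score → reduce →
evaluate pipeline per fold, with k-fold or leave-one-subject-out (LOSO)
splitting; imputation statistics are fit on the training fold only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold, LeaveOneGroupOut

from .imputation import Imputer
from .reduction import reduce_topk
from .rule_model import RuleSet, extract_rules, simplify_ruleset
from .scoring import PreferenceProfile, score_ruleset

__all__ = [
    "VOTE_SCHEMES",
    "EvaluationReport",
    "PipelineConfig",
    "FittedPipeline",
    "predict",
    "predict_all",
    "evaluate",
    "fit_pipeline",
    "cross_validate",
    "ruleset_size_sweep",
]

VOTE_SCHEMES = ("majority", "score_weighted", "best_rule")


@dataclass(frozen=True)
class EvaluationReport:
    """Classification metrics of a rule set on one data set.

    ``sensitivity``/``specificity`` are one-vs-rest for ``positive_class``
    and are ``None`` (undefined, not zero) when the data contain no
    positive / no negative samples.  ``coverage`` is the fraction of
    samples matched by at least one rule.
    """

    accuracy: float
    sensitivity: float | None
    specificity: float | None
    coverage: float
    n_samples: int
    positive_class: object

    def __post_init__(self):
        for name in ("accuracy", "sensitivity", "specificity", "coverage"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")


def _vote_matrix(ruleset: RuleSet, X: np.ndarray, vote: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample class vote tallies and score sums.

    Returns ``(votes, score_sums)``, each shaped (n_samples, n_classes);
    ``votes`` holds the aggregation weight per class under the chosen
    scheme, ``score_sums`` the summed scores of matching rules (tie-break
    information for the majority scheme).
    """
    n = X.shape[0]
    classes = list(ruleset.class_labels)
    votes = np.zeros((n, len(classes)))
    score_sums = np.zeros((n, len(classes)))
    best_score = np.full(n, -np.inf)
    best_class = np.full(n, -1)

    for rule in ruleset.rules:
        if rule.infeasible:
            continue
        mask = rule.matches_matrix(X)
        if not mask.any():
            continue
        ci = classes.index(rule.outcome)
        s = rule.score if rule.score is not None else 0.0
        score_sums[mask, ci] += s
        if vote == "majority":
            votes[mask, ci] += 1.0
        elif vote == "score_weighted":
            votes[mask, ci] += s
        else:  # best_rule
            better = mask & (s > best_score)
            best_score[better] = s
            best_class[better] = ci

    if vote == "best_rule":
        matched = best_class >= 0
        votes[matched, best_class[matched]] = 1.0
    return votes, score_sums


def predict_all(ruleset: RuleSet, features, vote: str = "majority") -> np.ndarray:
    """Predict a class label for every row of a feature matrix."""
    if vote not in VOTE_SCHEMES:
        raise ValueError(f"unknown vote scheme {vote!r}; choose from {VOTE_SCHEMES}")
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"expected a 2-D feature matrix, got shape {X.shape}")
    if np.isnan(X).any():
        raise ValueError("feature matrix contains missing values; impute them first "
                         "(forestrules.imputation.impute)")
    if vote != "majority" and not ruleset.scored:
        raise ValueError(f"vote scheme {vote!r} needs scored rules; run score_ruleset first")

    votes, score_sums = _vote_matrix(ruleset, X, vote)
    classes = np.array(ruleset.class_labels, dtype=object)
    n = X.shape[0]

    # winner per sample: max votes, ties -> larger summed score -> lowest class index
    out = np.empty(n, dtype=object)
    top = votes.max(axis=1)
    for i in range(n):
        if top[i] <= 0:
            out[i] = ruleset.fallback_class
            continue
        tied = np.flatnonzero(votes[i] == top[i])
        if len(tied) > 1:
            tied = tied[score_sums[i, tied] == score_sums[i, tied].max()]
        out[i] = classes[tied[0]]
    return out


def predict(ruleset: RuleSet, sample, vote: str = "majority"):
    """Classify a single sample (1-D feature vector)."""
    return predict_all(ruleset, np.atleast_2d(np.asarray(sample, dtype=float)), vote)[0]


def coverage(ruleset: RuleSet, features) -> float:
    """Fraction of samples matched by at least one (feasible) rule."""
    X = np.asarray(features, dtype=float)
    if X.shape[0] == 0:
        return 0.0
    matched = np.zeros(X.shape[0], dtype=bool)
    for rule in ruleset.rules:
        matched |= rule.matches_matrix(X)
        if matched.all():
            break
    return float(matched.mean())


def evaluate(ruleset: RuleSet, features, labels, positive_class,
             vote: str = "majority") -> EvaluationReport:
    """Accuracy, one-vs-rest sensitivity/specificity and coverage of a rule
    set on labelled data."""
    if positive_class not in ruleset.class_labels:
        raise ValueError(f"positive_class {positive_class!r} not in class universe "
                         f"{ruleset.class_labels}")
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    pred = predict_all(ruleset, X, vote)

    correct = pred == y
    pos = y == positive_class
    pred_pos = pred == positive_class
    tp = int((pos & pred_pos).sum())
    fn = int((pos & ~pred_pos).sum())
    tn = int((~pos & ~pred_pos).sum())
    fp = int((~pos & pred_pos).sum())

    return EvaluationReport(
        accuracy=float(correct.mean()) if len(y) else 0.0,
        sensitivity=tp / (tp + fn) if tp + fn > 0 else None,
        specificity=tn / (tn + fp) if tn + fp > 0 else None,
        coverage=coverage(ruleset, X),
        n_samples=int(len(y)),
        positive_class=positive_class,
    )


# ---------------------------------------------------------------------------
# Pipeline: train forest -> extract -> simplify -> score -> reduce
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the end-to-end workflow in one declarative object.

    Forest hyperparameters mirror the classifier's: number of trees, split
    quality criterion (``gini``/``entropy``), the number of features
    considered per split, and the maximum tree depth.  ``keep_fraction``
    drives the reduction step (1.0 = keep everything); ``profile`` carries
    the user's feature preferences into the personalisable score.
    """

    n_trees: int = 100
    criterion: str = "gini"
    max_features: object = "sqrt"
    max_depth: int | None = None
    score_variant: str = "personalised"
    profile: PreferenceProfile = field(default_factory=PreferenceProfile)
    keep_fraction: float = 1.0
    vote: str = "majority"
    impute_strategy: str = "mean"
    test_fraction: float = 0.3
    positive_class: object = None

    def to_dict(self) -> dict:
        return {
            "n_trees": self.n_trees, "criterion": self.criterion,
            "max_features": self.max_features, "max_depth": self.max_depth,
            "score_variant": self.score_variant,
            "profile": {"favorites": list(self.profile.favorites),
                        "cautions": list(self.profile.cautions),
                        "x": self.profile.x, "k": self.profile.k},
            "keep_fraction": self.keep_fraction, "vote": self.vote,
            "impute_strategy": self.impute_strategy,
            "test_fraction": self.test_fraction,
            "positive_class": self.positive_class,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        prof = d.pop("profile", None)
        profile = PreferenceProfile(**prof) if prof else PreferenceProfile()
        return cls(profile=profile, **d)


@dataclass
class FittedPipeline:
    """Artifacts of one pipeline fit on one training set."""

    forest: RandomForestClassifier
    imputer: Imputer
    full_ruleset: RuleSet      # simplified + scored, before reduction
    ruleset: RuleSet           # after reduction
    config: PipelineConfig

    def evaluate(self, features, labels, positive_class=None) -> EvaluationReport:
        X = self.imputer.transform(_as_2d(features))
        pos = positive_class if positive_class is not None else _default_positive(
            self.ruleset.class_labels, self.config.positive_class)
        return evaluate(self.ruleset, X, labels, pos, self.config.vote)


def _as_2d(features) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float)
    return np.asarray(features, dtype=float)


def _default_positive(class_labels, configured):
    if configured is not None:
        return configured
    return class_labels[-1]  # conventional: last label is the case/disease class


def fit_pipeline(config: PipelineConfig, features, labels, seed: int,
                 feature_names: Sequence[str] | None = None) -> FittedPipeline:
    """Train a forest and distill it into a scored, reduced rule set."""
    if feature_names is None and isinstance(features, pd.DataFrame):
        feature_names = [str(c) for c in features.columns]
    X = _as_2d(features)
    y = np.asarray(labels)

    imputer = Imputer(config.impute_strategy)
    X = imputer.fit_transform(X)

    forest = RandomForestClassifier(
        n_estimators=config.n_trees, criterion=config.criterion,
        max_features=config.max_features, max_depth=config.max_depth,
        random_state=seed, n_jobs=1)
    forest.fit(X, y)

    classes, counts = np.unique(y, return_counts=True)
    fallback = classes[np.argmax(counts)]
    fallback = fallback.item() if hasattr(fallback, "item") else fallback

    ruleset = extract_rules(forest, feature_names=feature_names, fallback_class=fallback)
    ruleset = simplify_ruleset(ruleset)
    ruleset = score_ruleset(ruleset, X, y, config.profile, config.score_variant)
    reduced = (reduce_topk(ruleset, keep_fraction=config.keep_fraction)
               if config.keep_fraction < 1.0 else ruleset)
    return FittedPipeline(forest, imputer, ruleset, reduced, config)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def _fold_indices(scheme: str, y: np.ndarray, k: int, subject_ids, seed: int):
    n = len(y)
    if scheme == "kfold":
        if not 2 <= k <= n:
            raise ValueError(f"k must be in [2, {n}], got {k}")
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        yield from splitter.split(np.zeros(n))
    elif scheme == "loso":
        if subject_ids is None:
            raise ValueError("leave-one-subject-out needs subject_ids")
        splitter = LeaveOneGroupOut()
        yield from splitter.split(np.zeros(n), groups=np.asarray(subject_ids))
    else:
        raise ValueError(f"unknown scheme {scheme!r}; choose 'kfold' or 'loso'")


def _mean_report(reports: list[EvaluationReport]) -> EvaluationReport:
    def mean_of(attr):
        vals = [getattr(r, attr) for r in reports if getattr(r, attr) is not None]
        return float(np.mean(vals)) if vals else None

    return EvaluationReport(
        accuracy=mean_of("accuracy"), sensitivity=mean_of("sensitivity"),
        specificity=mean_of("specificity"), coverage=mean_of("coverage"),
        n_samples=sum(r.n_samples for r in reports),
        positive_class=reports[0].positive_class)


def cross_validate(config: PipelineConfig, features, labels, scheme: str = "kfold",
                   k: int = 10, subject_ids=None, seed: int = 0,
                   ) -> tuple[list[EvaluationReport], EvaluationReport]:
    """Run the full pipeline per fold and report per-fold plus mean metrics.

    ``scheme='kfold'`` shuffles then splits into ``k`` folds;
    ``scheme='loso'`` makes one fold per subject so no subject contributes
    to both training and testing of any fold.
    """
    X = _as_2d(features)
    y = np.asarray(labels)
    names = [str(c) for c in features.columns] if isinstance(features, pd.DataFrame) else None
    pos = _default_positive(sorted(np.unique(y).tolist()), config.positive_class)

    reports = []
    for fold, (train, test) in enumerate(_fold_indices(scheme, y, k, subject_ids, seed)):
        fitted = fit_pipeline(config, X[train], y[train], seed=seed + fold,
                              feature_names=names)
        Xt = fitted.imputer.transform(X[test])
        reports.append(evaluate(fitted.ruleset, Xt, y[test], pos, config.vote))
    return reports, _mean_report(reports)


def ruleset_size_sweep(config: PipelineConfig, features, labels,
                       fractions: Sequence[float],
                       profiles: dict[str, PreferenceProfile | None],
                       seed: int = 0, k: int = 10) -> pd.DataFrame:
    """Accuracy as a function of reduced-rule-set size, per preference profile.

    For every cross-validation fold the forest is trained once; each
    profile re-scores the extracted rules, and each fraction keeps the
    corresponding top slice before evaluation.  Returns one row per
    (fraction, profile) with the mean and standard deviation of fold
    accuracies — the experiment behind size-vs-accuracy curves.
    """
    X = _as_2d(features)
    y = np.asarray(labels)
    names = [str(c) for c in features.columns] if isinstance(features, pd.DataFrame) else None
    pos = _default_positive(sorted(np.unique(y).tolist()), config.positive_class)

    acc: dict[tuple[float, str], list[float]] = {
        (f, p): [] for f in fractions for p in profiles}
    for fold, (train, test) in enumerate(_fold_indices("kfold", y, k, None, seed)):
        base = replace(config, keep_fraction=1.0)
        fitted = fit_pipeline(base, X[train], y[train], seed=seed + fold, feature_names=names)
        Xt = fitted.imputer.transform(X[test])
        Xtr = fitted.imputer.transform(X[train])
        for pname, profile in profiles.items():
            scored = score_ruleset(fitted.full_ruleset, Xtr, y[train],
                                   profile or PreferenceProfile(), config.score_variant)
            for frac in fractions:
                reduced = reduce_topk(scored, keep_fraction=frac)
                rep = evaluate(reduced, Xt, y[test], pos, config.vote)
                acc[(frac, pname)].append(rep.accuracy)

    rows = [{"fraction": f, "profile": p,
             "mean_accuracy": float(np.mean(v)), "std_accuracy": float(np.std(v))}
            for (f, p), v in acc.items()]
    return pd.DataFrame(rows)
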
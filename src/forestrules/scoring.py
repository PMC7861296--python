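"""Rule scores: coverage counting, the two classical scores, and the
personalisable score with favorite-feature bonuses and caution penalties.

The base score (``score1``) rewards rules that cover many training samples
correctly and few incorrectly::

    score1 = (cc - ic) / (cc + ic) + cc / (ic + k)

where ``cc``/``ic`` count covered training samples classified
correctly/incorrectly and ``k > 0`` damps the second term (default 4).
``score2 = score1 + cc/rl`` additionally favors shorter rules (``rl`` =
rule length), since short rules are the more transparent ones.

The personalisable score lets a user rank *favorite* features and flag
*caution* features.  A rule containing the favorite of rank ``i`` (0 =
most preferred) earns a bonus of ``x / (i + 2)``; a contained caution
feature of rank ``i`` costs the same amount.  With the default ``x = 40``
the top favorite is worth +20 score points.  ``x`` scales how strongly
preferences steer rule retention; a bonus of about one third of the
maximum unpersonalised score keeps preferences influential without
overruling the forest's own assessment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .rule_model import Rule, RuleSet

__all__ = [
    "PreferenceProfile",
    "count_cc_ic",
    "score1",
    "score2",
    "score_pers",
    "score_ruleset",
]

DEFAULT_K = 4.0
DEFAULT_X = 40.0

SCORE_VARIANTS = ("score1", "score2", "personalised")


@dataclass(frozen=True)
class PreferenceProfile:
    """User preferences steering rule retention.

    ``favorites`` is ordered: index 0 is the most preferred feature.
    ``cautions`` lists features to down-weight, ranked the same way.
    The two lists are disjoint and duplicate-free.
    """

    favorites: tuple[int, ...] = ()
    cautions: tuple[int, ...] = ()
    x: float = DEFAULT_X
    k: float = DEFAULT_K

    def __init__(self, favorites: Sequence[int] = (), cautions: Sequence[int] = (),
                 x: float = DEFAULT_X, k: float = DEFAULT_K):
        object.__setattr__(self, "favorites", tuple(favorites))
        object.__setattr__(self, "cautions", tuple(cautions))
        object.__setattr__(self, "x", float(x))
        object.__setattr__(self, "k", float(k))
        if self.x <= 0:
            raise ValueError(f"x must be positive, got {self.x}")
        if self.k <= 0:
            raise ValueError(f"k must be positive, got {self.k}")
        if len(set(self.favorites)) != len(self.favorites):
            raise ValueError("duplicate features in favorites")
        if len(set(self.cautions)) != len(self.cautions):
            raise ValueError("duplicate features in cautions")
        overlap = set(self.favorites) & set(self.cautions)
        if overlap:
            raise ValueError(f"features {sorted(overlap)} are both favorite and caution")

    @property
    def empty(self) -> bool:
        return not self.favorites and not self.cautions


def count_cc_ic(rule: Rule, features: np.ndarray, labels: Sequence) -> tuple[int, int]:
    """Count covered training samples classified correctly (``cc``) and
    incorrectly (``ic``).  Samples the rule does not match count toward
    neither."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.shape[0] == 0:
        return 0, 0
    n_feat = X.shape[1]
    for c in rule.conditions:
        if not 0 <= c.feature < n_feat:
            raise IndexError(f"rule tests feature {c.feature} but the matrix has "
                             f"{n_feat} columns")
    mask = rule.matches_matrix(X)
    correct = mask & (y == rule.outcome)
    return int(correct.sum()), int(mask.sum() - correct.sum())


def score1(cc: float, ic: float, k: float = DEFAULT_K) -> float:
    """Coverage-accuracy score ``(cc-ic)/(cc+ic) + cc/(ic+k)``.

    A rule that covers nothing (``cc + ic == 0``) has an undefined first
    term; it is defined as 0 here so dead rules score low but remain
    comparable (and prunable) instead of raising.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    covered = cc + ic
    first = (cc - ic) / covered if covered > 0 else 0.0
    return first + cc / (ic + k)


def score2(cc: float, ic: float, k: float = DEFAULT_K, rl: int = 1) -> float:
    """``score1 + cc/rl`` — identical coverage behavior, but shorter rules
    (smaller ``rl``) score higher.  An empty-condition rule is treated as
    length 1: a root-only tree is one maximally short rule."""
    if rl < 0:
        raise ValueError(f"rule length must be >= 0, got {rl}")
    if rl == 0:  # empty-condition rule
        rl = 1
    return score1(cc, ic, k) + cc / rl


def _preference_addend(rule_features: set[int], ranked: Sequence[int], x: float) -> float:
    # membership, not occurrence count: a feature tested twice in one rule
    # earns its bonus once (scoring runs after within-rule simplification,
    # where duplicates have already collapsed)
    return sum(x / (i + 2) for i, f in enumerate(ranked) if f in rule_features)


def score_pers(rule: Rule, cc: float, ic: float, profile: PreferenceProfile) -> float:
    """Personalisable score: ``score2`` plus ``x/(i+2)`` per contained
    favorite of rank ``i``, minus the same per contained caution feature.

    A rule containing no listed feature scores exactly ``score2``.
    """
    base = score2(cc, ic, profile.k, rule.rl)
    feats = rule.features
    return (base
            + _preference_addend(feats, profile.favorites, profile.x)
            - _preference_addend(feats, profile.cautions, profile.x))


def score_ruleset(ruleset: RuleSet, features: np.ndarray, labels: Sequence,
                  profile: PreferenceProfile | None = None,
                  variant: str = "personalised") -> RuleSet:
    """Fill ``cc``, ``ic`` and ``score`` for every rule (returns a new set).

    ``variant`` selects ``score1``, ``score2`` or ``personalised``; the
    personalised variant with an empty profile reduces exactly to
    ``score2``.  Rules covering no training sample are flagged
    ``zero_coverage`` so reduction can rank them below covering rules of
    equal score.
    """
    if variant not in SCORE_VARIANTS:
        raise ValueError(f"unknown score variant {variant!r}; choose from {SCORE_VARIANTS}")
    if profile is None:
        profile = PreferenceProfile()
    scored = []
    for rule in ruleset.rules:
        cc, ic = count_cc_ic(rule, features, labels)
        if variant == "score1":
            s = score1(cc, ic, profile.k)
        elif variant == "score2":
            s = score2(cc, ic, profile.k, rule.rl)
        else:
            s = score_pers(rule, cc, ic, profile)
        scored.append(replace(rule, cc=cc, ic=ic, score=s, zero_coverage=(cc + ic == 0)))
    return ruleset.replace_rules(scored)
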
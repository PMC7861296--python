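"""Rule-set reduction: deterministic top-k pruning and score-proportional
stochastic sampling.

Reducing a scored rule set to a fraction of its size (say 10%) is the step
that turns an unwieldy forest transcript into an inspectable decision aid;
on well-separated data it costs little accuracy.  Two strategies:

* :func:`reduce_topk` drops the weakest rules outright — keep a fraction or
  drop a fixed count.
* :func:`reduce_stochastic` samples rules without replacement with
  probability proportional to their (shifted-positive) score, the selection
  scheme of the classic hill-climbing rule extractor.
"""

from __future__ import annotations

import math

import numpy as np

from .rule_model import RuleSet

__all__ = ["reduce_topk", "reduce_stochastic"]


def _require_scored(ruleset: RuleSet) -> None:
    if not ruleset.scored:
        raise ValueError("rule set is not fully scored; run score_ruleset first")


def _rank_order(ruleset: RuleSet) -> list[int]:
    """Rule indices from strongest to weakest.

    Ties on score break toward covering rules first, then shorter rules,
    then earlier extraction order — deterministic, and biased toward the
    transparent (short, actually-covering) rule.
    """
    return sorted(range(len(ruleset)),
                  key=lambda i: (-ruleset.rules[i].score,
                                 ruleset.rules[i].zero_coverage,
                                 ruleset.rules[i].rl,
                                 i))


def reduce_topk(ruleset: RuleSet, keep_fraction: float | None = None,
                drop_n: int | None = None) -> RuleSet:
    """Remove the lowest-scoring rules.

    Exactly one of ``keep_fraction`` (0 < f <= 1; kept count is
    ``ceil(f * n)``, so 10% of a tiny set is never empty) or ``drop_n``
    (0 <= drop_n < n) must be given.  Survivors keep their original
    relative order.
    """
    _require_scored(ruleset)
    n = len(ruleset)
    if (keep_fraction is None) == (drop_n is None):
        raise ValueError("give exactly one of keep_fraction or drop_n")
    if keep_fraction is not None:
        if not 0 < keep_fraction <= 1:
            raise ValueError(f"keep_fraction must be in (0, 1], got {keep_fraction}")
        n_keep = math.ceil(keep_fraction * n)
    else:
        if not 0 <= drop_n < n:
            raise ValueError(f"drop_n must be in [0, {n}), got {drop_n}")
        n_keep = n - drop_n
    kept = sorted(_rank_order(ruleset)[:n_keep])
    return ruleset.replace_rules(ruleset.rules[i] for i in kept)


def reduce_stochastic(ruleset: RuleSet, target_size: int, seed: int) -> RuleSet:
    """Sample ``target_size`` rules without replacement, selection
    probability proportional to score.

    Scores can be negative, so they are shifted by ``|min| + eps`` before
    normalisation; an all-equal (degenerate) score vector falls back to
    uniform sampling.  Identical seeds give identical selections.
    """
    _require_scored(ruleset)
    n = len(ruleset)
    if not 0 <= target_size <= n:
        raise ValueError(f"target_size must be in [0, {n}], got {target_size}")
    if target_size == n:
        return ruleset.replace_rules(list(ruleset.rules))
    scores = np.array([r.score for r in ruleset.rules], dtype=float)
    if np.ptp(scores) == 0:
        weights = np.ones(n)
    else:
        lo = scores.min()
        shift = (abs(lo) + 1e-9) if lo <= 0 else 0.0
        weights = scores + shift
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n, size=target_size, replace=False, p=weights / weights.sum())
    return ruleset.replace_rules(ruleset.rules[i] for i in sorted(chosen))
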
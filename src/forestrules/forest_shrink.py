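"""Forest shrinking: tree-importance measures and sub-forest selection.

A random forest often carries many near-duplicate trees.  Three measures
identify removable ones:

* **accuracy impact** ``delta = P_F - P_{F-T}`` — the change in
  majority-vote accuracy when tree ``T`` is dropped; the tree with the
  smallest impact goes first;
* **average similarity** ``rho_T`` — the mean correlation of ``T``'s
  prediction vector with every other tree's; the most redundant tree
  (largest ``rho``) goes first;
* **pairwise similarity** — find the most-correlated pair, drop its more
  redundant member, and update per-tree weights
  ``w_t += cor(T_rs, t) / (rho_{T_rs} * (N_F - 1))``.

Removing trees one at a time while recording sub-forest accuracy gives a
performance trajectory ``h(i)`` over sub-forest sizes ``i``; the selected
size maximises ``h``.  Evaluate the trajectory on data held aside from
training, otherwise the size choice trivially overfits.

Prediction vectors feed Pearson correlations, so they must be numeric: for
binary problems the class index is used directly; with more than two
classes a per-sample correctness indicator (tree correct = 1) replaces it,
since Pearson correlation of arbitrarily ordered nominal labels is
meaningless.  A zero-variance vector correlates as 0 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "TreeImportance",
    "tree_predictions",
    "majority_vote",
    "delta_accuracy",
    "avg_similarity",
    "pairwise_shrink_step",
    "performance_trajectory",
]

MEASURES = ("delta", "avg_sim", "pairwise")


@dataclass(frozen=True)
class TreeImportance:
    """Importance summary of one tree within its forest."""

    tree: int
    delta: float | None = None   # accuracy impact of removing the tree
    rho: float | None = None     # mean correlation with the other trees
    weight: float = 1.0          # pairwise-shrinking weight, starts at 1

    def __post_init__(self):
        if self.rho is not None and not -1 - 1e-12 <= self.rho <= 1 + 1e-12:
            raise ValueError(f"rho={self.rho} outside [-1, 1]")


def _trees(forest) -> list:
    return list(forest.estimators_) if hasattr(forest, "estimators_") else list(forest)


def tree_predictions(forest, features) -> np.ndarray:
    """(n_trees, n_samples) matrix of per-tree hard predictions."""
    X = np.asarray(features, dtype=float)
    return np.stack([np.asarray(t.predict(X)) for t in _trees(forest)])


def majority_vote(pred: np.ndarray, class_labels: Sequence) -> np.ndarray:
    """Per-sample majority over tree predictions; ties break toward the
    lowest class index."""
    classes = list(class_labels)
    counts = np.stack([(pred == c).sum(axis=0) for c in classes])  # (n_classes, n)
    return np.asarray(classes, dtype=object)[np.argmax(counts, axis=0)]


def _ensemble_accuracy(pred: np.ndarray, y: np.ndarray, classes: Sequence) -> float:
    return float((majority_vote(pred, classes) == y).mean())


def _classes_of(forest, pred: np.ndarray) -> list:
    classes = getattr(forest, "classes_", None)
    if classes is None:
        classes = np.unique(pred)
    return np.asarray(classes).tolist()


def delta_accuracy(forest, tree_index: int, features, labels) -> float:
    """Accuracy impact ``P_F - P_{F-T}`` of removing one tree.

    ``P`` is majority-vote accuracy on the given data.  The tree whose
    removal changes accuracy least (smallest ``delta``) is the best
    candidate for elimination.
    """
    pred = tree_predictions(forest, features)
    if pred.shape[0] < 2:
        raise ValueError("delta_accuracy needs a forest of at least 2 trees")
    if not 0 <= tree_index < pred.shape[0]:
        raise IndexError(f"tree index {tree_index} out of range")
    y = np.asarray(labels)
    classes = _classes_of(forest, pred)
    full = _ensemble_accuracy(pred, y, classes)
    without = _ensemble_accuracy(np.delete(pred, tree_index, axis=0), y, classes)
    return full - without


def _encode(pred: np.ndarray, classes: Sequence, y: np.ndarray | None) -> np.ndarray:
    """Numeric encoding of prediction vectors for correlation."""
    if len(classes) <= 2:
        lookup = {c: i for i, c in enumerate(classes)}
        return np.vectorize(lookup.get)(pred).astype(float)
    if y is None:
        raise ValueError("similarity on a >2-class problem needs labels to form "
                         "correctness-indicator vectors")
    return (pred == y).astype(float)


def _cor(a: np.ndarray, b: np.ndarray) -> float:
    # zero-variance vectors correlate as 0, not NaN
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _cor_matrix(enc: np.ndarray) -> np.ndarray:
    n = enc.shape[0]
    C = np.zeros((n, n))
    for i in range(n):
        C[i, i] = 1.0
        for j in range(i + 1, n):
            C[i, j] = C[j, i] = _cor(enc[i], enc[j])
    return C


def avg_similarity(forest, tree_index: int, features, labels=None) -> float:
    """Mean correlation of one tree's predictions with every other tree's."""
    pred = tree_predictions(forest, features)
    if pred.shape[0] < 2:
        raise ValueError("avg_similarity needs a forest of at least 2 trees")
    classes = _classes_of(forest, pred)
    enc = _encode(pred, classes, None if labels is None else np.asarray(labels))
    others = [i for i in range(enc.shape[0]) if i != tree_index]
    return float(np.mean([_cor(enc[tree_index], enc[i]) for i in others]))


@dataclass
class ShrinkState:
    """Mutable working set for iterative pairwise shrinking."""

    trees: list            # remaining tree objects
    indices: list[int]     # their original indices in the forest
    weights: np.ndarray    # per-remaining-tree weight, initialised to 1

    @classmethod
    def from_forest(cls, forest) -> "ShrinkState":
        trees = _trees(forest)
        return cls(trees, list(range(len(trees))), np.ones(len(trees)))


def pairwise_shrink_step(state: ShrinkState, features, labels=None,
                         classes: Sequence | None = None) -> tuple[int, np.ndarray]:
    """One pairwise-similarity elimination step.

    Finds the most-correlated tree pair, computes the average similarity
    ``rho`` of each member to the rest of the current forest, removes the
    member with the larger ``rho`` (ties: the lower original index), and
    updates every remaining weight as
    ``w_t += cor(T_rs, t) / (rho_{T_rs} * (N_F - 1))`` with ``N_F`` the
    size before removal.  Returns the removed tree's original index and
    the updated weights.  Pair selection uses raw correlations; the
    weights are bookkeeping for downstream inspection.
    """
    n = len(state.trees)
    if n < 3:
        raise ValueError("pairwise step needs at least 3 remaining trees")
    pred = np.stack([np.asarray(t.predict(np.asarray(features, dtype=float)))
                     for t in state.trees])
    if classes is None:
        classes = np.unique(pred).tolist()
    enc = _encode(pred, classes, None if labels is None else np.asarray(labels))
    C = _cor_matrix(enc)

    # most similar pair; ties toward the lowest index pair
    iu = np.triu_indices(n, k=1)
    best = np.argmax(C[iu])
    s1, s2 = int(iu[0][best]), int(iu[1][best])

    rho = (C.sum(axis=1) - 1.0) / (n - 1)  # mean correlation with the others
    rs = s1 if rho[s1] >= rho[s2] else s2
    if rho[s1] == rho[s2]:
        rs = min(s1, s2)

    cor_rs = C[rs]
    denom = rho[rs] * (n - 1)
    keep = [i for i in range(n) if i != rs]
    new_weights = state.weights[keep].copy()
    if denom != 0:
        new_weights += cor_rs[keep] / denom

    removed_original = state.indices[rs]
    state.trees = [state.trees[i] for i in keep]
    state.indices = [state.indices[i] for i in keep]
    state.weights = new_weights
    return removed_original, new_weights


def performance_trajectory(forest, features, labels, measure: str = "delta",
                           ) -> tuple[dict[int, float], int]:
    """Iteratively shrink the forest, recording accuracy per sub-forest size.

    Returns ``(h, selected_size)`` where ``h`` maps sub-forest size ``i``
    (from the full size ``N_F`` down to 1) to majority-vote accuracy on the
    given data, and ``selected_size`` is the argmax of ``h`` (smallest size
    on ties).  ``h[N_F]`` is the full forest's accuracy; the removal
    trajectory proper has ``N_F - 1`` entries.  Pass held-aside selection
    data, not the training set.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    trees = _trees(forest)
    classes = _classes_of(forest, None) if hasattr(forest, "classes_") else None
    pred = np.stack([np.asarray(t.predict(X)) for t in trees])
    if classes is None:
        classes = np.unique(pred).tolist()

    n0 = len(trees)
    h: dict[int, float] = {n0: _ensemble_accuracy(pred, y, classes)}
    remaining = list(range(n0))
    state = ShrinkState([trees[i] for i in remaining], list(remaining), np.ones(n0))

    while len(remaining) > 1:
        sub = pred[remaining]
        n = len(remaining)
        if measure == "delta":
            full = _ensemble_accuracy(sub, y, classes)
            deltas = [full - _ensemble_accuracy(np.delete(sub, j, axis=0), y, classes)
                      for j in range(n)]
            drop = int(np.argmin(deltas))
        elif measure == "avg_sim":
            enc = _encode(sub, classes, y if len(classes) > 2 else None)
            C = _cor_matrix(enc)
            rho = (C.sum(axis=1) - 1.0) / (n - 1)
            drop = int(np.argmax(rho))
        else:  # pairwise
            if n >= 3:
                removed, _ = pairwise_shrink_step(state, X, labels=y, classes=classes)
                drop = remaining.index(removed)
            else:  # two trees left: drop the more redundant (here: higher index)
                drop = 1
        del remaining[drop]
        if measure != "pairwise":
            pass  # state only tracked for the pairwise measure
        h[len(remaining)] = _ensemble_accuracy(pred[remaining], y, classes)

    sizes = sorted(h)
    best_acc = max(h.values())
    selected = min(s for s in sizes if h[s] == best_acc)
    return h, selected
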
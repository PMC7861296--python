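"""Synthetic data generators and fixed fixtures.

Everything in the package is exercisable without any external download:

* :func:`make_tabular` draws two-class Gaussian-cluster tables shaped like
  clinical feature matrices (22 columns by default, a minority of them
  informative), with optional missing cells and subject identifiers for
  leave-one-subject-out splitting.
* :func:`example_tree` builds a fixed eight-leaf decision tree whose
  branches include two canonical worked-example rules — one with a
  redundant repeated test on the same feature — used as the anchor for
  extraction and simplification tests.
* :func:`make_phantom_volume` builds blob phantoms with a three-tissue
  label mask for the imaging descriptors.

All generators take a mandatory seed and are bit-reproducible under it;
there is no hidden global random state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["make_tabular", "example_tree", "figure_tree_expected", "make_phantom_volume",
           "ArrayTree"]


# ---------------------------------------------------------------------------
# Tabular data
# ---------------------------------------------------------------------------

def make_tabular(n_samples: int = 500, n_features: int = 22, n_informative: int = 3,
                 class_sep: float = 3.0, missing_rate: float = 0.0,
                 n_subjects: int = 10, seed: int = 0,
                 ) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Two-class Gaussian-cluster feature table.

    The first ``n_informative`` columns differ in mean by ``class_sep``
    between the classes (unit variance); the rest are pure noise.  Classes
    are balanced.  Missing cells are injected uniformly at random at rate
    ``missing_rate``; samples are assigned round-robin to ``n_subjects``
    subject identifiers.

    Returns ``(features, labels, subject_ids)`` with labels 0/1.
    """
    if not 0 <= n_informative <= n_features:
        raise ValueError(f"n_informative must be in [0, {n_features}], got {n_informative}")
    if not 0 <= missing_rate < 1:
        raise ValueError(f"missing_rate must be in [0, 1), got {missing_rate}")
    if n_samples < 1 or n_subjects < 1:
        raise ValueError("n_samples and n_subjects must be positive")

    rng = np.random.default_rng(seed)
    y = np.arange(n_samples) % 2
    rng.shuffle(y)
    X = rng.normal(size=(n_samples, n_features))
    X[:, :n_informative] += np.outer(y, np.ones(n_informative)) * class_sep

    if missing_rate > 0:
        mask = rng.random(size=X.shape) < missing_rate
        X[mask] = np.nan

    subjects = np.arange(n_samples) % n_subjects
    columns = [f"feature{i}" for i in range(n_features)]
    return pd.DataFrame(X, columns=columns), y, subjects


# ---------------------------------------------------------------------------
# Fixed worked-example tree
# ---------------------------------------------------------------------------

@dataclass
class ArrayTree:
    """A decision tree in flat-array form (scikit-learn's ``tree_`` layout).

    ``children_left[i] == children_right[i] == -1`` marks leaf ``i``;
    internal node ``i`` routes ``feature[i] <= threshold[i]`` left, else
    right.  ``value[i]`` holds per-class sample counts; ``classes_`` the
    label universe.
    """

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    value: np.ndarray
    classes_: np.ndarray

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = []
        for row in X:
            node = 0
            while self.children_left[node] != -1:
                node = (self.children_left[node]
                        if row[self.feature[node]] <= self.threshold[node]
                        else self.children_right[node])
            out.append(self.classes_[int(np.argmax(self.value[node]))])
        return np.asarray(out)


HEALTHY = "healthy"
PARKINSONS = "Parkinson's Disease"


def example_tree() -> ArrayTree:
    """A fixed eight-leaf depth-3 tree over speech-style features.

    Two of its branches are canonical worked examples:

    * the outer-left path reads
      ``feature18 <= -6.421 AND feature10 <= 0.008 AND feature6 <= 0.002``;
    * the path to leaf 5 (sixth leaf from the left) reads
      ``feature18 > -6.421 AND feature14 <= 0.004 AND feature18 > -6.246``
      implying Parkinson's Disease — feature 18 is tested twice, so the
      root test is redundant and within-rule simplification collapses the
      rule to ``feature14 <= 0.004 AND feature18 > -6.246``.
    """
    # node ids: 0 root; 1,2 internal left; 3 leaf... laid out explicitly.
    #        0: f18 <= -6.421
    #       /                \
    #   1: f10 <= 0.008    2: f14 <= 0.004
    #    /        \          /          \
    # 3: f6     4: f2     5: f18      6: f4
    #  <=0.002   <=0.75    <=-6.246    <=1.5
    # /  \      /  \      /   \       /   \
    # 7   8    9   10    11   12    13   14
    children_left = np.array([1, 3, 5, 7, 9, 11, 13, -1, -1, -1, -1, -1, -1, -1, -1])
    children_right = np.array([2, 4, 6, 8, 10, 12, 14, -1, -1, -1, -1, -1, -1, -1, -1])
    feature = np.array([18, 10, 14, 6, 2, 18, 4, -2, -2, -2, -2, -2, -2, -2, -2])
    threshold = np.array([-6.421, 0.008, 0.004, 0.002, 0.75, -6.246, 1.5,
                          -2, -2, -2, -2, -2, -2, -2, -2], dtype=float)
    # per-leaf (healthy, parkinson's) counts; leaf 12 (the twice-tested
    # feature-18 branch, leaf index 5 counting leaves left to right) is PD
    value = np.zeros((15, 2))
    leaf_counts = {7: (9, 1), 8: (2, 6), 9: (7, 0), 10: (1, 4),
                   11: (5, 2), 12: (0, 8), 13: (6, 1), 14: (2, 5)}
    for node, (h, p) in leaf_counts.items():
        value[node] = (h, p)
    return ArrayTree(children_left, children_right, feature, threshold, value,
                     np.array([HEALTHY, PARKINSONS], dtype=object))


def figure_tree_expected() -> dict:
    """Ground truth for :func:`example_tree`, stated independently of the
    extraction code: leaf count and the two worked-example conjunctions."""
    return {
        "n_leaves": 8,
        "outer_left": [(18, "le", -6.421), (10, "le", 0.008), (6, "le", 0.002)],
        "leaf5_raw": [(18, "gt", -6.421), (14, "le", 0.004), (18, "gt", -6.246)],
        "leaf5_simplified": [(14, "le", 0.004), (18, "gt", -6.246)],
        "leaf5_outcome": PARKINSONS,
    }


# ---------------------------------------------------------------------------
# Phantom volumes
# ---------------------------------------------------------------------------

def make_phantom_volume(shape: tuple[int, int, int] = (24, 24, 20), n_blobs: int = 3,
                        noise_sd: float = 0.1, seed: int = 0,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Blob phantom with a matching tissue-label mask.

    ``n_blobs`` (at most 3) spherical blobs of distinct intensity are
    placed on a zero background; blob ``b`` carries intensity ``10 * b``
    and label ``b``.  Gaussian noise of standard deviation ``noise_sd`` is
    added inside the blobs only, so the background stays exactly 0.

    Returns ``(intensities, labels)`` as same-shape arrays.
    """
    if not 1 <= n_blobs <= 3:
        raise ValueError(f"n_blobs must be in [1, 3], got {n_blobs}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    vol = np.zeros(shape)
    lab = np.zeros(shape, dtype=int)
    grid = np.indices(shape).astype(float)
    radius = max(2.0, min(shape) / 6.0)
    for b in range(1, n_blobs + 1):
        center = np.array([rng.uniform(radius, s - radius) for s in shape])
        dist = np.sqrt(((grid - center[:, None, None, None]) ** 2).sum(axis=0))
        inside = dist <= radius
        inside &= lab == 0  # keep blobs disjoint; first blob wins overlaps
        vol[inside] = 10.0 * b
        lab[inside] = b
    if noise_sd > 0:
        noise = rng.normal(scale=noise_sd, size=shape)
        vol[lab > 0] += noise[lab > 0]
    return vol, lab
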
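# Methods

This note records the model, the numerical and design choices, and what
the synthetic test conditions do and do not demonstrate.

## Rule model and extraction

A fitted binary decision tree with single-feature threshold splits is read
as a set of rules, one per leaf: the conditions are the node tests along
the root-to-leaf path in root-first order, the outcome is the leaf's
majority class. Boundary semantics are fixed package-wide as *left branch
⇔ `feature <= threshold`*, matching scikit-learn's trees, so serialized
rules are unambiguous and the extracted rule set reproduces the forest's
per-tree votes exactly (verified by a vote-equivalence test). Leaf ties
break toward the lowest class index, deterministically. Oblique
(multi-feature) splits and regression trees are unsupported and rejected
with an explicit error.

Feature identity is canonical as the column index; names are display
metadata carried by the `RuleSet`. Serialization is a flat JSON schema
(feature names, class labels, fallback class, rules with conditions,
provenance, `cc`/`ic`/score) designed to round-trip losslessly.

## Within-rule simplification

Per feature, all `>` conditions collapse to the single largest threshold
and all `<=` conditions to the single smallest; the tightest bounds imply
the discarded ones, so the simplified rule matches exactly the same set of
points (property-tested against a brute-force membership oracle). The
rule count never changes. A rule whose collapsed bounds contradict each
other (possible only for hand-edited rules — no tree path contradicts
itself) is flagged `infeasible`, excluded from inference, and never
silently deleted: in a decision-support setting an auditable artifact must
not lose rules behind the user's back.

## Scores

- `score1 = (cc−ic)/(cc+ic) + cc/(ic+k)` with `k = 4` by default. When a
  rule covers no training sample (`cc+ic = 0`) the first term is defined
  as 0 rather than raising on 0/0; such rules additionally carry a
  `zero_coverage` flag and rank below any covering rule of equal score, so
  dead rules stay prunable without being conflated with covering ones.
- `score2 = score1 + cc/rl`. An empty-condition rule (a root-only tree)
  uses `rl = 1`: it is one maximally short rule.
- The personalisable score adds `x/(i+2)` per contained favorite feature
  of rank `i` (0 = most preferred) and subtracts the same per contained
  caution feature. Membership counts once even if a feature appears in
  several conditions of one rule — scoring runs after simplification,
  where within-rule duplicates have already collapsed, so the distinction
  only matters for hand-built rules and the membership reading is the
  stable one.
- `x` defaults to 40 (top-favorite bonus +20). The calibration guidance —
  pick `x` so the rank-0 bonus is roughly one third of the maximum
  unpersonalised score — is documentation, not an automatism: the right
  trade-off between the forest's own assessment and the user's preferences
  is a judgement call, and silently rescaling `x` would hide it.

## Reduction

`reduce_topk` ranks by score with deterministic tie-breaking (covering
before zero-coverage, then shorter rule first, then extraction order —
short rules are the transparent ones, so ties resolve toward
transparency) and keeps `ceil(fraction · n)` rules; ceiling rounding
guarantees "10%" of a tiny set is never empty. Ranking is single-pass:
scores are not recomputed after partial deletion, since deletion does not
change any remaining rule's `cc`/`ic`.

`reduce_stochastic` samples without replacement with probability
proportional to the score shifted by `|min| + 1e-9` (scores can be
negative; probabilities cannot), falling back to uniform sampling when all
scores are equal. Fixed seed ⇒ identical selection.

## Inference

All matching rules vote. The aggregation is deliberately configuration
(`majority` | `score_weighted` | `best_rule`) because once rules have been
pruned there is no single canonical aggregation; the default, unweighted
majority with ties broken by larger summed rule score and then lowest
class index, is closest to the forest's own one-tree-one-vote semantics
and makes the full-rule-set predictor agree with the originating forest's
majority vote. A sample matched by no rule receives the fallback class
(training-set majority, stored in the rule set so inference is
self-contained). Missing feature values at predict time are an explicit
error pointing at the imputation module, not a silent NaN comparison.

Sensitivity and specificity are one-vs-rest for a named positive class;
when a fold contains no positive (or no negative) samples the metric is
reported as undefined (`None`), never as 0. For multi-class problems
accuracy is always defined and sensitivity/specificity remain one-vs-rest.

## Cross-validation harness

`cross_validate` re-runs the entire pipeline — impute, train forest,
extract, simplify, score, reduce — inside every fold; imputation
statistics are fit on the training fold only and applied to the test fold,
standard leakage hygiene. Schemes: shuffled k-fold (default k = 10) and
leave-one-subject-out, where each fold's test set is exactly one subject's
rows. The size-versus-accuracy sweep trains each fold's forest once and
re-scores/reduces per profile and fraction, which keeps the sweep linear
in folds rather than in folds × fractions × profiles.

## Forest shrinking

Three tree-importance measures drive iterative removal: accuracy impact
`δ = P_F − P_{F−T}` (remove the argmin), average prediction correlation
`ρ_T` (remove the argmax), and pairwise similarity (find the
most-correlated pair, remove the member with larger ρ, ties to the lower
index). Pairwise steps update bookkeeping weights
`w_t += cor(T_rs, t) / (ρ_{T_rs} · (N_F − 1))`, initialised to 1; the
update is reported for inspection but does not feed back into pair
selection, which uses raw correlations — how the weights should influence
later steps is underdetermined, so the neutral reading was chosen and
documented.

Correlation needs numeric vectors: binary problems use the class index
directly; with more than two classes, per-sample correctness indicators
replace it (Pearson correlation of arbitrarily ordered nominal labels is
meaningless). Zero-variance vectors correlate as 0 by convention, not NaN.

The trajectory `h(i)` records majority-vote accuracy from the full size
`N_F` down to 1; the selected size is the argmax (smallest size on ties),
taken over all sizes *including* `N_F`, so the selected sub-forest is
never worse than the full forest on the selection data. Callers are
expected to pass held-aside selection data — choosing the size on
training data trivially overfits — and the CLI's `shrink` command does the
70/30 split itself.

## Imputation

Mean / median / most-frequent column-wise fills, backed by
scikit-learn's `SimpleImputer` behind the package's fit/apply surface;
most-frequent ties break toward the smallest value (deterministic). An
all-missing column is an error naming the column. Accepted missing
markers in delimited text: empty cell, `NA`, `NaN`.

## Imaging descriptors

Volumes are Gaussian-smoothed first (`sigma` in voxels, default 1.0 — a
mild smoothing suited to ~1 mm isotropic structural scans; configurable),
with reflective boundaries and the kernel truncated at 4σ and
renormalised, so constants pass through unchanged and interior impulses
conserve mass. All descriptors are computed on the smoothed volume,
including the middle-slice features (middle index `floor(dim/2)`).

The histogram mode discretises the considered intensities into 256
equal-width bins (a color-level histogram; bin count configurable) and
returns the fullest bin's center, lowest bin on ties; the background value
0 is excluded by default. "Maximum of the sums of the inner arrays" is
implemented as `max_slab_sum`: sum over the two inner axes to one value
per outermost index, then take the maximum; the reduction axis is
configurable since the phrase admits more than one reading. Per-tissue
features mask the volume by an integer label image (1 = CSF, 2 = gray
matter, 3 = white matter) supplied by the caller — tissue segmentation
itself (e.g. MRF-based) is out of scope and not reimplemented.

## Synthetic data

`make_tabular` draws balanced two-class Gaussian clusters: 22 features by
default (the width of a typical biomedical voice-measurement table), of
which 3 informative columns differ in class mean by `class_sep` (default
3.0, a strongly separable regime) at unit variance; missing cells uniform
at `missing_rate`; subjects assigned round-robin for LOSO. It emulates the
*shape* of clinical tables — not real marginal distributions, feature
correlations, site effects, or label noise — so tests passing on it show
the machinery is correct (extraction is vote-faithful, reduction retains
accuracy when signal is concentrated, favorites are retained
preferentially), not that any particular clinical accuracy is attainable.
The phantom volumes are disjoint constant-intensity blobs (intensity
10·label) with optional Gaussian noise inside the blobs and an exactly
zero background; they validate the descriptor arithmetic, not anatomy.

Test and default problem sizes (hundreds of samples, tens of trees) were
chosen as the smallest scales at which the statistical assertions are
stable across seeds; all generators take a mandatory seed and are
bit-reproducible.

## Known limitations

- Only axis-aligned threshold trees are supported.
- The stochastic reducer implements score-proportional selection only, not
  a full hill-climbing add/remove search around it.
- Pairwise-shrinking weights are reported, not used for selection (see
  above).
- No probability calibration or abstention; no automatic learning of
  preference profiles.
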
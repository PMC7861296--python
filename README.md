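# forestrules

Gray-box clinical decision support from random forests.

Random forests diagnose well but explain poorly: a few hundred trees voting
in concert cannot be audited by the physician who has to sign the
diagnosis. `forestrules` turns a trained forest into an explicit rule set —
one rule per root-to-leaf branch, a conjunction of threshold tests implying
a class — and then makes that rule set small enough to read, while letting
the user's own judgement steer *which* rules survive. It is aimed at
interpretable decision support on tabular biomedical data (clinical scores,
voice measurements, features derived from structural MRI), where the
decision process matters as much as the prediction.

## The method

1. **Extract.** Every branch of every tree becomes a rule
   `(x_a <= t_1 ∧ x_b > t_2 ∧ …) ⇒ class`. A forest's rules reproduce its
   votes exactly: per tree, exactly one rule matches any sample.
2. **Simplify.** Within a rule, repeated tests on one feature collapse to
   the tightest bound (all `>` thresholds to the largest, all `<=` to the
   smallest); the rule matches exactly the same points, only shorter.
3. **Score.** Each rule is scored on the training data with

   ```
   score1     = (cc − ic)/(cc + ic) + cc/(ic + k)
   score2     = score1 + cc/rl
   score_pers = score2 + Σ_favorites x/(i+2) − Σ_cautions x/(i+2)
   ```

   where `cc`/`ic` count covered samples classified correctly/incorrectly,
   `rl` is the rule length, `k > 0` (default 4) damps the accuracy term,
   and the personalisable part adds `x/(i+2)` for each *favorite* feature
   of rank `i` the rule contains (subtracting the same for *caution*
   features). With the default `x = 40` the top favorite is worth +20.
4. **Reduce.** Keep the best-scoring fraction (e.g. 10%), drop the N
   weakest, or sample score-proportionally. Favorite-containing rules
   survive preferentially; caution-containing ones die first.
5. **Classify & evaluate.** Matching rules vote; accuracy, sensitivity and
   specificity come from k-fold or leave-one-subject-out cross-validation
   that re-runs the whole pipeline per fold.

Also included: tree-level *forest shrinking* (remove trees by accuracy
impact δ, average prediction correlation ρ, or pairwise similarity, and
pick the sub-forest size maximising the performance trajectory `h(i)`),
column-wise missing-value imputation (mean / median / most frequent), and
first-order descriptors of 3-D volumes (global and middle-slice
statistics, background-excluding histogram mode, per-tissue sums) so that
imaging studies reduce to the same tabular workflow.

## Worked example

The package ships a fixed eight-leaf decision tree over speech-style
features. Extracting and simplifying it prints:

```python
import forestrules as fr
rs = fr.extract_rules([fr.fixtures.example_tree()])
print(fr.print_rules(fr.simplify_ruleset(rs)))
```

```
(feature18<=-6.421 ∧ feature10<=0.008 ∧ feature6<=0.002) ⇒ healthy
(feature18<=-6.421 ∧ feature10<=0.008 ∧ feature6>0.002) ⇒ Parkinson's Disease
(feature18<=-6.421 ∧ feature10>0.008 ∧ feature2<=0.75) ⇒ healthy
(feature18<=-6.421 ∧ feature10>0.008 ∧ feature2>0.75) ⇒ Parkinson's Disease
(feature18>-6.421 ∧ feature14<=0.004 ∧ feature18<=-6.246) ⇒ healthy
(feature14<=0.004 ∧ feature18>-6.246) ⇒ Parkinson's Disease
(feature18>-6.421 ∧ feature14>0.004 ∧ feature4<=1.5) ⇒ healthy
(feature18>-6.421 ∧ feature14>0.004 ∧ feature4>1.5) ⇒ Parkinson's Disease
```

Eight leaves, eight rules. The sixth rule originally tested feature 18
twice (`> -6.421` at the root, `> -6.246` two levels down); simplification
dropped the root test because the tighter bound implies it — the rule's
meaning is unchanged.

The same workflow from the shell, on a generated two-class table (300
samples, 22 features of which 3 carry signal), keeping the best 10% of
rules while preferring feature 0:

```
$ forestrules fixtures make-tabular --out data.csv --n-samples 300 --seed 7
wrote 300 samples to data.csv
$ forestrules run --input data.csv --out run --n-trees 50 --keep 0.1 --favorite 0 --seed 7
rules: 548 -> 55
accuracy=1.0000 sensitivity=1.0 specificity=1.0 coverage=1.0000
```

The 50-tree forest produced 548 rules; the kept 55 still classify the
held-out 30% perfectly (the data are well separated), and every test
sample is matched by at least one rule. `run/frequency.csv` shows how
reduction concentrated on the informative features:

```
feature,name,original,reduced
0,feature0,253,43
1,feature1,204,18
2,feature2,200,25
3,feature3,51,2
...
```

Feature 0 (informative, and the declared favorite) appears in 43 of the 55
kept rules; the noise feature 3 all but vanishes.

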
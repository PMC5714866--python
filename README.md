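# moltox

Toxicity classification and solubility/permeability regression for small
molecules, built from molecular descriptors and substructure fingerprints.

`moltox` is for cheminformaticians and toxicology researchers who want a
reproducible QSAR pipeline: given molecules (SDF or SMILES) labelled as
toxins or non-toxins, it featurizes them, screens and ranks the features,
optimizes random-forest classifiers by out-of-bag (OOB) error, and emits
per-molecule toxin probabilities. Two companion regression suites predict
aqueous solubility (LogS) and caco-2 cell permeability (LogP — the log10
apparent permeability through a human intestinal-absorption cell model,
*not* the octanol–water partition coefficient), both toxicity-relevant
absorption properties.

## The methods at its core

**Classification.** Molecules are described by 1D/2D descriptors
(RDKit registry, with descriptors that fail on part of a corpus excluded
up front) and by concatenated binary fingerprint families; any feature
column with a missing value is dropped rather than imputed. Candidate
learners (RF, SVM, KNN, CART) are compared by 10-fold cross-validated
ROC AUC on identical folds; random forests win and are then optimized:
features are ranked by *mean decrease in accuracy* (per-tree OOB accuracy
drop under column permutation), `mtry` is tuned by an OOB-error hill
climb, and an OOB-error grid over (top-k feature subset, mtry, ntree) picks
the final descriptor, fingerprint, and hybrid (descriptors + fingerprint
bits) models. A molecule is called toxic when its tree-vote fraction
exceeds 0.5. Evaluation uses the confusion-matrix bundle

```
Sens = TP/(TP+FN)   Spec = TN/(TN+FP)   Prec = TP/(TP+FP)
Acc  = (TP+TN)/N    MCC  = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN))
```

plus a Wilcoxon rank-sum screen (p ≤ 0.05, uncorrected) for descriptors
and bits that discriminate toxins from non-toxins.

**Regression.** Three schemes on descriptor tables, each with its own
variable-selection rule: MLR (`Y = a₁X₁ + … + aₙXₙ + C`, keeping the
descriptors with the smallest coefficient p-values — 15 for LogS, 11 for
LogP), random-forest regression (mtry hill-climb from 14 with step 0.5
and improvement 10⁻⁵ at 100 trees, refit on the 40 / 10 most important
descriptors), and PLS regression (collinearity-tolerant; CV-chosen
component count; top 5 descriptors by absolute standardized coefficient).
Blind-set quality is reported as Pearson r and its square.

## Worked example

Twenty packaged toy molecules (halogenated toxin-like chemistry vs
CHNOP metabolites) through the descriptor pipeline:

```python
from moltox import (build_feature_table, toy_molecule_panel,
                    train_classifier, wilcoxon_screen)

panel = toy_molecule_panel()
table = build_feature_table(panel, kinds={"descriptor"})
res = train_classifier(table, ntree=200, seed=0)
print(res.summary())
```

```
Toxin random-forest classifier
==============================
kind:        descriptor
features:    206
mtry:        14
ntree:       200
seed:        0
class ratio: 1.50 (toxin:nontoxin)
OOB error:   0.0000
OOB metrics:
  sensitivity  1.0000
  ...
  mcc          1.0000
```

The two chemistries are trivially separable, so every OOB metric is 1.
The rank-sum screen says why — hydrogen-bond acceptor counts dominate:

```python
for h in wilcoxon_screen(table, alpha=0.05)[:3]:
    print(h.feature, f"p={h.p_value:.4f}", h.direction)
```

```
NumHAcceptors p=0.0001 higher-in-nontoxin
NHOHCount     p=0.0001 higher-in-nontoxin
NOCount       p=0.0001 higher-in-nontoxin
```

Metabolites are rich in N/O hydrogen-bonding groups, toxins in halogens.
The packaged blind evaluation table for solubility reproduces its
published correlation:

```python
from moltox import load_blind_fixture, evaluate_regression
pairs = [(b.observed, b.predicted) for b in load_blind_fixture("LogS")]
ev = evaluate_regression(pairs)
print(f"r={ev.pearson_r:.3f}, r^2={ev.r_squared:.3f}")
# r=0.917, r^2=0.841
```

A `moltox` CLI wraps the same library:
`moltox featurize | screen | compare | grid | train | evaluate | regress | predict`.

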
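# Methods

## Problem and model

`moltox` treats molecular toxicity as a binary classification problem —
toxin vs non-toxin — driven entirely by 1D/2D structure: no dose,
exposure route, or target information enters the model. The working
assumption is that toxins occupy a distinguishable region of descriptor
and substructure space (e.g. halogen enrichment, fewer hydrogen-bonding
groups), so an ensemble of decision trees over those features can
separate the classes. Two absorption-related properties, aqueous
solubility (LogS, log10 mol/L scale) and caco-2 permeability (LogP,
log10 apparent permeability in cm/s; caco-2 cells model intestinal
absorption), are modelled as regressions on the same descriptors.

## Featurization

* **Composition** — exact per-element atom counts, with implicit
  hydrogens counted by default (`include_h=True`) so that CHNOP
  chemistry is comparable across protonation conventions.
* **Descriptors** — the RDKit 1D/2D registry (206 descriptors after the
  default exclusions). `MinPartialCharge`, `MaxPartialCharge`,
  `MaxAbsPartialCharge` and `Ipc` are pre-excluded: the partial-charge
  descriptors fail on atoms outside the Gasteiger parameterization and
  `Ipc` overflows on large molecules, so they would be dropped by the
  missing-value rule on any realistic corpus anyway.
* **Fingerprints** — six binary families with fixed widths: MACCS (167),
  Morgan radius-2 (1024), RDKit path (1024), hashed atom-pair (1024),
  hashed torsion (1024) and pattern (1024), 5,287 bits total. The
  registry is configurable; tests assert against the configured total,
  not a particular historical composition. Tanimoto similarity
  |a∧b|/|a∨b| is defined as 0 when both vectors are empty.
* **Exclusion rule** — a feature column with *any* missing value across
  the table is dropped and logged (never imputed); a row with *no*
  computable feature is dropped and logged. The rule is idempotent.
* **Splitting** — train size is `round(ratio·n)`; splits are stratified
  by class when binary labels are present, so a skewed corpus (the
  generator default is 2.25:1 toxin:non-toxin) keeps its ratio in both
  partitions. The rounding rule is a package choice; other conventions
  (per-class floor, independent Bernoulli) give counts off by one or two.

## Classifier selection and optimization

* **Algorithm screen** — RF (500 trees), RBF-SVM, KNN (both on z-scored
  features) and CART are compared by mean ROC AUC over the *same*
  stratified k-fold partition (default 10 folds). This is a screen with
  documented fixed defaults, not a per-algorithm tuning exercise.
* **Importance** — out-of-bag mean decrease in accuracy, computed by
  hand: for each tree, the OOB rows are recovered from the tree's
  bootstrap RNG state, the tree's OOB accuracy is measured before and
  after permuting one column (one permutation per tree), and the drop is
  averaged over trees. For regression forests the score is the increase
  in OOB MSE. scikit-learn's `permutation_importance` has no OOB mode,
  and OOB semantics are what the procedure calls for. Ranking ties break
  lexicographically so results are deterministic.
* **mtry tuning** — hill climb from a start value (sqrt(p) for
  classification, p/3 for regression), multiplying/dividing by a step
  factor while the relative OOB improvement exceeds a threshold, then
  returning the best value visited. A step factor below 1 is read
  reciprocally, so the regression convention (start 14, step 0.5,
  improvement 10⁻⁵, 100 trees) walks the same lattice.
* **Grid** — OOB error over (subset, mtry, ntree); metrics come from OOB
  votes. The ntree range 200–1,000 is enumerated as five even levels
  {200, 400, 600, 800, 1000}. The best point minimizes OOB error with
  ties broken toward smaller subset, then smaller mtry, then smaller
  ntree — invariant to enumeration order. Whether the decision metric
  should be OOB- or CV-based is genuinely ambiguous in the field's
  practice; both are computed here and OOB drives the choice.
* **Wilcoxon screen** — two-sided rank-sum test per feature, hits at
  p ≤ α inclusive (default α = 0.05, uncorrected — the screen is
  descriptive, not inferential). Exact p for combined n ≤ 20 with no
  ties, tie-corrected normal approximation otherwise. Direction comes
  from the class-median difference, falling back to means at zero.
* **Calls** — toxin probability is the tree-vote fraction; the call is
  toxic iff probability > 0.5 strictly, so exactly 0.5 is non-toxic.
  Metrics with zero denominators are reported as undefined with a flag,
  never silently coerced to 0.
* **Published-table consistency** — sensitivity, specificity and
  precision of a printed performance row over-determine the positive:
  negative ratio (P/N = prec·(1−spec)/(sens·(1−prec))); with the ratio
  fixed, accuracy and MCC follow and can be checked against the printed
  cells without the underlying corpus. `classify.implied_counts`
  implements this reconstruction; all 56 packaged reference rows agree
  within ±2×10⁻⁴.

## Regression

* **MLR selection** fits the full linear model once and ranks
  coefficient p-values (not stepwise); when the design is rank-deficient
  (n ≤ p+1) it falls back to univariate p-values with a log notice.
  Exact collinearity is an error that names the dependent columns (via
  pivoted QR).
* **RFR** tunes mtry by OOB, ranks by permutation importance, and
  refits on the top-k descriptors (defaults 40 for LogS, 10 for LogP);
  the refit mtry is capped at the subset size.
* **PLSR** chooses its component count by 10-fold CV RMSE capped at 10,
  ranks variables by absolute standardized regression coefficient
  (a VIP-style weighting; the precise selection function used in the
  original analyses is not documented, so this is a package choice),
  retains the top 5, and refits. With full components on a full-rank
  design PLS reproduces OLS, which the tests exploit as an equivalence
  oracle.
* **Evaluation** reports Pearson r and r² (squared correlation) as the
  headline numbers; the coefficient-of-determination variant
  (1 − SSE/SST) is exposed as `cod` but is not the default, because
  blind-set quality here is a correlation claim, not a calibration
  claim.
* Default algorithms: random forest for LogS, PLS for LogP — each the
  better performer for its target on the packaged blind tables.

## Synthetic data

The generator plants known signal so every stage is testable without
external corpora. Continuous ("descriptor-like") informative features
shift their class means by `effect_size · noise_sd`; binary
("fingerprint-like") bits shift the on-probability by `effect_size` over
a sparse base rate of 0.1, mimicking substructure-bit sparsity. Noise
features are class-independent. Defaults: 225 toxins vs 100 non-toxins
(the ~2.25:1 corpus shape), 20 informative among 980 noise features,
effect size 2, unit noise SD. What the generator does *not* emulate:
correlated descriptor blocks, heavy-tailed descriptor distributions, and
activity-cliff structure — so passing planted-signal tests demonstrates
the pipeline's mechanics (ranking, tuning, calibration), not real-corpus
accuracy. Regression tables are exact linear models plus Gaussian noise.
All generators are bit-reproducible under (spec, seed).

A 20-molecule packaged panel (halogenated toxin-like vs CHNOP
metabolite-like structures, names familiar from standard solubility
test sets) provides hand-checkable compositions for featurization tests.

## Numerical choices and problem sizes

* Random forests run single-threaded with explicit integer seeds; OOB
  rows with no vote are excluded from OOB metrics.
* PCA z-scores descriptor columns (heterogeneous physical scales) and
  only centers fingerprint bits.
* Planted-signal acceptance runs use n = 400 (200 + 200), 1,000
  features, 500 trees and 5 seeds; cross-validated comparisons use 10
  folds. These sizes make the whole suite a desk-scale computation while
  leaving the detection margins wide (observed recovery is 20/20
  informative features in the top 40 and AUC ≈ 1.0 at effect size 2;
  chance-level AUC at effect size 0).

## Known limitations

* The blind-set tables ship as packaged data; retraining the original
  corpora-scale models requires external toxin/metabolite corpora that
  are deliberately out of scope.
* The Wilcoxon screen reports raw p-values by design; users comparing
  thousands of bits should apply their own multiplicity control.
* Molecule sanitization failures are excluded (with a report), so corpus
  counts can shrink slightly relative to raw inputs; the exact exclusion
  set depends on RDKit's valence model.
* Descriptor/fingerprint registries are versioned by configuration, not
  pinned to any external tool's historical bit layout.
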
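# Methods

This note documents the modelling procedure implemented by `dicpred`, its
assumptions, the defaults and why they were chosen, what the synthetic data
does and does not emulate, and the numerical conventions that matter for
reproducing its outputs.

## The classification problem

Drug-induced cholestasis (DIC) prediction is cast as binary classification
of compounds described by concatenated binary fingerprint blocks:

- **target block** — bit(c, t) = 1 iff compound c has a reported potency of
  pChEMBL ≥ 5 against liver-expressed protein target t. pChEMBL is
  −log10 of a molar IC50/EC50/Ki/Kd/AC50/Potency value, so the threshold
  corresponds to activity at or below 10 µM. When several measurements
  exist for a pair, the maximum (most potent) is used, which makes the
  binarization order-independent and idempotent under record duplication.
  The threshold comparison is inclusive (≥).
- **pathway block** — a compound hits a pathway iff any protein in the set
  {its active targets} ∪ {first-degree interactome neighbours of those
  targets} is assigned to the pathway, and the pathway passes the
  liver-expression filter. Whether the direct targets' own pathway
  assignments count is genuinely ambiguous in the source material; both
  behaviours are implemented (`include_direct`, default True) because
  dropping direct targets discards exactly the mechanistic links the block
  exists to encode.
- **substructure block** — precomputed binary structural keys (e.g. the
  881-key PubChem-style vector). The key definitions are not reimplemented;
  the block is consumed as a file, or computed upstream by an external
  fingerprinting library.
- **transporter block** — nine bits, one per hepatic transporter; a bit is
  1 iff at least 3 of the per-transporter algorithm votes predict
  inhibition (5 algorithms per transporter, 4 for OATP1B1).

Blocks are concatenated over the intersection of their compound sets, with
feature ids qualified by block label to prevent collisions between a
protein id and the same id reused as a pathway key. Compounds whose row is
duplicated within any of the target/pathway/substructure spaces are
removed before modelling (the nine-bit transporter block is too coarse to
define identity and is never consulted for deduplication): duplicate rows
with conflicting class labels are unlearnable, and duplicate rows with the
same label would leak between train and test.

Matrix coverage — set bits over compounds × features — is computed as a
fraction and formatted as a 2-decimal percentage only at the reporting
layer.

## Class imbalance

Cholestasis data is dominated by negatives (about 3.3:1). Two balancing
strategies are implemented, both applied strictly inside training data
(including inside each cross-validation training fold):

- **SMOTE**: synthetic minority compounds are interpolated between a
  random minority row and one of its k = 5 nearest minority neighbours
  (Euclidean distance on the binary rows), until the classes are 1:1.
  Fractional coordinates are kept rather than re-binarized — tree learners
  split on thresholds and handle them naturally, and rounding would
  collapse distinct interpolants onto existing rows.
- **Undersampling into subsets**: the majority class is partitioned
  uniformly at random (without replacement) into 4 disjoint subsets whose
  sizes differ by at most one; each subset is paired with the full minority
  class and trains one submodel. With a 550/169 training composition this
  gives subsets of 138/138/137/137 majority compounds, so the per-subset
  imbalance inverts mildly (137 < 169); no correction is applied.

## Consensus decision rules

Base learners are scikit-learn `GradientBoostingClassifier` and
`RandomForestClassifier` with library-default hyperparameters and fixed
seeds; every hyperparameter and seed is recorded in the saved bundle
manifest. A single model votes "active" when its positive-class
probability is ≥ 0.5 (the boundary counts as active).

- **4-submodel undersampling consensus**: active at 3–4 votes, inactive at
  0–1 votes; a 2–2 tie is resolved by the arithmetic mean of all four
  probabilities (≥ 0.5 → active). The mean probability is always stored,
  because the filtering step operates on it.
- **9-member expanded consensus**: the 4 GB and 4 RF undersampling
  submodels (sharing one majority-class partition per run, configurable)
  plus one SMOTE-trained model; active iff at least 5 of 9 vote active.
  The SMOTE member is GB or RF, whichever achieves the higher pooled
  balanced accuracy in an internal stratified CV on the unbalanced
  training set with SMOTE applied inside each fold (5 folds by default —
  enough to rank two candidates without doubling the training cost).
- **Probability-range filtering**: compounds whose mean probability lies in
  [0.35, 0.65], boundaries included, are set aside as uncertain. Retained
  compounds are relabelled from the mean probability alone (< 0.35 →
  inactive, > 0.65 → active). This convention — rather than keeping the
  raw vote labels — is the one under which filtered metrics are exactly
  derivable from the band-count table, which keeps the reported tables
  internally consistent.

## Evaluation

The positive class is cholestasis-positive throughout. Reported metrics:
accuracy, MCC, sensitivity, specificity, precision, and balanced accuracy
= (sensitivity + specificity)/2. Any metric with a zero denominator is NaN
(an explicit undefined marker), never silently 0, so degenerate folds
cannot inflate summaries. Metrics are rounded to 2 decimals only at the
reporting layer; model selection compares balanced accuracy at 3 decimals,
with ties broken by higher sensitivity, then higher MCC, then name — a
total order, so selection is permutation-invariant.

Cross-validation is stratified k-fold (k = 10 by default) with **pooled**
out-of-fold predictions: every compound is predicted exactly once, and
metrics and the probability-band table are computed on the pooled set.
Pooling (rather than averaging per-fold metrics) is what makes the band
table's class totals equal the training-set class sizes, and is the only
aggregation under which band counts and CV metrics are mutually
consistent.

Probability bands partition [0, 1] as [0, 0.35), [0.35, 0.65], (0.65, 1]
— the uncertain middle band is closed on both sides, matching the filter.
Filtered metrics drop the middle band and read the low band as
predicted-negative and the high band as predicted-positive.

Feature importance for the 4-submodel ensemble is the **mean scaled
influence**: each submodel's raw importance vector is divided by its own
maximum (top feature → 1.0), the scaled vectors are averaged, and features
are ranked descending (ties broken by feature id for determinism). A
submodel with all-zero importances contributes zeros and triggers a
warning rather than an error.

## Synthetic data

The generators produce what the pipeline sees, not what chemistry looks
like: independent Bernoulli bits with class-conditional rates for planted
informative features and block-level background rates otherwise. Defaults
mirror the baseline study conditions at quarter scale — 53 positives /
172 negatives (3.25:1), blocks of 270 target / 512 pathway /
220 substructure / 9 transporter bits with background densities matching
the observed per-block coverages (0.01 / 0.114 / 0.145 / 0.07), and
planted presence-rate pairs copied from the top-ranked real descriptors
(0.69/0.47, 0.55/0.33, 0.40/0.22, 0.21/0.08). Quarter scale keeps
full-pipeline tests in seconds while preserving the imbalance and sparsity
regime; the statistical acceptance checks use n = 500–899 so that pooled
CV estimates are stable.

What the generator deliberately does **not** emulate: feature correlation
(real pathway bits are strongly nested through shared targets), valid
chemistry, network topology, or label noise. Passing tests therefore
demonstrate that the machinery is correct and well calibrated — null data
yields MCC ≈ 0, planted signal is recovered, filtering concentrates
correct calls — not that any particular real-data performance level will
be reached.

## Numerical conventions and degenerate inputs

- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng` and scikit-learn `random_state`); derived
  seeds are kept below 2³¹. Refitting with the same data and seed is
  bit-reproducible.
- Stratified splitting takes floor(fraction × N) training compounds and
  apportions them to classes by largest remainder (ties to the larger
  fractional remainder, then the larger class), so per-class counts never
  deviate from fraction × class size by more than one. This is the only
  rounding rule consistent with the 719/1324/971/724 train sizes of the
  four study data-set compositions at 80%.
- Class-balance ratios are reported as "R:1" with two decimals; an
  undefined ratio (no positives) is reported as "undefined".
- An empty tissue filter yields a zero-column matrix with a warning rather
  than an error (the degenerate case is legal but almost certainly a data
  problem); an empty transporter vote list is an error naming the
  compound/transporter pair.
- SMOTE requires the minority class to exceed k; the error message advises
  reducing k.

## Known limitations

- No probability calibration, stacking, weighted voting, or
  applicability-domain estimation beyond the probability band.
- Base-learner hyperparameters are ecosystem defaults; no tuning machinery
  is included by design.
- The pathway expansion treats the interactome as a flat first-degree
  neighbour set; no path weighting or depth-2 propagation.
- External target-prediction tools and substructure-key definitions are
  consumed as files, never computed.
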
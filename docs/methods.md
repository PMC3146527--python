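# Methods

## Model and assumptions

The predictor treats ubiquitination-site recognition as binary
classification of lysine-centered sequence windows.  The underlying
assumption is that the determinants of ubiquitin attachment visible in
sequence are short-range residue collocations (short linear motifs in
largely disordered regions) rather than a rigid position-specific
consensus; the CKSAAP encoding is built to expose exactly those
collocations.  No structural information is used, and the model is
organism-specific: a model trained on yeast sites should not be expected to
transfer across proteomes.

### CKSAAP encoding

For a fragment of length L and spacing k, the ordered pair at positions
(i, i + k + 1) is tallied for all admissible i, and each of the 400 pair
counts is divided by the number of pairs the fragment holds,
N_total = L − k − 1.  For the full 27-residue window this gives
N_total = 26, 25, 24, 23, 22, 21 for k = 0..5 (the formula, applied
uniformly; fragments truncated at a protein terminus get smaller
denominators automatically).  Blocks for k = 0..5 are concatenated:
6 × 400 = 2400 features, each in [0, 1], each block summing to exactly 1
whenever the fragment holds at least one pair at that spacing and all-zero
otherwise.

Numerical conventions fixed here:

- Feature order is k-major, then first residue, then second residue, in
  `ACDEFGHIKLMNPQRSTVWY` order.  The order is part of the model file, so
  serialized ensembles are portable.
- Pairs spanning the central K are counted like any other pair; the center
  is excluded only in the binary scheme, where it is constant.  (Excluding
  center-spanning pairs would be the one defensible alternative; it changes
  at most 2 of the N_total pairs per spacing.)
- Truncated fragments are encoded from their actual residues only.  The
  padding symbol `O` exists only in the binary one-hot scheme
  (alphabet `ACDEFGHIKLMNPQRSTVWYO`, 21 × 26 = 546 dimensions).
- Non-standard residue letters are rejected by default; under the optional
  `mask` policy they become `X`, pairs touching an `X` are skipped, and
  N_total counts only scorable pairs so the block normalization is
  preserved.

### Dataset assembly

Fragments are extracted one per lysine, truncated at termini.  Redundancy
is removed with a greedy first-come-kept filter at 40% identity, where
identity of two fragments is the fraction of matching positions under a
center-anchored ungapped alignment, divided by the length of the shorter
fragment.  This denominator is the simplest defensible definition for
mixed-length fragments; listing positives before negatives makes the
filter retain positives preferentially, which is the deliberate policy
here since positives are scarce.  The filter is idempotent and the kept
set provably satisfies the pairwise bound.

### Feature ranking

Chi-squared (CHI) and information gain (IG) scores rank features for
interpretation.  Composition features are sparse, so each is binarized to
presence (> 0) / absence; CHI is the 2×2 chi-squared statistic without
continuity correction, IG the mutual information of presence and class in
bits.  Ties are broken by feature name, so rankings are deterministic.
Rankings must be computed on training folds only; the API takes an
explicit fold-restricted matrix.  CHI/IG variants differ across
implementations (continuity correction, discretization), so ordering
identity with any externally produced top-25 list is not claimed — on
synthetic data with implanted pairs both methods are required to recover
the implants instead.

### SVM, ensemble, thresholds

The backend is scikit-learn's C-SVC (libsvm).  The kernel convention is
pinned: K(u, v) = exp(−γ‖u − v‖²) with γ multiplying the squared
distance.  Signed decision values are the scores; no probability
calibration is applied, and score parity with other SVM implementations
(e.g. SVM-light) is not claimed — decision values from a different
optimizer agree only approximately, which is the main reason point metrics
reported by one implementation can differ slightly from a re-run with
another.

Hyperparameters default to C = 2.0, γ = 8.0, the argmax of cross-validated
mean accuracy over the 16 × 32 = 512-point grid (C ∈ [0.5, 8.0],
γ ∈ [0.5, 16.0], step 0.5, ends inclusive).  When several balanced
datasets are supplied (one per negative resampling) the grid criterion
averages accuracy over all of them, so all members share one (C, γ); ties
go to the earliest grid point.

The ensemble holds 10 members by default, each trained on all positives
plus an equal-sized negative subset drawn without replacement from the
pool under a recorded per-member seed; the ensemble score is the
arithmetic mean of member decision values, which is invariant to member
order.  Thresholds for the 2% and 10% FPR operating points are the
smallest score cutoffs whose empirical FPR on reference negatives does not
exceed the level.  The `train` subcommand calibrates on pool negatives
left unused by every member when at least 50 remain, otherwise on the full
pool; for formal evaluation, pooled out-of-fold scores from the balanced
cross-validation are the recommended calibration input and can be passed
explicitly.  These balanced-data thresholds are optimistic for proteome
scanning, where negatives outnumber positives ~17:1; stricter cutoffs
should be used in practice.

### Evaluation protocol

Stratified k-fold cross-validation (100 folds by default) with a seeded
round-robin partition per class, valid down to leave-one-out; each sample
is scored exactly once out-of-fold.  Pooled scores give one ROC (every
distinct threshold, ties as single steps) and the trapezoidal AUC, which
equals the normalized Mann–Whitney U statistic.  Point metrics Ac, Sn, Sp
and MCC are taken at decision threshold 0 — the SVM's natural boundary —
with MCC defined as 0 when a denominator factor vanishes.  Reported
operating points from other implementations rarely state their exact
threshold, a second source of small discrepancies when comparing point
metrics.  The procedure repeats over seeded negative resamplings (10 by
default) and reports each metric's mean and sample SD (ddof = 1; 0 when
there is a single repeat).

Per-position residue enrichment around the central K uses a two-sample
pooled-variance t-test on occurrence indicators, reported at raw
P < 0.05 by default with an optional Bonferroni flag, matching the
convention of sequence-logo significance displays.

## Synthetic data generator

Negatives are i.i.d. draws from a background amino-acid distribution
(uniform by default; a yeast-proteome composition preset is provided)
around a fixed central K.  Positives add configured "implants": each
(pair, spacing, excess-probability) triple overwrites, with that
probability, a uniformly chosen admissible (i, i + k + 1) position pair
that avoids the center.  A truncation-fraction knob produces terminally
truncated fragments to exercise edge handling.  The default strong-signal
condition used by the acceptance tests is 300 positives + 300 negatives
with three implants (`ExE`, `EQ`, `KxxK`) at excess probability 0.8 — pair
signals shaped like the ones real ubiquitination data show.

What the generator does **not** emulate: realistic positional preferences
(implant positions are uniform), correlations between pairs, disorder or
any structural context, homology between fragments, and the severe class
imbalance of a real proteome.  Passing the recovery tests therefore shows
the pipeline can detect pair-composition signal of realistic strength; it
does not certify accuracy on real proteomes.

## Problem sizes used in the test suite

The self-checks run the full protocol at reduced scale: signal and null
recovery at 300 + 300 samples with 100-fold cross-validation, and the
resampling protocol at 100 positives against a 500-negative pool for
10 repeats of 100-fold cross-validation.  These sizes keep the suite
compact while leaving every fold with enough samples on each side to
train.

## Known limitations

- Decision-value parity with SVM-light is not claimed (different
  optimizer, different stopping rule); metrics reported by other
  implementations are approached, not reproduced bit-for-bit, even on
  identical data.
- The redundancy filter is greedy and order-dependent by design; a
  different input order yields a different (equally valid) kept set.
- Threshold calibration is empirical; with few calibration negatives the
  2% level is coarse (1/n resolution).
- The model file is a joblib archive containing fitted scikit-learn
  members plus JSON-serializable metadata (seeds, params, thresholds,
  encoder config); it is versioned but not portable across major
  scikit-learn releases.
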
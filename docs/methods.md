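# Methods

## Problem and model

`seqbind` treats ligand-binding-residue prediction as residue-level binary
classification from sequence-derived profiles. Each residue is described by
a window of evolutionary conservation scores (the PSSM), optionally
compressed, plus its predicted solvent accessibility; a gradient-boosted
tree ensemble maps the feature vector to a binding probability; the
operating threshold is chosen afterwards against MCC or an FPR/sensitivity
constraint. The pipeline assumes binding residues cluster in sequence (so a
window carries neighbourhood signal) and that conservation and exposure are
informative about binding — both standard assumptions of sequence-based
predictors.

## Feature engineering

* **Window** `w = 17` (odd; centre residue ± 8). Positions past either
  terminus contribute all-zero rows. Zero padding, rather than edge
  replication, keeps terminal windows sparse and is the convention behind
  the "sparse evolution image" picture of the window.
* **Raw log-odds** are used as-is; an optional element-wise
  `1/(1+e^{−x})` squashing is available behind `pssm_sigmoid` (default
  off), since no normalization is part of the core scheme.
* **DCT**: orthonormal 2-D type-II transform (`scipy.fft.dctn`,
  `norm="ortho"`), index ranges `0..M−1`/`0..N−1`. Truncation keeps the
  first `r = 9` whole rows (all 20 columns) rather than a zig-zag scan:
  the compression acts along the window axis only. Parseval holds to
  1e−9 relative, and the transform is checked against a brute-force
  double-sum oracle in the tests.
* **DWT**: a level-by-level cascade (`pywt.dwt`, `mode="symmetric"`,
  wavelet `db4`, 4 levels) applied per PSSM column. Per level the feature
  takes the **first five coefficients of the approximation band** plus
  {std, mean, max, min} of the approximation band and {std, mean, max, min}
  of the detail band — 13 values/level, 52/column, 1040 total. This
  band/statistic composition is the unique natural reading that yields the
  1040-dimensional feature; "first five coefficients" is read as the five
  lowest-index coefficients of the band. `db4` guarantees ≥ 5 coefficients
  in every band at `w = 17` (shorter filters at tiny windows raise a
  configuration error naming the wavelet and level).
* **PSA** contributes the **centre residue's** three probabilities only; a
  windowed PSA would add 51 dimensions and contradict the 183-D total of
  the flagship `pssm_dct_psa` scheme.

Scheme dimensions are pure functions of the configuration: 340 / 180 /
1040 / 343 / 183 / 1043 / 1223.

## File formats

PSI-BLAST `-out_ascii_pssm` files are parsed from the first 20-column
(log-odds) block, cross-checked against the sequence when given; a bare
L×20 TSV dialect is accepted for pre-extracted matrices. PSA files are a
5-column TSV (index, residue, p_buried, p_intermediate, p_exposed) — a
deliberate artifact-defined dialect, since upstream accessibility
predictors vary; rows renormalize when their sum is within [0.95, 1.05] and
error otherwise. Converting another tool's output means writing these five
columns. Label files put a 0/1 line after each FASTA sequence. Feature
tables serialize floats at `%.17g`, so round-trips are bit-exact.

## Balancing

SMOTE synthesizes minority points on segments between a minority point and
one of its `k = 5` minority nearest neighbours (Euclidean, raw feature
space, no scaling — balancing runs directly on extracted features), with
`u ~ U(0,1)`; the majority class is uniformly under-sampled without
replacement. The default target of 19,000 rows per class reflects the
calibrated choice for benchmark-scale training sets; for small runs the
workflow caps the target at the majority count. Originals are always
retained when the minority is below target. Balancing happens strictly
after the train/test split and inside each CV fold's training portion; test
sets stay imbalanced. Plain random under-sampling (majority down to the
minority count) is provided for scheme comparisons.

## Boosting

Binary logistic loss with `g = p − y`, `h = p(1 − p)`; leaf weight, tree
structure score, and split gain follow the closed forms of the L2-and-
leaf-count-regularized second-order objective and are exported as plain
functions. The reference trainer performs exact greedy search over
midpoints of distinct sorted feature values (tied values are unsplittable),
stops a branch when the best gain ≤ 0 or at `max_depth`, and supports
per-tree row/column subsampling. The base score is the logit of the
training prevalence — exactly 0 after balancing. The xgboost backend
(`tree_method="exact"`, `min_child_weight=0`, matched λ, γ, η) optimizes
the same objective and is the practical trainer at scale; the tests confirm
both produce the identical first-tree root split on small instances.
Models dump to a self-describing JSON tree list (feature, threshold,
children, leaf weight) from either backend; predictions are reproducible
from the dump alone. xgboost routes `x < t` left while the dump convention
is `x ≤ t`; thresholds are nudged down one ulp on conversion so the two
rules agree for all representable inputs.

No hyper-parameter values are inherited from any benchmark: the default
grid (`max_depth` 3–8, η ∈ {0.05, 0.1, 0.3}, 100–500 trees, row/column
subsampling ∈ {0.8, 1.0}) covers standard ranges and is fully overridable.

## Evaluation

Predicted positive ⇔ score ≥ threshold (so threshold 0 marks everything
positive, matching the ROC endpoint convention). MCC with an empty
predicted-class marginal is reported as 0 with an `mcc_defined=False` flag.
Candidate thresholds are midpoints between adjacent distinct scores plus
the two sentinels; `max_mcc` breaks ties toward the higher threshold;
`fpr_at(α)` picks, among thresholds with FPR ≤ α, the one with the highest
sensitivity (ties toward the higher threshold). Selecting the threshold on
the evaluation set itself reproduces the common benchmark practice but is
optimistically biased; the CV driver therefore also reports fixed-0.5
numbers, and per-fold as well as score-pooled summaries (both are reported
because pooling and per-fold averaging genuinely differ). Replicate
averaging (default 10 seeds in calibration studies) addresses the
stochasticity of balancing and training. AUC uses the Mann–Whitney
formulation with ties credited ½.

## Synthetic data

The generator emulates the **shape** of real inputs, not their biology:

* labels in contiguous patches (4–12 residues), overall positive rate 0.04
  (≈ 1:25, the imbalance scale of ligand benchmarks); the final patch is
  truncated so the realized rate tracks the target (±20 % bookkeeping
  guarantee at 10⁴ residues);
* PSSM entries `round(N(0, noise_sd))` clipped to [−10, 13] (PSI-BLAST's
  typical integer range), `noise_sd = 2.0` chosen as a realistic log-odds
  spread; binding rows add `effect_size` to the first `n_signal_cols`
  columns before rounding;
* PSA rows `Dirichlet(2, 2, 2)`, mixed toward the fully-exposed corner with
  weight `psa_effect` for binding rows.

What it does **not** emulate: inter-column covariance of real profiles,
alignment-depth effects, residue-composition biases, homology between
proteins. Passing the calibration tests therefore shows the machinery is
sound (no leakage: null-signal AUC ≈ 0.5; signal recovered: effect size 4
on 6 columns gives mean AUC ≥ 0.9; AUC monotone in effect size), not that
any particular accuracy transfers to real benchmarks.

Calibration problem sizes: 30 proteins of 110–150 residues (~3,900
residues, ~3,000 of them evaluated after a by-protein 77 % test split), 10
seeds per condition, SMOTE target capped at the training majority count,
100 trees of depth 4 — sizes chosen so a single CPU completes the full
calibration grid in a couple of minutes.

## Known limitations

* The published per-ligand tables this family of methods reports are
  averages of replicate runs; their printed SN/SP/ACC/MCC rows are not all
  mutually consistent with any single confusion matrix, so count-level
  reconstruction from printed rates can disagree with printed MCC by up to
  ~0.04 on some rows (the test suite documents exactly which).
* Real-data performance requires PSI-BLAST and an accessibility predictor;
  neither is bundled.
* The reference trainer is exact but O(n²·d) per node in the worst case —
  it is an oracle for small instances, not a production trainer.
* No ligand-specific features (binding-propensity profiles, predicted
  secondary structure or dihedrals); metal-ion sites, with very few
  positives, are known to be the hard case for this feature family.
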
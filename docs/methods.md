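# Methods

## Problem setting

Microarray subtype panels are small-n, large-p and imbalanced: the cohort
this package emulates has 281 samples, 22,283 probe-set intensities and
seven leukemia subtypes whose sizes range from 74 down to 17. The pipeline
addresses the imbalance before modeling (SMOTE-Tomek), the dimensionality
before training (chi-square top-k), and prediction variance at the model
level (a fixed-weight ensemble of three small convolutional networks).

## Synthetic cohort generator

`SyntheticSpec`/`generate_dataset` emulate the study conditions rather
than real probe biology. Defaults: class counts 74/51/22/17/46/53/18;
22,283 probes; 300 informative probes at random positions; per-probe
baseline means drawn uniformly in (2.6, 7.4), the visible range of
log-scale intensities in such cohorts; within-class noise SD 0.4, chosen
so that a few log-units of baseline separation dwarfs within-class spread
the way normalized microarray data behave, and so that intensities stay
positive; effect size 2.5, the separation used throughout the end-to-end
checks. Each informative probe is shifted upward by
`effect_size x noise_sd` for exactly one class, with classes assigned
round-robin, so every class is recoverable and per-class recovery is
measurable. Values are Gaussian around these means and clipped at zero
(hybridization intensities are nonnegative; at the default noise level the
clip is a < 1e-10 tail event per cell, so the Gaussian moment structure is
effectively intact).

What the generator does **not** model: probe-probe correlation, batch
effects, heavy-tailed intensity noise, multi-class marker genes, or
cross-hybridization. Passing tests therefore show the pipeline's
machinery is correct and recovers planted signal under idealized
conditions; they do not certify performance on real accession data.

## SMOTE-Tomek

SMOTE targets `equalize_to_majority` by default (explicit per-class counts
are accepted; a target below the current count is an error — the
operation never undersamples). `k_neighbors` defaults to 5, the canonical
SMOTE setting, capped at class_size − 1 with a warning for tiny classes.
Neighborhoods are Euclidean on raw feature values by default; a
`standardize` flag computes them in z-score space instead (the convex
combination itself is unaffected by the affine change of coordinates).
Nearest-neighbor ties break to the lower sample index for determinism.
Every synthetic row records its two parent indices, which is what makes
the leakage assertions in cross-validation checkable.

Tomek detection runs once, after SMOTE, on the augmented set; the method
is not iterated. `remove_both` (the classic combined cleaning) is the
default; `remove_majority_only` deletes only the link member of the
currently larger class and keeps both on ties. Deleted positions are
reported as indices into the augmented pre-removal array.

With the cohort profile, equalizing to the majority yields 7 × 74 = 518
samples before link removal. Published post-rebalancing tallies for this
kind of cohort sometimes show per-class counts above the majority count;
no standard SMOTE target policy produces that, and this implementation
follows its own arithmetic.

## Chi-square selection

The statistic is `sum((O − E)^2 / E)` over feature-state × class cells.
Expression is continuous, so two discretizations are provided:

* **mass** (default): observed is the probe's intensity sum per class,
  expected is total mass × class fraction, summed over classes. This is
  the convention of mainstream feature-selection toolkits for nonnegative
  tabular data and is cross-checked in the tests against
  `sklearn.feature_selection.chi2`. Negative values are rejected with a
  pointer to binarized mode.
* **binarized**: each probe is thresholded at its own median into a
  presence indicator and the score is the chi-square of the resulting
  2 × C contingency table (for C = 2 this is the four-cell formula
  `n(ad − bc)^2 / ((a+b)(c+d)(a+c)(b+d))`); the independent oracle in the
  tests is `scipy.stats.chi2_contingency` without continuity correction.

Zero-variance probes score 0 in both modes — observed equals expected —
rather than erroring. Raw statistics are ranked directly; no p-values or
multiple-testing correction, since only the ordering matters for top-k
retention. Ties in `select_top_k` break to the lower feature index.
Selection can be fitted after the split (default, leakage-free) or before
it.

## Ensemble members and training

Members are fixed architectures (see `build_architecture`); the
convolution is stride 1, no padding, single input channel, so the k
selected probes enter as an ordered length-k sequence. The output layer
is softmax with categorical cross-entropy — the fusion rule needs
probability distributions — with a sigmoid output available behind a
config flag (its outputs are row-renormalized before fusion).

Training choices that the architecture tables of such studies typically
leave unstated, fixed here as package defaults: 100 epochs, batch size 16,
no early stopping, per-feature min-max normalization fitted on training
data only (z-score and none are available). Members train in fixed order
with seeds `seed`, `seed+1`, `seed+2` for decorrelated initializations;
all randomness flows through `numpy.random.Generator`, so training is
bit-reproducible. The engine itself (conv/dense/dropout forward-backward,
Adam with bias correction) lives in `wvcnn.nn` and is verified against
central finite differences in the test suite.

Numerical guards: `log(p + 1e-12)` in the loss; softmax shifted by the row
max; min-max scale of a constant feature treated as 1 so constant inputs
pass through as zeros rather than dividing by zero.

## Evaluation protocol

The stratified split takes `ceil(n x fraction)` test samples (281 at 15%
gives 43, hence 238/43) and allocates them per class by largest-remainder
rounding — remainder ties prefer the larger class, then the lower index —
so every class's test share is within one sample of proportional.
Metrics derive from per-class one-vs-rest TP/FP/FN/TN; a class never
predicted contributes precision 0 and is flagged. Macro averaging is the
default (conservative under imbalance); weighted averaging is available.
Reported files round to 4 decimals; in-memory values are full precision.

Cross-validation uses `sklearn.model_selection.StratifiedKFold`
(shuffled, seeded) for fold assignment and runs the full
rebalance/select/train pipeline independently per fold. The default
`strict` mode refits everything on each training fold; `pooled` mode
rebalances and selects once on all data before folding, reproducing the
bookkeeping style in which resampled totals appear on both sides of the
split. Strict is the default because the alternative leaks synthetic
neighbors of test samples into training.

## Known limitations

* The CNN engine is plain NumPy: fine for the k = 300 regime it serves,
  not intended for large inputs or deep stacks.
* Tomek detection materializes the full pairwise distance matrix
  (O(n²) memory), which is appropriate at cohort scale (hundreds of
  samples) only.
* The generator's independence across probes makes selection easier than
  on real arrays with correlated probe sets; recovery rates on real data
  will be lower at equal effect size.
* Hard voting is provided for completeness but discards calibration; the
  soft vote is the intended operating mode.
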
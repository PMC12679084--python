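# Methods

## The prediction task

A compound i measured at concentration c yields a raw scavenging readout
y(i, c). Readouts are Z-normalized with the training-fold mean and sample
SD (ddof = 1) into the *MGO scavenging activity score*; higher means a
stronger scavenger. The model learns score = f(x_i, c) where x_i is the
compound's molecular descriptor vector (mixed binary substructure flags
and continuous physicochemical/topological descriptors). Descriptors are
consumed, never computed: the readers accept the PaDEL-Descriptor CSV
dialect (header row, first column `Name`) or plain CSV with a chosen id
column.

## Normalization and splitting

All preprocessing statistics — per-descriptor min/max, activity mean/SD,
and the dose-scaler range — are fit on the training records only and
stored in a `NormalizationState` that travels with the trained model.
Choices where the convention was open:

- **Sample SD (n−1)** for the Z-score.
- **Constant descriptors** (min = max) map to 0, keeping p fixed.
- **No clipping**: screening compounds outside the training range produce
  scaled values outside [0, 1], preserving linearity of the transform.
- **Missing descriptor cells** are imputed with the column median and
  logged; they are never dropped, so the feature count is stable.
- **Split is by assay record** at 8:1:1 (val = test = ⌊n/10⌋, train the
  remainder), so replicates of one compound can land in different folds;
  an optional group-by-compound mode keeps compounds intact. The
  record-level convention matches how the assay table is organized but
  has a measurable consequence discussed under *Limitations*.

## Network and training

Three conv blocks (kernels per block M = 32/16/8, length L = 8, stride 2,
batch norm, activation) over the descriptor signal, flatten, one dense
layer; the dose enters as min-max-scaled **log10 concentration** through
its own small dense layer; concatenation is followed by two dense layers
to the scalar score. At the reference width p = 2,756 with a 77-wide
feature dense, 16-wide dose branch and 64-wide head this counts 220,558
trainable parameters (weights, biases, batch-norm scale/shift) — the
deliberately parsimonious ≈0.22 M budget appropriate for p > n tables.

The dose is log-transformed before scaling because assay concentrations
span six orders of magnitude and potency varies on a log scale; plain
linear scaling is available (`ConcentrationScaler(log10=False)`).

Training: Adam, learning rate 2·10⁻⁴, batch 50, exactly 200 epochs, loss
= per-batch √MSE (the literal root of the batch mean squared error; it
shares its optimum with MSE but scales gradients differently), no early
stopping or schedule. Bias is per kernel, the standard convolutional
convention; a per-position bias would inflate the parameter count far
beyond the 0.22 M budget. Everything is NumPy with explicit
backpropagation, so a fixed seed reproduces weights bit-for-bit on one
CPU; checkpoints are JSON (floats round-trip exactly via repr).

Activation: ReLU is the default in the reference full-width spec; the
compact synthetic-study spec (below) defaults to tanh, which on smooth
saturating dose-response targets roughly halves validation RMSE at that
width. Both are selectable everywhere.

The `deepic50_like` and `resnet18_like` comparators are width/depth
presets of the same generic trainer — intentionally larger-capacity
conv nets for the benchmark contrast, not ports of the original
architectures.

## Baselines and feature selection

Univariate importance of descriptor j is the single-regressor F statistic
F_j = (n−2) r_j² / (1 − r_j²), computed on training rows only;
zero-variance descriptors score 0 and rank last, ties break by column
order, and the ranking is identical to ranking by r². Top-q% selection
keeps ⌊q·p/100⌋ best-ranked descriptors (min 1) in original column
order; the retained sets are nested across q. Baselines (lasso, ridge,
random forest, SVR via scikit-learn, plus the deep families) are fit by
exhaustive grid search minimizing validation RMSE, ties resolved by grid
order, winner refit on the training fold. Default grids: α ∈ 10⁻⁴…10²
(7 log-spaced) for lasso/ridge; trees ∈ {100, 500} × depth ∈ {∞, 16} for
RF; C ∈ {0.1, 1, 10} × ε ∈ {0.01, 0.1}, RBF, for SVR. Published grids
can be supplied explicitly when known.

## Validation as a classifier and screening

A labeled active/inactive compound set is scored at a single screening
dose (400 µM, the campaign's screening concentration). AUROC is computed
by midranks (Mann-Whitney; ties credit ½). The 95% CI is a stratified
percentile bootstrap (2.5/97.5 percentiles, default 2,000 replicates,
resampling positives and negatives within class, seeded). The operating
cutoff maximizes Youden's J over midpoints between adjacent unique
scores (plus one below-all candidate); ties take the lowest threshold,
and a strictly-greater-than rule converts scores to activity calls
(default cutoff −0.186). Screening ranks (compound, dose) pairs
descending by score with lexicographic tie-breaks, so rank 1 is the
single best pair; a per-compound best summary is secondary.

## Shapley explanations

The value of a descriptor coalition S for instance x is
v(S) = mean_b f(x_S, b_{\bar S}) over a background sample drawn from
training rows only (default 100 rows). For p ≤ 12 all 2^p coalitions are
enumerated and the attributions are exact Shapley values, so local
accuracy, symmetry and dummy hold to solver precision; wider models use
seeded paired-coalition sampling with the kernel-weighted least-squares
estimator under the efficiency constraint. The dose input is held fixed
at a user-chosen value during explanation, so attributions are over
descriptors alone. Global importance is the mean |φ| per descriptor over
the explained instances.

## The synthetic study generator

The generator emulates the statistical structure of the assay campaign
so every stage is testable without the proprietary tables:

- **Descriptors**: binary ~ Bernoulli(0.2), continuous ~ N(0, 1);
  defaults 160 + 40 = 200 columns. The width is a deliberate reduction
  from the real campaign's 2,756: synthetic columns carry none of the
  redundancy of real descriptor blocks, and 200 keeps a 200-epoch
  training run in minutes on one CPU while preserving p ≫ k sparsity.
- **Latent potency**: k = 20 informative columns with weights of
  magnitude U(0.5, 1.5) and random sign *on the standardized feature
  scale* (so binary and continuous descriptors contribute comparable,
  non-negligible signal), passed through a logistic link with spread
  2.0. Every informative descriptor is therefore recoverable in
  principle by univariate screening.
- **Dose-response**: activity = potency · cʰ/(cʰ + EC50ʰ) + N(0, σ),
  Hill h = 1, σ = 0.05 by default; doses drawn from
  {0.1, 1, 10, 100, 400, 1000} µM. EC50 is a deterministic decreasing
  function of potency (log10 EC50 runs linearly from 2.5 down to 0 as
  potency rises): potent scavengers also act at lower dose. Tying EC50
  to potency keeps activity a deterministic function of descriptors and
  dose, so the regression task is learnable to the noise floor; an
  independent per-compound EC50 would inject compound-level variance no
  descriptor model could explain.
- **Shape emulation**: 660 compounds / 2,262 records by default
  (each compound gets ≥ 1 record, the remainder spread at random);
  labeled sets threshold latent potency (the 11/61 quantile reproduces
  the 50-active/11-inactive validation-panel shape). Raw activities are
  emitted unscaled so the real normalization path is always exercised.
- One global seed fans out to per-stage child seeds; identical seeds
  give byte-identical tables.
- `generate_unseen_compounds` draws fresh compounds governed by the
  *same* informative weights — candidates the model never saw whose true
  potencies live on the learned landscape.

Passing tests on this generator demonstrate that the pipeline recovers
planted structure under its own assumptions (sparse linear-logistic
signal, Hill kinetics, Gaussian noise); they do not certify performance
on real descriptor tables, whose correlation structure, measurement
error and activity cliffs the generator does not imitate.

## Screening-panel design for the rank-1 check

Latent potency is a logistic of a Gaussian score, so compounds pile up
near 0 and 1; among near-saturated compounds the top activities differ
by less than any regressor's ordering resolution, and "the most potent
compound ranks first" would be a coin flip. The zero-noise screening
check therefore screens a 12-member panel with 11 compounds spread over
potency 0.05–0.70 plus one stand-out near 0.99 — the shape of an
application set with a clear best hit — giving a top gap (~0.9 Z at the
high doses) well above the model's resolution on study compounds
(residual SD ≈ 0.26 Z).

## Numerical conventions

- log₂RMSE uses −∞ as the sentinel at RMSE = 0; R² may be negative; PCC
  of a constant prediction vector is NaN.
- AUROC/PCC require both classes / ≥ 2 distinct observed values;
  degenerate inputs raise rather than return silently wrong numbers.
- Batch norm uses ε = 10⁻⁵ and running-stat momentum 0.9; inference uses
  running statistics, so predictions are row-order independent (within a
  batch, identical rows agree to BLAS rounding, ~10⁻¹⁶).
- A NaN/∞ training loss aborts with a diagnostic naming the learning
  rate and target scale.

## Known limitations

- **Record-level splits overstate novel-compound generalization.** With
  replicates of one compound split across folds, the held-out fold shares
  compounds with training: at the emulation scale the zero-noise model
  reaches r ≈ 0.97 (residual 0.26 Z) on study compounds but r ≈ 0.62
  (residual 0.78 Z) on freshly drawn compounds from the same ground
  truth. The grouped split mode exists for measuring the stricter
  compound-level generalization.
- The percentile bootstrap CI undercovers at the 50/11 validation-panel
  size (~89–90% observed at nominal 95% for true AUROC 0.82 over 200
  simulated sets) — a known small-sample property of percentile-type
  intervals for the AUC with a small negative class; interpret the CI at
  that design as approximate.
- Full kernel-SHAP over thousands of descriptors is compute-prohibitive;
  wide models rely on coalition sampling (seeded) or explaining a
  feature subset against a fixed reference row.
- The synthetic generator makes no attempt at chemical realism (no
  SMILES, no correlated descriptor blocks, no activity cliffs).
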
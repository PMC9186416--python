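# Methods

## Model and assumptions

The package implements a two-stage group sparse-representation model for
multitask BOLD data.  Its assumptions, in order of importance:

1. **Shared temporal structure.**  All subjects' runs, once truncated to a
   common length and column-normalized, are sparse combinations of a
   common set of temporal atoms (task responses, slow resting-state
   fluctuations, artifacts).  Stage 1 learns those atoms by online
   dictionary learning with the unit-ℓ₂-ball atom constraint; without the
   constraint the ℓ₁ penalty could be defeated by scaling the dictionary
   up and the codes down.
2. **Shared spatial structure.**  The spatial loading patterns of those
   atoms are themselves sparse combinations of a common set of spatial
   maps.  Stage 2 learns these on the restacked loading blocks.
3. **Task identity lives in the loadings.**  Because both dictionaries
   are shared across subjects and tasks, whatever distinguishes tasks
   must appear in the stage-2 loading blocks `α²_{i,t}`; these are the
   classification features.

Held-out data never touches the dictionaries: test subjects are coded by
solving the per-column LASSO against frozen `D¹`, `D²` with the training
penalties, and `transform_test` refuses penalty overrides outright.

## Parameters that matter

| parameter | default | meaning / why |
|---|---|---|
| `k1` | 200 | temporal atoms; canonical protocol scale |
| `lambda1` | 0.05 | stage-1 ℓ₁ penalty (columns are unit-norm, so 0.05 is 5% of the maximum possible atom-signal correlation) |
| `k2` | 50 | spatial atoms |
| `lambda2` | 0.1 | stage-2 ℓ₁ penalty |
| `voxel_fraction` | 0.1 | random in-mask voxel subsample used everywhere; one seeded subset **shared by all subjects**, because stage 2 stacks loading rows across subjects and needs row correspondence |
| `n_train_subjects` | 30 | subject-level split |
| `n_repeats` | 10 | fresh split + fresh voxel sample per repeat |
| pseudocount | 1 | added to ROA support counts; keeps log-ratios finite for empty rows |
| `support_tolerance` | 1e-8 | magnitude below which a coefficient counts as zero, making support counts solver-agnostic |
| `map_z_threshold` | 2.3 | within-atom z threshold for spatial-map supports |
| `r_task`, `o_rsn`, `o_int` | 0.4, 0.3, 0.25 | categorization thresholds (task-evoked / resting-state / integrated); fixed, documented, and deliberately plain — categories in real data are ultimately judged by inspection |

The desk-scale study conditions (`desk_scale_config`) shrink the geometry
to what a laptop CPU handles in seconds while keeping every structural
element: a 10×10×10 grid (1000 voxels, 10% sampled), 12 subjects split
8/4, seven unequal-length block-design runs (120–176 frames at TR 0.72 s,
truncated to 120), k₁=24, k₂=16 with the canonical penalties, Gaussian
noise σ=0.05 against unit-norm temporal atoms with task gains of 3, and
10% multiplicative spatial-map jitter per subject.  The acceptance script
and the test suite both run at these sizes.

## The ROA convention

The ratio-of-activation statistic is defined here as the absolute mean of
log support-count ratios over the T(T−1)/2 task pairs,
`ROA_i = |mean_{t<k} log(c_{i,t}/c_{i,k})|` — the pair mean makes the
score independent of the number of tasks, and the absolute value sits
outside the mean so that consistent one-sided imbalance is rewarded while
mixed imbalances cancel.  A variant normalizing the pair sum by T instead
of the pair count is available (`convention="literal"`); it differs only
by a constant factor for fixed T and produces the same ranking.  Ties are
broken by ascending component index for determinism.

## What the synthetic generator emulates — and what it does not

Emulated: seven block-design tasks of unequal length with jittered,
mutually decorrelated designs (pairwise regressor |r| < 0.3 at the
canonical 176-frame length); canonical double-gamma HRF (peak 6 s,
undershoot 16 s, 1:6 ratio); resting-state atoms as slow (0.008–0.03 Hz)
oscillations and artifact atoms as polynomial drifts, spike trains and
baseline steps, each rejection-sampled until paradigm-independent
(|r| < 0.3 vs every task regressor) — a planted "shared" component that
tracked a paradigm would be mislabeled ground truth; distinct Gaussian
blob spatial maps; strictly dominant own-task gains; per-subject
multiplicative smooth map jitter; iid Gaussian sensor noise.

Not emulated: physiological noise spectra (cardiac/respiratory),
temporal autocorrelation of BOLD noise, registration error, partial
volume effects, hemodynamic variability across regions, and genuinely
overlapping/correlated spatial networks.  Passing tests therefore show
that the implementation recovers the structure the model assumes when it
is present; they do not show that real fMRI satisfies those assumptions,
and the printed desk-scale numbers (e.g. perfect held-out accuracy) are
properties of the synthetic conditions, not claims about real data.

## Numerical choices

* **Solvers.**  LASSO coding uses scikit-learn's `sparse_encode`.  The
  public `lasso_code` defaults to the exact LARS path, which satisfies
  the KKT optimality conditions to ~1e-15; the fitting loops use
  coordinate descent (`lasso_cd`), which agrees with LARS to ~1e-5 at a
  fraction of the cost on wide matrices.  `lambda = 0` falls back to
  least squares.
* **Dictionary learning** is scikit-learn's minibatch solver driven in
  explicit seeded epochs: atoms initialized from k random data columns,
  sample order reshuffled per epoch, the penalized objective monitored on
  a fixed 512-column subsample, early stop when its relative change drops
  below 1e-5 (batch noise can produce upticks; the descent test allows
  5%).  Atom signs are fixed by making each atom's largest-magnitude
  entry positive.  Fixed seed ⇒ bit-identical results.
* **Stage-2 normalization is off by default.**  The natural reading of
  stage 1's treatment would normalize S² columns too, but a loading
  column of a temporal atom unused in some task is near zero, and
  rescaling it to unit norm manufactures unit-norm noise: measured on the
  fixture this erased the task-specific support contrast ROA counts,
  degraded planted-map overlap from 1.0 to 0.83 and accuracy from 1.0 to
  0.93.  The switch (`normalize_s2`) remains for the other convention.
* **Degenerate inputs.**  Constant (dead-voxel) columns are zeroed and
  flagged rather than erroring; constant series have undefined Pearson
  correlation and return NaN, never 0; an empty reference template is an
  error for overlap; a stage-1 penalty λ₁ ≥ 1 zeroes all loadings of
  unit-norm columns (atoms live in the unit ball, so every atom-signal
  correlation is ≤ 1) and the pipeline degrades to chance-level
  classification rather than failing.
* **Truncation** keeps the earliest frames of every run, cut to the
  shortest run; it is idempotent and never reorders frames.
* **Voxel sampling** draws `round(fraction·|mask|)` indices without
  replacement, sorted ascending; columns are ordered by ascending linear
  (C-order) mask index throughout.

## Design choices where the design was open

* The stage-2 input is assembled with n rows (voxels), since
  `D² ∈ R^{n×k₂}` requires it; the per-(subject, task) blocks are
  transposed loading blocks, stacked subject-major, task-major,
  atom-minor.
* Sampling happens before normalization (normalize the sampled columns),
  so the group matrix statistics depend only on the voxels actually used.
* The reference ("GLM") templates used for overlap can be supplied as
  files from any external activation analysis; the built-in
  mass-univariate OLS (per-voxel regression on event regressors +
  intercept, one-sample t across subjects, t→z conversion, z > 2.3) is a
  minimal stand-in sufficient for synthetic oracles, without prewhitening
  or autocorrelation correction.
* The incremental-ROA classifier applies the selected component rows in
  ascending index order, so selecting all rows reproduces the
  full-feature model bit for bit — the curve's endpoint identity is
  structural, not approximate.
* The headline classifier uses all k₂ components, with the incremental
  curve reported alongside; how many top-ROA components "suffice" is left
  to the curve rather than fixed a priori.
* Multiclass scheme: scikit-learn's `SVC(kernel="linear")` one-vs-one
  default with all other hyperparameters at their defaults.

## Known limitations

* The canonical block designs are optimized for runs of 120–176 frames at
  TR 0.72 s; at other generation lengths the pairwise decorrelation bound
  may fail and `make_ground_truth` raises rather than planting correlated
  "distinct" designs.
* Reconstruction through the chain is deliberately lossy at the canonical
  penalties: unit normalization makes weak-signal voxels mostly noise,
  which the group model leaves unexplained.  Near-exact reconstruction
  (≤5% relative error) holds only in the noiseless, small-penalty,
  sufficient-capacity limit, as the tests demonstrate.
* The minibatch dictionary learner's objective is non-convex; different
  seeds give different (equally valid) dictionaries.  All reported
  quantities are defined up to atom permutation and sign, and the tests
  match atoms by best assignment.
* Memory: group matrices are dense `float64`; at full protocol scale
  (p=30, ~23k sampled voxels) S¹ is ~7 GB, so protocol-scale runs need to
  reduce the voxel fraction or subjects per pass.
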
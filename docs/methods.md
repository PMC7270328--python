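# Methods

This note records the statistical model behind `connharm`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical and design decisions a maintainer would otherwise
have to reverse-engineer.

## Connectivity features

The entry point is a per-subject T×p matrix of ROI time courses with
optional nuisance traces. The pipeline order is fixed:

    censor (scrub) → band-pass → nuisance regression → Pearson r → Fisher z

- **Scrubbing.** Frames with framewise displacement above a threshold
  (default 0.5 mm, a common resting-state choice) are censored. Because an
  IIR filter cannot handle gaps, censored frames are linearly interpolated
  for the filtering step and excluded again before the correlation. A
  subject with fewer than `min_frames` (default 50) surviving frames raises
  a quality error naming the subject rather than producing a silent, noisy
  feature vector. The displacement trace itself is an input; the package
  does not impose one formula for it.
- **Band-pass.** Zero-phase (forward–backward) Butterworth, order 5,
  0.008–0.1 Hz — the standard BOLD fluctuation band. Nuisance traces are
  filtered with the same filter before regression, otherwise the regression
  could reintroduce out-of-band variance into the residuals.
- **Nuisance regression.** Ordinary least squares of every ROI column on
  [intercept, 6 motion parameters, white matter, CSF, global signal (flag)].
  Collinear design columns are dropped via pivoted QR with a logged warning.
  Global-signal regression is a flag (`use_gsr`) because its use is
  contested; the default is on.
- **Correlation and Fisher z.** Correlations are clipped to |r| ≤ 1−10⁻⁷
  before arctanh so z stays finite (z ≈ ±8.406 at the clip). Zero-variance
  columns yield z = 0 on their edges with a warning instead of NaNs. Edge
  order is canonical: 0-based upper triangle, row-major — 9,316 edges at
  p = 137.

## Harmonization model

Per edge e, training features are modeled as

    z_e = δ_site,e + β_age,e · (age − ā) + β_sex,e · sex + ε_e

with one dummy per site and no global intercept (cell-means coding), age
centered at the training mean, sex coded {0,1} with the mapping stored in
the model. Interactions (site×age, site×sex) are deliberately excluded from
the harmonization: with small per-site samples the extra coefficients
inflate generalization error, and the fixed-effect additive model is exactly
what the synthetic generator produces (see below). The
`interaction_diagnostics` routine exists to *check* this assumption: it
F-tests the interaction block per edge and summarizes the p-value histogram
with a chi-square goodness-of-fit test against uniformity (default 20
equal-width bins, 19 df). Residual variance is not rescaled per site; only
location is harmonized.

The fit pools patients and controls (the confound regression should see the
same population the classifier will see). A consequence worth stating
explicitly: in a site with patient fraction ρ, the site dummy absorbs ρ·d of
any diagnosis effect d, so training-control residuals center at −ρ·d on
affected edges, not at zero. The model therefore stores the per-edge mean
residual of the training controls (`hc_residual_mean`).

### Calibration of an unseen site

Default method `"offset"`: with the training coefficients frozen, the new
site's offset is

    offset_e = mean over calibration controls of (x_e − β_age,e·age_c − β_sex,e·sex) − hc_residual_mean_e

i.e. the covariate-adjusted control mean, anchored to where training
controls actually sit. Without the anchor, calibration would place the new
site's controls at zero while the decision boundary was learned against
controls at −ρ·d, shifting every new-site subject by ρ·d relative to the
boundary; in simulation this costs roughly 15 accuracy points at d = 1.5.
The `"refit"` method instead re-estimates the full regression on training
plus calibration subjects with an added dummy; the two agree on balanced,
noise-free calibration sets and `"offset"` is the default because it cannot
perturb the trained classifier's feature geometry.

Subjects used for calibration are recorded by identifier and refused at
scoring time (a leakage error, overridable with an explicit flag that logs).

For *uncalibrated* transfer — the condition calibration is meant to fix —
a site with no dummy is residualized by subtracting the mean of the
training-site offsets (the new site is treated as an average training
site). Any true offset of that site then remains in its features, which is
precisely what produces the one-class collapse the evaluation protocols
demonstrate.

## Screening and classifiers

- **Rank-sum screen.** Per-edge two-sided Wilcoxon rank-sum test on the
  training split only; exact null distribution when both groups have ≤ 10
  subjects, normal approximation with tie and continuity correction
  otherwise (scipy's axis-vectorized Mann–Whitney U). Threshold α = 0.05 by
  default, no multiplicity correction — the screen is a dimension-reduction
  device, not an inference, and the false-positive edges it admits are
  diluted by the classifier. If nothing survives, the single smallest-p edge
  is kept so downstream code always has a feature.
- **Classifiers.** SVM, random forest and AdaBoost wrap scikit-learn
  estimators behind hyperparameter names from the tree/SVM tooling
  vocabulary: box constraint C ∈ [10⁻³,10³] (log), kernel scale s ∈
  [10⁻³,10³] (log, gamma = 1/s²), kernel ∈ {gaussian, linear, polynomial
  (degree 3)}; minimum leaf size ∈ [1, n/2], maximum splits ∈ [1, n−1]
  (max_leaf_nodes = splits+1), ensemble cycles ∈ [10, 500], AdaBoost learn
  rate ∈ [10⁻³,1] (log). Labels are coded control = 0, patient = 1, and
  every classifier exposes a continuous decision value for ROC ranking.
- **Sparse logistic regression (ARD).** Bayesian logistic regression with an
  independent Gaussian prior N(0, 1/α_j) per weight. The weight posterior is
  approximated by Laplace around the penalized MAP (inner Newton/IRLS);
  precisions follow MacKay's evidence updates α_j = γ_j/w_j²,
  γ_j = 1 − α_j Σ_jj; weights with α_j > 10⁸ are pruned; the intercept has a
  near-flat fixed prior and is never pruned. Convergence requires both a
  relative evidence change below 10⁻⁴ *and* stable precisions — the evidence
  flattens long before slowly diverging precisions finish pruning, and
  stopping on evidence alone leaves weak null features in the model.
  Precisions are initialized at n (strong shrinkage), which approximates the
  sequential "start empty" construction: in a separable high-dimensional
  regime, starting from a flat prior lets noise features lock themselves in.
  Intrinsic limitation: on data containing *only* noise, evidence
  maximization still retains a minority of features (a lone null feature is
  kept with probability ≈ 1/3); aggressive pruning of null features (>90%)
  is achieved when informative structure is present to compete with them.
- **Bayesian optimization.** Inner-CV accuracy (stratified, default 8-fold)
  is the objective. After a random initial design (8 points), a Matern-5/2
  GP with a white-noise term is fitted on the normalized search space
  (log-scaled continuous dimensions, one-hot categoricals) and each next
  point maximizes Expected Improvement over 256 random candidates. Budgets
  below 5 evaluations fall back to defaults with a warning; a
  hyperparameter setting whose fit fails scores zero. The loop is a pure
  function of (data, space, budget, seed).

## Evaluation protocols

All protocols refit confound regression, screening and (when budgeted)
hyperparameter search inside each training split, and a guard asserts train
and test identifier sets are disjoint at every split. Two outer schemes are
provided because both are in common use and they answer slightly different
questions: strict leave-one-subject-out (`run_loocv`) and a stratified
9-fold outer loop (`run_kfold`) whose folds balance diagnosis × sex × site
cells and whose hyperparameters come from an 8-fold inner CV. The
permutation test permutes diagnosis labels *before* any training-side
computation — selection and fitting are redone per permutation — because a
null that reuses selected features is anti-conservative; its p-value is the
add-one estimator (1 + #{null ≥ observed})/(B + 1).

Independent-site evaluation trains once on the training sites, then per
repeat draws calibration controls (default size n_HC − n_MDD so the
remaining test set is class-balanced), calibrates, and scores the balanced
remainder; it reports mean ± SD over repeats (default 100) plus the
uncalibrated full-site baseline. Leave-one-site-out reports per-site
accuracy/sensitivity/specificity/AUC (AUC by the rank statistic on decision
values, threshold fixed at 0).

## Synthetic cohorts

Feature-mode generative model (edge e, subject s):

    z_se = μ_e + β_age,e·(age_s − 47.5) + β_sex,e·sex_s + δ_site(s),e
           + d_s·noise_sd·1{patient}·1{e affected} + ε_se,  ε ~ N(0, noise_sd²)

μ_e ~ N(0.25, 0.2²) (typical Fisher-z connectivity levels), ages uniform on
[20, 75], sex balanced, site offsets δ fixed per site (sampled once with SD
`site_offset_sd`), a fraction `effect_fraction` of edges carrying a
standardized effect d, and patients flagged melancholic optionally carrying
a larger d — the homogeneous-subgroup scenario. The generator and the
harmonization estimator are conjugate by design: the additive fixed-effect
structure is exactly what the regression removes, so parameter recovery is a
meaningful test. Defaults (4 sites, 10+10 subjects/site, 137 ROIs, effect
fraction 0.02, d = 0.5, offset SD 0.5, noise SD 1) describe a moderate,
realistic regime.

Time-series mode maps each subject's noise-free feature values through tanh
into a designed correlation matrix (projected to the nearest
positive-definite correlation matrix by eigenvalue flooring at 10⁻⁶),
draws latent multivariate-normal series, and applies an AR(1) recursion
(coefficient 0.3) — which preserves instantaneous correlations — plus
weakly coupled smooth nuisance signals, random-walk motion traces and a
derived displacement series.

What the generator does **not** emulate: heavy-tailed motion artifacts,
multiplicative or heteroscedastic site effects (a scale knob exists but
defaults to 1), edge-to-edge correlation structure of the noise,
age-by-diagnosis interactions, and scanner drift. Passing tests on these
cohorts therefore demonstrate the *logic* of harmonization, calibration and
leakage-free evaluation — not robustness to every artifact of real fMRI.

## Problem sizes in the shipped experiments

The canned experiments (`connharm.experiments`, used by the test suite and
`scripts/acceptance.py`) choose sizes so each phenomenon is demonstrated
with comfortable statistical margins on a single CPU: 137 ROIs (9,316
edges) wherever the edge count or the type-I-error rate over many edges is
itself the quantity of interest, and 16 ROIs (120 edges) for the protocol
experiments. The site-transfer experiment uses offset SD 4× the noise SD
and d = 1.5 on 5% of edges, averaged over six independently shifted test
sites with 100 calibration repeats each: whether a *single* random site
shift collapses the classifier depends on how it projects onto the decision
direction (benign shifts occur), while the average over sites is stable.
The homogeneity experiment (d = 1.5 vs 2.5 for melancholic patients,
per-site-balanced subgroup, six replicate cohorts) likewise averages
replicates because single-cohort comparisons near ceiling are noisy. The
permutation experiment uses 50 permutations; its expected outcome on a
separable cohort is the distribution floor 1/51.

## Known limitations

- Location-only harmonization; no empirical-Bayes shrinkage (ComBat-style),
  no traveling-subject designs, no variance harmonization.
- Binary diagnosis only; no multi-class support or probability calibration.
- The ARD logistic regression uses a Laplace approximation; for tiny n its
  evidence surface can be flat and the non-convergence flag should be
  checked.
- Voxel-level preprocessing (realignment, normalization, segmentation) is
  out of scope; ROI time series are the entry point.
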
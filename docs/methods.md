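# Methods

This note documents the statistical model behind `voxelsvm`, the synthetic
cohort generator it is validated on, the numerical choices, and the known
limits of what the tests demonstrate.

## Analysis model

### Features

Input is one GM-density volume per subject (values in [0, 1], already in a
common space) plus a participants table. The pipeline:

* **Smoothing.** Gaussian, default FWHM 8 mm, σ_axis = FWHM /(2√(2 ln 2)) /
  voxel_size_axis, honoring anisotropic voxels via the affine. Boundary
  handling is normalized convolution with the renormalization applied at the
  source voxel: the input is divided by the smoothed indicator before
  convolving. For a symmetric kernel this conserves the total GM density
  exactly (Σ_x g(x−c) equals the indicator value at c) and coincides with
  plain convolution wherever the kernel fits inside the lattice.
* **Mask.** A voxel enters the analysis iff the mean smoothed density over
  *all* subjects (both sites pooled) is strictly greater than 0.2. Pooling
  both sites before the train/test split mirrors the classical protocol and
  is a mild information leak; a `strict_split` mode fits mask and nuisance
  regression on the training site only.
* **Voxel order.** Masked voxels are flattened with the x index varying
  fastest; the column→(i,j,k) map is stored with the feature matrix and is
  invertible, so any per-voxel statistic can be scattered back to a volume.
* **Nuisance removal.** Per site, each voxel column is regressed (OLS) on an
  intercept plus site-centered covariates (age and sex by default; sex coded
  F = 0, M = 1; any numeric column such as intracranial volume may be
  added). The output is residual + fitted intercept, so the site mean — and
  the 0.2-scale interpretation of densities — is retained. Rank-deficient
  designs (constant covariate, single-sex site) raise an error rather than
  silently dropping a column.

### Classifier

A linear soft-margin SVM with the study's label convention (patient = −1,
control = +1). The dual

    min_α ½ αᵀQα − 1ᵀα,  0 ≤ α_i ≤ C,  yᵀα = 0,  Q = yyᵀ ∘ XXᵀ

is solved by SMO with maximal-violating-pair working-set selection on the
precomputed Gram matrix (cohorts have ~100 subjects and 10³–10⁵ voxels, so
the n × n kernel is the cheap object). Stopping rule: maximal KKT violation
≤ 1e-6. The bias is the mean of y_k − f_k over free support vectors
(midpoint of the violating bounds if none are free). Decision d(x) = w·x + b
with w = Σ α_i y_i x_i; d = 0 predicts patient. Features are *not*
standardized before the SVM — nothing beyond residualization is applied.

C is selected on the training site by stratified ten-fold CV over a log₂
grid 2⁻¹⁰ … 2¹⁰ (21 points), accuracy pooled over held-out folds, ties
broken toward the smaller C. The reported "CV accuracy" is the pooled
held-out accuracy at the selected C (non-nested); a nested procedure would
be less biased but is not the protocol reproduced here.

### Performance and its permutation null

With patient as the positive class: sensitivity TP/(TP+FN), specificity
TN/(TN+FP), PPV TP/(TP+FP), NPV TN/(TN+FN); zero-denominator ratios are
reported missing, never 0. AUC is the rank statistic of the decision values
oriented so higher risk (= lower d) means patient, with half-credit for
ties. Permutation p-values permute the *training* labels, retrain at the
fixed C of the unpermuted fit, and re-evaluate the untouched test set:
p = max(#{null ≥ observed}, 1)/B. The floor 1/B makes the smallest
reportable p at B = 5000 equal to 2×10⁻⁴. For CV accuracy, labels are
permuted before the CV loop. Whether one should instead permute test labels
is a design fork; training-label permutation with retraining is the default
because it nulls the learned model, not just the evaluation.

### Weight-map inference

Retraining under B label permutations yields per-voxel null weight samples.
Only streaming tallies are kept (counts of |w_null| ≥ |w_obs| and of
w_null ≥ w_obs), so memory is O(voxels) regardless of B. Voxel p-values are
count-based with the same 1/B floor. The default sidedness compares
magnitudes (two-sided): a literal one-sided rule on signed weights is
selectable, but under it large negative weights — voxels where patients have
*higher* GM pull — could never reach significance, which contradicts how
such weight maps are read; the magnitude rule is therefore the default and
the divergence is deliberate.

Significance is decided by Benjamini–Hochberg step-up over all masked
voxels as one family (q = 0.05 default; per-voxel null, not a max-statistic
null). Significant voxels are grouped into connected components
(26-connectivity default; 6 and 18 selectable) and components with voxel
count ≤ min_size (default 100, strict) are discarded. Clusters are sorted
ascending by size; each is reported with voxel count, the unweighted
centroid of member voxel centers mapped to mm ("center of gravity"), and
the arithmetic mean of the observed weight over members. No anatomical
atlas lookup is attempted — clusters are coordinates, not region names.

**Interaction between B and the mask size.** With count-based p-values
floored at 1/B, BH at level q over m voxels can only reject if at least
m/(B·q) voxels sit exactly at the floor. At B = 5000, q = 0.05 and m ≈
8000 masked voxels that is ~32 voxels — attainable. At B = 200 it is 800
voxels and rejection is impossible. Desk-scale runs must therefore scale B
and the lattice together; the shipped tests use 16³ lattices (m ≈ 1000)
with B = 500 for localization checks and B = 200 only for null-calibration
checks, where no rejections is the expected outcome.

### Clinical statistics

ROI means are taken from the *residualized* volumes (the pipeline's final
preprocessed state; a flag-level choice, since "preprocessed" is ambiguous
by one step). Spearman ρ uses mid-ranks for ties and the two-sided
t-approximation p = 2·P(T_{n−2} ≥ |ρ|√((n−2)/(1−ρ²))). Correlations are
computed for patients only, per model/site, with pairwise deletion of
missing values and per-cell n reported; BH runs across the full ROI ×
variable family of one model. Demographic anchors use the pooled-variance
two-sample t from summary statistics (df = n₁+n₂−2) and the Pearson 2×2 χ²
without continuity correction.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not MRI physics.

* **Template.** An ellipsoidal "brain" support (semi-axes 0.42 of the
  lattice extent, raised-cosine taper from r = 0.75 to 1) carrying a base
  density 0.55 modulated by a seed-dependent low-frequency field (white
  noise on a 4³ lattice, cubic-upsampled, scaled to ±0.12·range).
  Interior values stay in [0.3, 0.8]; background defaults to 0.05, so the
  0.2 mask threshold separates brain from background with noise margin on
  both sides.
* **Subject volumes.** template + (site shift + age slope·(age − site mean
  age) + sex effect·[male]) · support + disease effect (patients only)
  + smoothed noise, clipped to [0, 1]. Offsets are modulated by the brain
  support so background voxels are unaffected (otherwise they clip against
  0 and the clipping-safety budget of < 1 % is blown). Noise is white
  Gaussian, smoothed with a plain Gaussian at the generator's intrinsic
  FWHM (default 8 mm) so images have realistic spatial autocorrelation —
  permutation inference on white noise would be an easier, unrepresentative
  test. "Age − mean age" uses the site's mean age, matching the per-site
  residualization downstream.
* **Disease effect.** Each region is an ellipsoid in world mm with profile
  cos²(πr/2) (1 at center, 0 at the boundary). The amplitude is
  effect_d · σ_within, where σ_within is the analytic within-group SD at
  the core for that site: √(noise_sd²·‖g‖² + (age_slope·age_sd)² +
  sex_effect²/4), with ‖g‖² the squared norm of the discrete smoothing
  kernel measured exactly from an impulse response. The realized Cohen's d
  at region cores is thus ≈ effect_d per site (verified to ±0.25 at the
  default sample sizes). The ground-truth mask is profile > 0.5.
* **Clinical scores.** Patients draw PANSS positive/negative/general
  subscales (total = their sum, which guarantees total ≥ each subscale),
  onset age (truncated below the subject's age; duration = age − onset),
  CPZ-equivalent dose and premorbid IQ from site-specific normal
  distributions; controls carry missing values for the patient-only
  variables and keep IQ. A region may declare a clinical link (variable,
  target Spearman ρ): the linked score is r·z + √(1−r²)·ε on the latent
  scale, where z is the standardized regional mean GM of that site's
  patients and r = 2 sin(πρ/6) converts the Spearman target to a Pearson
  correlation under approximate bivariate normality. An impossible link
  (|ρ| ≥ 1, or a region with no GM variance, e.g. empty on the lattice) is
  reported as an error, never silently clamped.
* **Defaults.** Two sites of 50/51 and 49/48 subjects, ages 38.8 ± 6.9 /
  36.5 ± 7.1 and 28.1 ± 5.0 / 26.9 ± 3.3 years, site-specific clinical
  distributions; lattice 32³ at 4 mm (full-scale grids via config); subject
  noise SD 0.08 with site-specific scanner noise 0.02/0.03 added in
  quadrature; age slope −0.002 density/year; sex effect +0.01 for males;
  two effect regions (16 and 14 mm radii) at effect_d = 1.2, the second
  coupled to CPZ dose at ρ = −0.35. The site intensity offsets are ±0.001:
  segmentation-based GM density maps carry no large whole-brain scanner
  offset, and a uniform offset aligns with the net-positive weight sum and
  would destroy cross-site threshold transfer that the analysis setting
  presumes; ±0.001 keeps the scanner effect detectable in the site means
  while leaving transfer intact. Under these defaults the cross-site
  accuracy is ≈ 0.65–0.85 with AUC ≈ 0.85 across seeds — the intended
  regime of a clearly-above-chance but imperfect classifier.

### What the generator does not emulate

No T1 acquisition, segmentation error, registration error, skull/CSF/WM
compartments, motion, or site-by-disease interactions; scanner effects are
a global offset plus stationary noise, while real scanner effects are
spatially structured. Consequently, passing tests show the *pipeline* is
correct and calibrated under its stated assumptions — they do not show that
real-scanner site effects are harmless, and the strict-split mode exists
precisely because the pooled mask/residualization is a known mild leak.

## Problem sizes and numerical choices

* Multi-seed statistical tests run on 16³ lattices (≈1000 masked voxels)
  with B = 200–500 and the default cohort sizes; single-run demonstrations
  use 32³. These sizes keep the full suite near half a minute while leaving
  every statistical property measurable (see the B-vs-mask-size note
  above).
* SMO: KKT tolerance 1e-6, iteration cap 2·10⁵ pair updates, degenerate
  pair curvature floored at 1e-14. Dual–primal consistency (w = Σα_iy_ix_i,
  Σα_iy_i = 0, 0 ≤ α ≤ C) holds to 1e-6 and the dual objective matches a
  generic QP solve to 1e-5 on small instances.
* Determinism: every stochastic stage takes an explicit seed; the workflow
  spawns per-stage seeds (< 2³¹) from one master seed via a seed sequence,
  and identical configurations produce byte-identical artifact manifests.
* Tie-breaks: C-selection ties go to the smaller C; decision-value ties at
  0 predict patient; BH uses the standard step-up; cluster records with
  equal sizes keep component-label order after the ascending sort.
* Degenerate inputs: single-class labels, non-finite features, empty
  p-vectors, empty ROIs, zero-margin 2×2 tables and rank-deficient designs
  raise errors with the offending object named.

## Known limitations

* The non-nested CV accuracy is optimistically biased; the nested variant
  is available but not the default, for protocol fidelity.
* Permutation p-values for AUC and accuracy share one null sample of B
  refits; their joint distribution is not corrected for multiplicity.
* The Spearman p uses the t-approximation everywhere, which is inaccurate
  below n ≈ 10; cells with fewer than 3 complete pairs are reported
  missing.
* Cluster extent thresholds are in voxels, not mm³, so they do not transfer
  across lattice resolutions; desk-scale runs must scale min_size
  accordingly.
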
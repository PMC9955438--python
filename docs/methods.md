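# Methods

This note documents the models implemented in `sersdx`, the defaults
and why they were chosen, what the synthetic cohort generator does and
does not emulate, and the numerical decisions a maintainer should know
about.

## Synthetic serum-SERS cohorts

Real serum SERS spectra in the 600–1800 cm⁻¹ fingerprint region are a
superposition of narrow vibrational bands from serum metabolites and
proteins, a broad autofluorescence background, and detector noise; the
absolute intensity scale varies strongly between acquisitions and
carries no analyte information. The generator reproduces exactly this
structure:

- **Grid.** 600–1800 cm⁻¹ in 2 cm⁻¹ steps (601 points). The span is the
  standard serum fingerprint window; 2 cm⁻¹ is a typical dispersive
  spectrometer resolution.
- **Bands.** Lorentzian profiles (the natural Raman lineshape), default
  FWHM 16 cm⁻¹, at the 11 wavenumbers where serum SERS consistently
  shows peaks (637, 722, 810, 888, 1003, 1134, 1203, 1333, 1432, 1557,
  1652 cm⁻¹). Per-sample band amplitudes are
  `base_amplitude × class_multiplier × lognormal jitter`
  (σ = 0.15, i.e. ≈15 % biological within-class variation per band).
- **Class effects.** Default multipliers encode the qualitative
  group differences the diagnostic analysis targets: gallbladder-stone
  serum depressed at 888 cm⁻¹ (glutathione), polyp serum elevated at
  1203 cm⁻¹ (phenylalanine), stone/polyp contrasts at 637, 722, 1203,
  1432 and 1652 cm⁻¹, an additional polyp contrast at 1134 cm⁻¹, and
  deliberately *no* effect at 810, 1003, 1333 and 1557 cm⁻¹. The
  literature reports only effect directions, not sizes; the default
  magnitudes (20–30 % shifts) were fixed once as a realistic
  moderate-effect regime and are fully configurable
  (`default_serum_bands(effect_scale=...)` rescales all of them).
- **Norm balance.** Within each class the up- and down-effects
  approximately cancel in total spectral energy. This is deliberate:
  SERS absolute intensity is uninformative, and vector normalization
  divides each spectrum by its norm, so a class that changed its total
  energy would leak artificial differences into the null-effect bands.
  With balanced effects the 1003 cm⁻¹ band stays statistically null
  after the full preprocessing chain, as a null band should.
- **Baseline.** A broad Gaussian hump (center 1300 cm⁻¹, FWHM
  600 cm⁻¹, mean height ≈2× the strongest band) plus a shallow linear
  slope, with per-sample lognormal height jitter — a stand-in for serum
  autofluorescence.
- **Replicates.** Five technical replicates per sample with i.i.d.
  Gaussian noise (σ = 0.03) are averaged into the sample's spectrum,
  mirroring the common acquisition protocol; averaged-noise variance is
  σ²/replicates.
- **Cohort.** 72 healthy / 51 stone / 25 polyp = 148 samples by
  default, the composition of the motivating clinical cohort.

What the generator does **not** emulate: wavenumber miscalibration and
peak drift, heteroscedastic shot noise, substrate (Ag-colloid)
batch effects, cosmic-ray spikes, or correlated biological covariates
(age, sex). Passing tests therefore demonstrate correctness of the
algorithms and recoverability of injected structure, not clinical
performance on real serum.

## Preprocessing

1. **Savitzky–Golay smoothing**, window 9 / order 5. The filter
   reproduces polynomials up to degree 5 exactly; endpoints evaluate
   the terminal-window fit rather than padding.
2. **airPLS baseline removal** per spectrum. Iteration *i* solves the
   weighted Whittaker problem `(W + λD'D) z = W y` (D = second
   difference); weights are then set to 0 where `y ≥ z` and to
   `exp(i·|y−z| / |Σ negative residuals|)` below the baseline, with the
   two endpoints anchored at the maximum weight. Stopping: negative
   residual mass < 0.1 % of total intensity, or 15 iterations.
   Defaults λ = 10⁴ (appropriate for ~600-point spectra with
   600 cm⁻¹-scale backgrounds); results are mildly λ-sensitive, so λ is
   exposed. Negative intensities after subtraction are retained — they
   are informative noise, and clipping would bias the normalization.
3. **Vector normalization** to unit Euclidean norm over the full grid.

Order is fixed: smooth → baseline → normalize. The whole chain is
deterministic.

## OPLS-DA

Classes are dummy-coded into Y (one column per class, rows sum to 1);
X and Y are mean-centered, with no variance scaling — spectra are
already on a common scale after vector normalization and unit-variance
scaling would inflate empty spectral regions.

- **Orthogonal components.** The candidate direction is the loading of
  the leading NIPALS component, made orthogonal to the whole span of
  X'Y (SVD basis). Because the orthogonal weight is exactly orthogonal
  to every column of X'Y, the orthogonal scores have exactly zero
  covariance with every class indicator. Orthogonalizing against the
  first predictive weight alone — the textbook single-response recipe —
  is *not* sufficient for a multi-class Y: it lets the deflation absorb
  the second class contrast and collapses the minority class.
- **Predictive components.** Multi-response NIPALS with deflation of
  both blocks; default count is `n_classes − 1` (2 for the triple
  model, 1 for binary models).
- **Orthogonal count.** Either fixed by the user (the pipeline default
  is 1) or selected automatically: components are added while
  cross-validated Q² improves by > 0.01, capped at 5.
- **Q²(cum).** Stratified k-fold (default 10, seeded); per component
  a, PRESSₐ pools out-of-fold squared error of the cumulative
  prediction, and Q²(cum) = 1 − Πₐ PRESSₐ/SSₐ₋₁ with SSₐ₋₁ the
  residual Y sum of squares of the full fit after a−1 components (the
  cumulative-product convention; the simpler 1 − PRESS/SS is obtained
  at one component). k = n gives leave-one-out.
- **Prediction.** New spectra are centered, orthogonal-filtered and
  projected; the reconstructed dummy estimates are the class scores and
  the maximum wins, ties broken by class order with a logged warning.
- **Score plots.** t₁ versus t₂ (or the first orthogonal score for
  single-component models) with a 95 % Hotelling T² ellipse,
  `T²crit = 2(n−1)/(n−2)·F₀.₉₅(2, n−2)`.

## PCA-LDA

PCA by centered SVD; the retained component count defaults to the
smallest number explaining ≥ 95 % of variance, capped at n/3 (the
motivating study does not state its rule). Fisher LDA solves the
generalized eigenproblem `S_b v = λ S_w v` on the PCA scores (never on
raw 601-dimensional spectra); the retained eigenvectors are
S_w-orthonormal, so Euclidean distance in the projected space is the
pooled-covariance Mahalanobis distance, and nearest-class-mean with
equal priors is the shared-covariance Bayes rule restricted to the
discriminant subspace. Equal priors are the diagnostic convention —
cohort prevalence should not bias the call — and are configurable. A
singular within-class scatter raises an error suggesting fewer
components.

## Validation

- **Confusion metrics.** Rows = true class. Sensitivity(c) =
  correct(c)/n(c). Two specificity conventions are always reported:
  the *cross-class* form Σ_{k≠c} correct(k) / Σ_{k≠c} n(k) (used in
  several clinical-spectroscopy tables, and the only definition that
  reproduces those tables' printed values) and the textbook one-vs-rest
  TN/(TN+FP). Percentages are rounded half-up to one decimal, matching
  how such tables are printed. `reconstruct_binary_counts` inverts
  printed binary sensitivity/specificity to integer counts for
  consistency checks.
- **Cross-validation.** Stratified k-fold (seeded); every sample is
  predicted exactly once out-of-fold and the report pools those
  predictions. Fold counts above the smallest class are rejected.
- **Permutation test.** Default 100 permutations. For each, the labels
  are shuffled, the OPLS model (including its Q² CV) refitted, and the
  abscissa is the mean absolute column-wise Pearson correlation between
  permuted and original dummy matrices. Least-squares lines through the
  permuted points plus the original model at correlation 1 give the
  R² and Q² intercepts; the model is declared well-constructed when
  R²-intercept < 0.4 and Q²-intercept < 0.05.
- **ROC/AUC.** Rank-statistic (Mann–Whitney) AUC with ties counting
  one half, one-vs-rest per class on that class's continuous model
  score; full ROC point lists are exported. Fitted-model (training) ROC
  is what such studies usually show; out-of-fold scores from
  `kfold_cv` are available and preferable for honest assessment.

## Peak analysis

Peak intensity is the local maximum within ±8 cm⁻¹ of the nominal
position (robust to small shifts; the located wavenumber is recorded;
half-width 0 degenerates to nearest-grid-point lookup). Per peak, a
one-way fixed-effects ANOVA across classes at α = 0.05, uncorrected —
matching common practice in this literature — with a Bonferroni column
emitted alongside for transparency.

## Problem sizes and determinism

Default analyses run on the 148 × 601 cohort; the test suite uses the
full default cohort for end-to-end checks, 20 generator seeds for the
ANOVA-recovery rate, 100 permutations for the permutation test, and
≤ 100-sample instances for brute-force oracle comparisons. Every
stochastic step (cohort generation, CV splitting, permutation) is
driven by an explicit integer seed, and a pipeline run writes a
manifest from which it can be replayed bit-identically.

## Known limitations

- The airPLS stopping rule scales with total intensity, so baseline
  estimates under constant offsets agree only to within the iteration
  granularity (tested at 5 % of signal range).
- The OPLS automatic orthogonal-component rule is greedy and stops at
  the first non-improving count.
- The cross-class specificity is not a per-class error rate in the
  usual sense; the one-vs-rest column should be used for comparisons
  with other literature.
- Q² conventions differ between chemometrics packages (cumulative
  product vs. total-PRESS ratio, fold counts, stratification); absolute
  Q² values are comparable only within one convention.
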
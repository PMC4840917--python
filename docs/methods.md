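# Methods

`vkproteome` implements a batch-aware association analysis for multiplexed
(isobaric-label) plasma proteomics against a continuous nutritional biomarker
— plasma PIVKA-II (des-γ-carboxy prothrombin), the standard marker of
subclinical vitamin K deficiency — and against the dichotomized deficiency
state (PIVKA-II > 2 μg/L). This note records the model, the conventions and
numerical choices, what the synthetic cohort generator does and does not
emulate, and the known limitations.

## Study design being modelled

A cohort of children (500 by default) contributes one plasma sample each.
Samples are multiplexed into iTRAQ 8-plex experiments (72 runs; 576 channel
slots, the surplus left empty), so every child belongs to exactly one
(experiment, channel) slot. Reporter-ion quantitation yields, per experiment,
a protein × channel table of relative abundances; which proteins are
quantified varies by experiment (missing-by-experiment), averaging ~589 of
~4705 proteins per run, with ~978 proteins quantified in more than 10% of
children (> 50). PIVKA-II is measured by immunoassay with a 0.001 μg/L
detection limit; undetectable values (26/500) are retained for group
analyses but cannot enter the log-scale continuous analysis (474 remain).

## Normalization

Reporter-ion intensities are log2-transformed and centered on the median of
each child's channel within its experiment, which removes sample-loading
differences and makes channels comparable across runs; after centering every
channel's log2 median is exactly 0 (enforced to 1e-9). Centering by protein
within experiment is available (`by="protein"`) as a sensitivity mode; which
of the two the original analysis used is not documented, and per-channel
centering is the convention adopted here because it is the one that makes
channels comparable. Normalization is idempotent on centered data and
invariant to rescaling any channel's raw intensities by a positive constant.

## The association model

For each protein p quantified in more than `min_children` (default 50)
distinct children, a univariate random-intercept linear mixed model combines
children across experiments j:

    y_i = β0 + β1 x_i + u_{j(i)} + e_i,   u_j ~ N(0, σ_u²),  e_i ~ N(0, σ_e²)

* **Continuous analysis** (`AssociationScan`): y = log2 PIVKA-II (474
  children with detectable values), x = normalized log2 abundance of protein
  p. The slope is reported as the percent change in PIVKA-II per doubling of
  protein abundance, (2^β1 − 1) × 100, with the 95% CI transformed
  monotonically from β1 ± 1.96·SE.
* **Group analysis** (`GroupDifferenceScan`): y = log2 abundance of protein
  p, x = deficiency indicator (PIVKA-II > 2 μg/L, deficient coded 1; the
  2 μg/L boundary itself is sufficient; below-detection children are
  sufficient and retained, so all 500 children are eligible). The
  coefficient is the percent difference in abundance, deficient relative to
  sufficient.

The two directions are deliberately asymmetric (biomarker on protein vs
protein on group) and are carried as explicit tags so they cannot be
swapped.

### Estimation

Parameters are estimated by REML, profiling the restricted likelihood over
the variance ratio λ = σ_u²/σ_e²: for fixed λ the GLS fixed effects and the
residual variance are closed-form, so the criterion is one-dimensional. It
is maximized by a 54-point grid on λ ∈ {0} ∪ [1e-6, 1e7] followed by bounded
scalar refinement (tolerance 1e-8), with ties broken toward λ = 0. σ_u² is
constrained non-negative; boundary estimates reduce the fit to OLS exactly,
as do the degenerate designs where the criterion is provably flat in λ (one
group, or one observation per group). Proteins observed in a single
experiment are therefore fitted rather than skipped. A brute-force reference
(`grid_reml_oracle`) evaluates the same criterion by dense-matrix linear
algebra on a fixed λ grid and is used only for validation.

### Inference conventions

* **Wald test**: the statistic is β1/SE with SE from the plug-in GLS
  covariance σ̂_e²(X'V̂⁻¹X)⁻¹ at the REML optimum. (statsmodels' MixedLM
  reports Hessian-based standard errors instead; the two agree to a few
  percent and the test suite cross-checks against it.) The plug-in SE
  ignores the uncertainty in the estimated variance components, whose
  effective sample size is the number of experiments, not of children:
  under a null with genuine between-experiment outcome variance, null
  z-statistics are over-dispersed (sd ≈ 1.008 at 72 experiments; ~10–40%
  excess mass below p = 0.01), which is enough to push realized FDR above
  its target in dense scans. The scans therefore default to a Student t
  reference with n_groups − 1 degrees of freedom (n − 2 in the single-group
  OLS limit), which restores far-tail calibration; a plain normal reference
  remains available (`AnalysisConfig(p_reference="normal")`). No
  Satterthwaite/Kenward–Roger machinery is used.
* **R²** is the proportion of outcome variance explained by the fitted
  values, Var(ŷ)/Var(y) clipped to [0, 1], where ŷ includes the BLUP random
  intercepts û_j = (λ n_j/(1 + λ n_j)) · (mean within-experiment residual).
  A fixed-effects-only mode is exposed (`r2(include_random=False)`).
* **Degenerate fits** (constant predictor, < 3 observations, a group with
  < 2 quantified children in the group analysis, zero SE) are logged and
  skipped, never fatal to a scan.

### Multiple testing

Each scan's p-value family is corrected separately with Storey q-values:
q_(i) = min over t ≥ p_(i) of π̂0·m·t/#{p ≤ t}. π̂0 is estimated by the
smoother convention — π0(λ) = #{p > λ}/(m(1−λ)) on λ = 0.05, 0.10, …, 0.95,
smoothed with a cubic polynomial and evaluated at λ = 0.95, clipped to
(1/m, 1] — with fixed-λ and π0 = 1 modes available; π0 = 1 reproduces
Benjamini–Hochberg exactly. Discovery thresholds are strict: q < 0.10
(primary) and q < 0.20 (relaxed, used for network selection).

### Correlation network

Proteins with q < 0.20 in either scan (union, ordered by ascending minimum
q) enter a co-abundance matrix. Pearson correlations are computed within
each experiment over children quantified for both proteins (experiments with
fewer than 3 complete pairs skipped: Pearson is undefined below 2 and
degenerate at ±1 with 2), then averaged unweighted across experiments, per
the analysis convention. Because per-experiment n is at most the plex size,
n-weighted and Fisher-z-averaged modes are provided for sensitivity. For
display, entries with |r| strictly below 0.01 are set to 0 (diagonal
untouched); the canonical output is the numeric TSV matrix, with an optional
blue-positive/red-negative heatmap.

### Descriptive cohort table

Deficient-vs-sufficient covariate comparisons use Welch's t-test for
continuous covariates declared normally distributed, Mann–Whitney for those
declared skewed (the declaration is per-covariate configuration, since
assignment by distribution shape is a judgement call), and chi-square for
categoricals with Yates continuity correction for 2×2 tables (toggleable).

## Synthetic cohort generator

The generator exists so every stage is testable without the study data and
so estimator recovery can be checked against known truth. It emulates:

* allocation of `n_children` (500) to `n_experiments` (72) runs of up to
  `plex_size` (8) channels, shuffled, with surplus channels empty;
* latent log2 abundance x_ip = u_{j(i),p} + b_ip with experiment batch
  effects u ~ N(0, σ_u² = 0.045) and biological variation
  b ~ N(0, σ_bio² = 0.06) — a total log2 SD of ~0.32, with the u:b split
  chosen so that the strongest driver's fitted-value R² lands near 0.3,
  the magnitude the analysis is designed to detect. These are assumptions:
  the true variance decomposition of the study data is unknown;
* a correlated block (default 6 proteins, within-block ρ = 0.8 via a shared
  child-level factor) emulating the hemoglobin/erythrocyte-enzyme cluster;
* driver proteins whose latent abundance drives the outcome:
  log2 Y_i = Σ_k β_k x_{i,k} + e_i. Default slopes (1.2479, −0.7322,
  −0.8890, −0.7027, 0.1596) correspond to percent changes of +137.5, −39.8,
  −46.0, −38.6 and +11.7 per doubling — the effect sizes the analysis is
  meant to resolve;
* a right-skewed PIVKA-II marginal: e_i is skew-normal with location, scale
  and shape solved numerically (least squares on the CDF scale,
  Gauss–Hermite quadrature over the driver contribution) to match median
  1.31 μg/L, quartiles 0.83/1.87 and a 20% deficient fraction. A symmetric
  residual cannot match these targets (the log2 quartile gaps are
  asymmetric), and with four targets and three parameters the fit is a
  balanced compromise, within ~0.01 on the CDF scale (~2% on the
  quantiles); infeasible targets raise `CalibrationError`;
* an assay floor: a random 26/500 of children have their latent log2
  PIVKA-II shifted far below the 0.001 μg/L detection limit and are
  recorded as 0 with a below-detection flag. The floor indicator is
  independent of protein abundance. This matters: if the undetectable
  children were instead the lower tail of the bulk distribution, excluding
  them from the continuous analysis would truncate the outcome and
  attenuate every slope by ~15–20%, which is not a feature of the design
  being emulated — there the undetectable values sit orders of magnitude
  below the bulk, so their exclusion is not selection on the modelled
  outcome. Bulk quantile targets are adjusted for the floor mass
  ((p − p0)/(1 − p0));
* missing-by-experiment detection: protein p is detected in experiment j
  with probability π_p ~ Beta(a, b), with (a, b) solved numerically so the
  mean detected-per-experiment count (589) and the expected number of
  well-covered proteins (978 in > 50 children) both hit their targets. The
  largest drawn π values are swapped onto driver/block proteins (a pure
  permutation of the draws) so the reported-effect proteins are analysable;
* raw reporter intensities 2^(14 + c_i + μ_p + x_ip) with per-channel
  loading offsets c_i ~ N(0, 0.3²) and per-protein baselines
  μ_p ~ N(0, 0.5²), both of which channel-median normalization removes.

One master seed fans out to per-stage substreams; identical config + seed
gives byte-identical TSV output.

**Reduced configurations.** Simulation studies (parameter recovery, FDR
control, null calibration) use `SimConfig.reduced()`: 300 proteins with a
high detected fraction (~200/experiment) instead of the full proteome's
589/4705. The detected fraction is deliberately *not* scaled down with the
proteome: the channel median that anchors normalization has variance
proportional to 1/#detected proteins, so a small proteome with realistic
12.5% detection would inject normalization noise — and hence slope
attenuation — that the full-scale design does not have. Problem sizes (50
replicate cohorts for recovery and FDR; 20 seeds for generator calibration)
were chosen to keep Monte-Carlo error well inside the test tolerances.

**What the generator does not emulate**, and hence what passing tests do
not establish about real data: reporter-ion ratio compression and
interference, peptide-to-protein rollup error, protein-abundance-dependent
(MNAR) detection, heteroscedastic assay noise, covariate structure (age,
lipids, inflammation are not generated), and any nonlinear
biomarker–protein relationships. Recovery results certify the estimator
under its own assumptions, not the biology.

## Numerical choices and degenerate inputs

* REML criterion: −2lR = (n−p)(log 2πσ̂² + 1) + log|Ṽ| + log|X'Ṽ⁻¹X|, with
  Ṽ = I + λZZ'; this matches the statsmodels REML log-likelihood convention
  and is evaluated per group in O(n).
* Grid-then-refine optimization avoids the flat/multimodal pathologies of
  pure scalar minimization at boundary optima; exact flat cases (one group;
  all singleton groups) short-circuit to OLS.
* Below-detection PIVKA-II is stored as measured (0 allowed) plus a flag —
  never imputed; each stage decides inclusion.
* Coverage counts distinct children, strict inequality (exactly 50 → out).
  The scan additionally requires > `min_children` analysable children
  (after dropping below-detection subjects), so reported n always exceeds
  the coverage threshold.
* Ties in p-value sorting are stable (mergesort), keeping output
  deterministic.
* Correlation entries with no contributing experiment are NaN, preserved in
  the TSV as missing rather than silently zeroed.

## Limitations

* Univariate models only: no covariate adjustment, interactions, or nested/
  crossed random effects; confounding by age or lipids is out of scope.
* Wald inference is asymptotic; for proteins quantified in few experiments
  the z-reference may be anticonservative relative to a t-reference.
* On small p-value families (a few hundred tests) π̂0 from the smoother has
  standard error ~0.3 regardless of smoothing, so realized FDR fluctuates
  around its target; q-value families are never pooled across analyses.
* Averaged correlations over ≤ 8-child experiments carry small-sample bias
  of order ρ(1−ρ²)/(2(n−1)) per experiment (≈ 0.02–0.03 at ρ = 0.8), which
  unweighted averaging does not remove — relevant when comparing the block
  recovery (~0.77) against its generative ρ = 0.8.
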
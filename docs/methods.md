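# Methods

This note documents the statistical models the package implements, the
generative models behind the synthetic data, the numerical choices that
matter, and the limitations of what the test suite can demonstrate.

## Exposure model

Weekly ethanol intake is the questionnaire sum
Σᵢ portionsᵢ × volumeᵢ × concentrationᵢ × k over six beverage types,
with concentration = ABV/100 × 0.789 g/mL (ethanol density) and
k ∈ {1, 12·7/365} for weekly/monthly reporters. k is stored at full
precision; 0.23 is its conventional rounding. The default beverage
table (175 mL wine at 12% ABV, 568 mL beer/cider at 4%, 25 mL spirits
at 40%, 50 mL fortified wine at 17.5%, 250 mL "other" at 4%) holds
UK-typical stand-in values and is fully replaceable from a 3-column
file; published food-composition tables should be substituted when
available.

Drinker categories follow the questionnaire logic exactly: "Never" plus
never-drank → never; "Never" plus previously-drank → former; "Special
occasions only" → infrequent; "1–3 times a month" or more often →
regular. Quantitative analyses use regular drinkers only: infrequent
drinkers' monthly reports are considered too coarse, and never/former
drinkers differ systematically from current drinkers (the classic
sick-quitter problem).

Trimming removes values strictly below the lower and strictly above the
upper percentile bound (linear interpolation between closest ranks; ties
at a bound are retained, the conservative reading). The default 1/1
trim is computed among regular drinkers only, before standardisation;
the per-SD scale is therefore defined on the trimmed analysis
population. Whether trimming should precede or follow the exclusion of
infrequent drinkers is genuinely ambiguous; this package fixes the
regular-drinkers-only convention and documents it here.

## Phenotype derivation

* **IOP** — mean of available corneal-compensated eye readings; for
  participants on ocular hypotensive medication the pretreatment value
  is imputed as measured/0.7; participants with glaucoma surgery/laser,
  corneal graft, refractive surgery or significant ocular trauma are set
  missing; finally the top/bottom 0.5 percentiles of the derived
  distribution are removed (device-artifact control).
* **OCT** — mRNFL and mGCIPL thicknesses as the mean of available eyes;
  no pathology-based exclusions (general-population estimand).
* **Glaucoma** — case on self-reported diagnosis/surgery or any
  qualifying ICD code (prefix match on normalised codes: H40.* except
  H40.0-prefixed, any H42.*, 365.* except 365.0-prefixed) dated ≤ 365
  days after baseline ("up to one year" read inclusively); cases with a
  qualifying diagnosis age < 30 are excluded; controls using ocular
  hypotensives or carrying a suspect code (H40.0 / 365.0) are excluded.
  Participants with glaucoma are *not* excluded from IOP/OCT analyses by
  default; a sensitivity variant removes them.

## Association models

All models adjust for thirteen covariates: age, sex, ethnicity
(White/Black/Other), Townsend deprivation index, assessment season, BMI,
height, systolic blood pressure, spherical equivalent, diabetes, smoking
status, smoking intensity and physical activity. Continuous outcomes use
OLS; glaucoma uses maximum-likelihood logistic regression (Newton/IRLS,
convergence on gradient, quasi-Newton fallback for ill-conditioned
designs) reported as odds ratios. Intervals are Wald-type throughout —
no robust or clustered variance, matching the design being emulated.

Quintiles of intake use interpolated 20/40/60/80th-percentile cut
points, lower-closed, ties to the lower quintile. The trend test refits
the model replacing quintile indicators with each participant's
quintile-median intake as a continuous term and Wald-tests that term;
the construction fixes the test since only the median-assignment recipe
is standard.

Restricted cubic splines use the truncated-power parameterisation with
nonlinear terms scaled by the squared boundary-knot span: for knots
t₁<…<t_k the j-th nonlinear basis is
[(x−tⱼ)₊³ − (x−t_{k−1})₊³ (t_k−tⱼ)/(t_k−t_{k−1}) +
(x−t_k)₊³ (t_{k−1}−tⱼ)/(t_k−t_{k−1})] / (t_k−t₁)², giving a function
linear beyond the boundary knots with continuous first and second
derivatives. Knots sit at Harrell's fixed heuristic percentiles
(k=3: 10/50/90; k=4: 5/35/65/95; k=5: 5/27.5/50/72.5/95;
k=6: 5/23/41/59/77/95; k=7: 2.5/18.33/34.17/50/65.83/81.67/97.5) of
log intake — the natural log both normalises the right-skewed intake
and magnifies the low-intake region where inflections occur. The knot
count (3–7) is chosen by minimum AIC. Curves report the adjusted
outcome difference relative to a reference intake (default: the
median); spline-basis contrasts cancel the covariates, and pointwise
bands use the delta method on the spline-coefficient covariance.

## Gene–environment interaction

The PRS is Σᵢ β̂ᵢ × dosageᵢ with dosages flipped (2−d) where the counted
allele differs from the weight file's effect allele, mean-imputed per
variant when missing, and standardised to mean 0 / SD 1 within the
scoring cohort. The headline interaction test adds a single continuous
intake × PRS product term to the maximally adjusted model (with both
main effects), making inference invariant to affine PRS rescaling.
Quintile-stratified per-SD effects are descriptive; quintiles are formed
on the analysis subset actually modelled. Covariate × PRS and
covariate × intake product terms are not included by default — the
single-product construction is the common epidemiological choice — but
the covariate list is extensible if interaction-test robustness to
confounder-by-gene structure is a concern.

## Mendelian randomization

With per-variant exposure betas bₓ (SE sₓ) and outcome betas b_y (SE
s_y), weights w = 1/s_y²:

* **IVW**: θ̂ = Σw bₓ b_y / Σw bₓ², SE² = 1/Σw bₓ², inflated by
  √max(1, Q/(n−1)) under the default multiplicative random-effects
  model (fixed-effect by flag); Cochran's Q = Σw (b_y − θ̂bₓ)² with I² =
  max(0, (Q−(n−1))/Q). One variant reduces to the Wald ratio b_y/bₓ
  with first-order SE s_y/|bₓ| (second-order option adds
  b_y²sₓ²/bₓ⁴).
* **MR-Egger**: weighted regression with intercept after orienting all
  bₓ > 0; slope is the causal estimate under InSIDE, the intercept
  tests average directional pleiotropy. Inference uses standard WLS
  overdispersion (φ = Q/(n−2), unfloored) with t(n−2) quantiles, which
  makes the intercept test exactly calibrated in the well-specified
  case. I²GX = (Q_GX − (n−1))/Q_GX with Q_GX = Σ(bₓ−b̄ₓ)²/sₓ² measures
  regression dilution from exposure-beta error.
* **Weighted median**: the 50% point of the weighted empirical quantile
  function of the Wald ratios (cumulative standardised weights
  sⱼ = (Σ_{i≤j}wᵢ − wⱼ/2)/Σw, linear interpolation at 0.5) with
  inverse-ratio-variance weights; SE by parametric bootstrap (1000
  draws, seeded), consistent while valid variants hold > 50% of weight.
* **Weighted mode**: argmax of a normal-kernel weighted density of the
  ratios on a 512-point grid spanning the ratios ± 3 bandwidths;
  bandwidth = φ × 0.9 × min(SD, MAD/0.6745) × n^(−1/5) (modified
  Silverman), φ = 1 by default; degenerate all-equal ratios return that
  value directly; bootstrap SE.
* **MR-PRESSO**: observed weighted RSS of each variant against its
  leave-one-out IVW prediction, compared to parametric simulations under
  the no-pleiotropy model. The global p uses the (+1)-corrected
  exceedance fraction; per-variant outlier tests use the plain
  exceedance fraction (so an observation beyond every simulation can
  clear Bonferroni correction at any panel size), Bonferroni-corrected
  at 0.05. The corrected estimate is the IVW on retained variants —
  reported only when outliers are detected — and the distortion p
  compares the observed correction against corrections from removing
  random variant subsets of the same size.
* **Multivariable MR**: weighted no-intercept regression of b_y on both
  exposure-beta columns jointly (e.g. alcohol plus a smoking-initiation
  proxy), reporting the primary coefficient with overdispersion-inflated
  SE.

Harmonisation inner-joins on variant id, sign-flips outcome betas where
the allele pair is swapped, and drops strand-ambiguous (A/T, C/G)
variants; results are ordered by variant id so input order is
irrelevant. The restricted instrument differs from the full instrument
only by the configured exclusion list (e.g. rs1229984, the ADH1B
variant whose direct tissue-toxicity pathway can violate the exclusion
restriction).

Real consortium summary files in the same 7-column dialect (snp_id,
effect_allele, other_allele, beta, se, pval, n) can be fed directly to
the `mr` CLI; LD clumping, proxy lookup and Steiger filtering are out of
scope.

## Synthetic-data generator

The generator's purpose is parameter recovery: every configured effect
should be recoverable by the downstream pipeline, so each default
encodes the study conditions being emulated.

* **Covariates** are drawn from marginal distributions (normals for
  age/BMI/height/SBP/Townsend/spherical equivalent/physical activity,
  categorical draws for sex/ethnicity/smoking/season/diabetes) — only
  marginal summaries are available to calibrate against, so covariate
  correlations are not modelled.
* **Intake** is log-normal among regular drinkers, median 91 g/week,
  with σ = 0.88 chosen so the SD after the 1/1 trim is ≈ 111 g/week
  (the population on which the per-SD unit is defined); the top
  quintile's median then falls near 280 g/week. Infrequent drinkers
  get a low-median (≈ 2.8 g/week) log-normal. Integer portion counts
  over sparse random beverage mixes realise each target, so some low
  monthly targets legitimately round to zero portions — exactly the
  implausible reports the 1-percentile trim removes. Category
  probabilities default to (never, infrequent, regular, former) =
  (0.048, 0.119, 0.797, 0.036).
* **Confounding** enters as a shared score Σ λ_c z_c of standardised
  covariates (default λ = 0.05 on age, BMI, SBP, male sex, current
  smoking) added to both log intake and every outcome, so unadjusted
  estimates are biased and adjusted ones are not.
* **Continuous outcomes** follow baseline + category contrast +
  per-SD effect × standardised intake (+ interaction × intake × PRS for
  IOP) + confounder score + Gaussian noise. Defaults: per-SD effects
  +0.08 mmHg (IOP), −0.17 μm (mRNFL), −0.34 μm (mGCIPL); category
  contrasts vs infrequent drinkers include +0.17 mmHg (regular, IOP)
  and −0.15 mmHg (former, IOP). Crucially, the standardised intake in
  these equations is computed by the *same* code path the analysis
  uses (portions → grams → trim → z-score), so recovery is exact in
  expectation rather than attenuated by trimming conventions. An
  optional change-point turns the exposure term into a hockey stick
  (flat below a threshold in g/week) for testing nonlinear recovery.
* **Interaction** defaults to 0.05 mmHg per SD intake per SD PRS. Since
  the mean of a standard normal above its 80th percentile is
  φ(z₀.₈)/0.2 ≈ 1.40, the implied top-quintile per-SD IOP effect is
  0.08 + 0.05 × 1.40 = 0.15 mmHg and the bottom quintile's is ≈ 0.01 —
  a graded profile across quintiles.
* **Glaucoma** is Bernoulli with logit = α + category log-OR (never
  1.23, regular 1.13, former 1.53) + log(1.11) × standardised intake +
  confounders; α is solved numerically (Brent) each draw so realised
  prevalence matches the 1.8% target exactly in expectation.
* **Measurements**: participant values split into two eyes with small
  per-eye noise and configurable missingness; treated participants'
  measured IOP is 0.7 × the pretreatment value, so the imputation rule
  inverts it exactly. A 1.2% fraction of IOP readings is replaced by
  implausible extreme values: the 0.5-percentile trim exists to remove
  device artifacts, and planting them means the trim removes artifacts
  rather than clipping genuine Gaussian tails (which would attenuate
  the per-SD slope by ≈ 7.5%, the variance deficit of a ±2.58σ
  truncated normal).
* **Diagnosis records**: true cases carry self-report only / codes only
  / both (25/35/40%), with qualifying codes dated within the window; a
  small fraction of controls carries suspect codes; 5% of everyone
  carries irrelevant codes; a 0.2% young-diagnosis fraction exercises
  the age exclusion. The PRS is emitted directly as a standard normal
  (the real weight panel being unavailable); a dosage-panel helper
  supports score round-trip testing.
* **Summary statistics**: true exposure effects |β| ~ U(0.008, 0.05)
  per SD with SEs 1/√n_exposure (all genome-wide significant at the
  default n = 941 280); outcome betas are θ × true exposure beta plus
  optional balanced/directional pleiotropy, planted outlier shifts and
  noise with SE ≈ outcome SD/√n_outcome. The ADH1B-like flagged
  variant gets 5 × the median effect magnitude and the id rs1229984. A
  separate truth seed lets replicates share truth while varying
  sampling noise; a noise-scale knob gives exact noiseless limits. The
  default scenario encodes the mGCIPL experiment: 80 variants,
  θ = −1.52 μm per SD, outcome n = 31 434. SNPs are independent (no
  LD) by construction.

One integer seed drives all randomness through a single generator.

**What passing tests do and do not show.** Parameter recovery on this
generator demonstrates that the estimators are correct for their model
classes, not that real questionnaire data satisfy those models: real
cohorts have correlated covariates, non-log-normal and misreported
intake, differential missingness, LD between instrument variants, and
selection effects, none of which are emulated. Conversely, failures of
the IV assumptions (pleiotropy, weak instruments) can be simulated here
but their real-world prevalence cannot.

## Numerical choices

* Percentile convention everywhere: linear interpolation between
  closest ranks (numpy default); strict-inequality exclusion at trim
  bounds.
* Standardisation uses the population (ddof = 0) SD; z-scores are
  computed on the included subset and applied affinely to all rows.
* Logistic fits: Newton, max 100 iterations; BFGS fallback (500
  iterations) when Newton fails to converge or hits a singular Hessian,
  as happens with rare outcomes and many parameters.
* Rank deficiency is detected by matrix rank and reported with the
  offending columns from the QR diagonal.
* Bootstrap and simulation counts default to 1000 (MR-PRESSO null
  draws, median/mode bootstraps); all seeded.
* IVW p-values use normal quantiles; Egger and multivariable MR use
  t(n−2).
* Degenerate inputs are errors, not warnings: all-missing trim vectors,
  constant PRS, zero exposure betas, empty instruments, collinear MVMR
  exposures.

## Problem sizes

The default test suite exercises cohorts of 6 000–50 000 and three
100 000-participant recovery cohorts; operating-characteristic suites
use 1000 null replicates. The acceptance script averages sixteen
100 000-participant replicates per cohort quantity and sixteen 80-SNP MR
replicates — sizes at which Monte-Carlo error is a few percent of each
target while a full run stays within a minute on one CPU.

## Known limitations

* The beverage table is a stand-in; absolute gram values shift with the
  true food-composition entries (category assignment and per-SD results
  are insensitive to moderate changes).
* Goldmann-correlated IOP, visual-field grading, 24-hour dietary
  recall, LD-aware instrument construction and real-data replication of
  the MR experiments are out of scope.
* The MR-Egger intercept test's exact calibration assumes the reported
  outcome SEs are correct; with misspecified SEs the unfloored
  overdispersion can under- or over-cover.
* The distortion-test null (random same-size removals) is a pragmatic
  reading of the published procedure; supplementary implementation
  details of the original are not public in this packaging.
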
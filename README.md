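# alcogla

Analysis toolkit for studying the association between habitual **alcohol
consumption** and **glaucoma-related traits** — intraocular pressure
(IOP), macular inner-retinal OCT thicknesses (mRNFL, mGCIPL) and
prevalent glaucoma — in biobank-style cohort data, together with a
from-scratch **two-sample Mendelian randomization** (MR) suite for
probing causal effects with GWAS summary statistics.

It is aimed at epidemiologists and statistical geneticists who want a
tested, reusable implementation of this analysis design, and ships a
synthetic-data module that emulates the relevant cohort structure so the
entire pipeline is runnable and testable without any restricted data
access.

## What it implements

**Exposure quantification.** Six-beverage drinking-questionnaire
responses are mapped to drinker categories (never / infrequent /
regular / former) and converted to grams of ethanol per week:

    grams/week = Σᵢ portionsᵢ × volumeᵢ(mL) × concentrationᵢ(g/mL) × k

with k = 1 for weekly reporters and k = 12·7/365 ≈ 0.23 for monthly
reporters. Estimates in the top and bottom 1 percentiles are trimmed,
and intake is expressed per SD for dose-response models. Helpers convert
grams to UK units (8 g) / US standard drinks (14 g) and to guideline
ceilings (UK 112 g/week; US 98 women / 196 men g/week).

**Phenotype derivation.** Corneal-compensated IOP as the mean of
available eyes with pretreatment imputation (measured/0.7 for users of
ocular hypotensives), surgical-history exclusions and 0.5-percentile
trimming; OCT layer means; glaucoma case/control status from self-report
plus ICD codes (ICD-10 H40.* excl. H40.0, H42.*; ICD-9 365.* excl.
365.0) within a window ending 1 year after baseline, excluding
young-onset cases and suspect/treated controls.

**Association models.** Two-step design: categorical contrasts against
an infrequent-drinker reference, then dose-response among regular
drinkers only — per-SD effects, quintile contrasts with a median-based
trend test, and restricted cubic splines of log intake (Harrell
percentile knots, 3–7, minimum-AIC selection). Thirteen standard
adjustment covariates; OLS and maximum-likelihood logistic fits with
Wald intervals, plus a sensitivity-analysis harness (sex stratification
and interaction, subgroup restriction, beverage type, extra covariates,
glaucoma exclusion).

**Gene-environment interaction.** A weighted-sum polygenic risk score
(PRS), standardised to mean 0 / SD 1, tested as a multiplicative
intake × PRS product term in the maximally adjusted model, with per-SD
intake effects reported within PRS quintiles.

**Mendelian randomization.** Harmonisation of exposure/outcome summary
statistics, full vs restricted instruments (e.g. excluding the ADH1B
variant rs1229984), and estimators written from first principles: Wald
ratio, IVW (fixed / multiplicative random effects with Cochran's Q and
I²), MR-Egger (with intercept test and I²GX regression dilution),
weighted median, weighted mode, MR-PRESSO (global, outlier and
distortion tests) and multivariable MR.

**Synthetic data.** `alcogla.synthetic` generates cohorts with realistic
covariate marginals, log-normal intake (median ≈ 91 g/week, post-trim
SD ≈ 111 g/week), configurable exposure effects, confounding,
intake × PRS interaction and a calibrated ≈ 1.8% glaucoma prevalence,
plus per-SNP GWAS summary statistics under a causal model with optional
pleiotropy and outliers. See `docs/methods.md` for the generative models
and their limitations.

## Worked example

```python
from alcogla.synthetic import CohortConfig, SummaryConfig, generate_cohort, generate_summary_stats
from alcogla.pipeline import build_analysis_table
from alcogla.association import per_sd_analysis, categorical_analysis
from alcogla.gxe import interaction_analysis
from alcogla.mr import harmonize, build_instrument, run_mr_battery

cohort = generate_cohort(CohortConfig(n_participants=50_000, seed=7))
table = build_analysis_table(cohort)

iop = per_sd_analysis(table, "iop")
former = next(r for r in categorical_analysis(table, outcomes=("glaucoma",))["glaucoma"]
              if r.term == "category_former")
gxe = interaction_analysis(table, "iop")

scenario = generate_summary_stats(SummaryConfig(seed=11))
inst = build_instrument(harmonize(scenario.exposure, scenario.outcome), p_threshold=1.0)
mr_results = run_mr_battery(inst, ("ivw", "egger"), seed=11)
```

prints (via the corresponding f-strings):

```
per-SD IOP effect: 0.103 mmHg (95% CI 0.069 to 0.137), n=37765
former vs infrequent glaucoma OR: 1.74 (95% CI 1.23 to 2.47)
intake x PRS interaction p = 1.07e-02; per-SD IOP effect in PRS Q5: 0.202 mmHg
ivw_multiplicative_random: -1.54 (95% CI -1.75 to -1.34), p=8.09e-48
egger: -1.25 (95% CI -1.65 to -0.85), p=2.83e-08
```

Each additional SD of weekly intake (~111 g) is associated with ~0.1
mmHg higher IOP in this 50 000-participant simulation; former drinkers
show higher glaucoma odds than infrequent drinkers; the alcohol–IOP
association strengthens with polygenic glaucoma risk; and the IVW
estimate recovers the simulated causal effect of alcohol on mGCIPL
thickness (−1.52 μm per SD) from 80 independent variants.

The same stages are available from the shell:

```bash
alcogla simulate cohort --seed 7 --n 50000 --out sim
alcogla derive outcomes --cohort sim.participants.tsv --dx sim.diagnoses.tsv --out table.tsv
alcogla associate --cohort table.tsv --outcome iop --step quantitative --out iop
alcogla simulate sumstats --seed 11 --out ss
alcogla mr --exposure ss.exposure.tsv --outcome ss.outcome.tsv --exclude rs1229984 --out mr
alcogla run --out results_dir   # full pipeline with a manifest
```

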
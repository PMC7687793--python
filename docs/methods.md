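# Methods

This note documents the models, conventions and simulation design behind
`ewasmeta`, and what the packaged synthetic data can and cannot show.

## Phenotype construction

BMI (kg/m²) is standardized to sex- and age-adjusted SD scores with the
LMS method: z = ((y/M)^L − 1)/(L·S), where L (Box–Cox power), M (median)
and S (coefficient of variation) are read from a reference table and
interpolated **linearly in age** within sex; published growth references
do not always state their interpolation rule, so linear is the documented
choice here.  |L| < 1e−8 switches to the logarithmic limit z = ln(y/M)/S.
The transform is inverted exactly (y = M(1 + L·S·z)^{1/L}), and the
round-trip is tested to 1e−9 across L ∈ [−3, 3], S ∈ (0, 0.3].

Weight status uses age/sex-interpolated BMI cutoff tables in the IOTF
layout.  A BMI exactly at a cutoff receives the category the cutoff names
(deterministic tie rule; for the underweight cutoff this means the
boundary belongs to underweight).  The binary outcome codes
overweight+obesity as cases and normal weight as controls; underweight
children are excluded, and a cohort with ≤ 10 members in either group is
ineligible.  The overweight-prevalence flag is strict: a cohort is flagged
only when the fraction, computed after excluding underweight children,
exceeds 0.30.

The packaged reference tables (`data/*_synthetic.csv`) are **synthetic**:
smooth curves with a childhood adiposity-rebound dip in M, L ≈ −1.6 and S
rising with age, with cutoffs placed at fixed z-scores (−1.88, +1.31,
+2.00) of the same curves.  They make the pipeline self-contained; real
LMS/IOTF tables can be supplied as CSV files in the same layout.

Puberty is dichotomized as early (both Tanner stages ≤ 3 and no
menarche/voice change) versus late (anything else), and the measurement
selector picks the oldest age inside a closed window [min, max] at which
BMI and methylation are both available.

## Probe quality control

The per-CpG outlier rule removes beta values outside
[Q1 − 3·IQR, Q3 + 3·IQR], with quartiles computed **once** on the input
by linear interpolation between order statistics (the common statistical
convention; configurable).  Removed values become missing — the sample is
retained for other probes — and probes with fewer than 4 non-missing
values are skipped with a warning.  Filtering is applied per cohort,
before modeling.

Manifest-driven filtering excludes probes measured in only one study,
probes on X/Y, and cross-reactive probes; SNP/INDEL/repeat probes are
retained but flagged through to the result files.  Probes present in the
data but missing from the manifest are retained with an `unannotated`
flag rather than silently dropped.

## Cohort-level models

Continuous BMI-SDS is fit per CpG with Huber robust regression:
iteratively reweighted least squares, tuning constant 1.345 (95% Gaussian
efficiency), residual scale from the normalized median absolute
deviation (rescaled each iteration), convergence when coefficients change
by < 1e−8 or after 50 iterations, and standard errors from the standard
M-estimator asymptotic covariance.  The fits are performed by
statsmodels' RLM with exactly these settings.  Non-converged probes are
recorded with `converged = False` and excluded from pooling.

The binary outcome uses maximum-likelihood logistic regression; complete
separation is caught and recorded as non-convergence.  Odds ratios are
reported with 95% Wald CIs, whose geometric mean equals the OR by
construction.

Covariate adjustment sets follow the four analysis models: the
cord-blood models (A, B) adjust for maternal age, education, smoking,
pre-pregnancy BMI, parity, gestational age, batch and six estimated cell
type proportions (one dropped to avoid the sum-to-one collinearity); the
cross-sectional childhood model (C) adds birth weight and breastfeeding;
the adolescent model (D) adds sex, age, own smoking and puberty status.
Complete cases on the model's covariates are selected once per model;
per-probe sample sizes then vary only with probe-level missingness.
Within a cohort, ethnic strata can be analyzed separately and enter the
meta-analysis as separate units.

Coefficients are estimated on the native beta scale (0–1) and rescaled to
"per 10% methylation" (× 0.1) only at the reporting stage, so cohort
summary files remain on one consistent scale.

## Meta-analysis

Fixed-effects inverse-variance weighting, with P values from the
standard-normal tail of z = β̂/SE (not a t reference), matching common
consortium practice.  Heterogeneity is Cochran's Q with
I² = max(0, 100(Q − (k−1))/Q), flagged when strictly above 50.
Leave-one-out re-pools with each cohort removed.  Probes reported by
fewer than two cohorts are excluded in consortium mode (single-cohort
pooling exists for unit tests).  Bonferroni uses 0.05/m and BH operates
over exactly the analyzed probe set of the model at hand, so m is
model- and subset-specific.  Reporting ties in P are broken by CpG id.
Sensitivity subsets (Europeans-only, ≤ 30% overweight, conservative) drop
whole cohorts before pooling and recompute the probe universe.

## Prior-set comparison

Look-up replication uses a per-source Bonferroni cutoff
0.05/(CpGs tested in that source); prior CpGs absent from the analyzed
universe are reported as untested, never as failures.  Enrichment is the
exact one-sided hypergeometric upper tail P(X ≥ k) with universe N equal
to the analyzed-probe count (the default; K can instead be restricted to
the intersection with the universe).  Effect concordance is Pearson
correlation with the two-sided t test on n − 2 df; correlation
differences use the Fisher r-to-z normal test — the package deliberately
implements r-to-z for comparing two correlations even where the
literature sometimes labels such comparisons "exact" tests, because it is
the standard large-sample procedure for independent correlations.  The
2×2 overlap test is Pearson chi-square without continuity correction
(with-correction available by flag); note the statistic is discrete, so
its null P values are only approximately uniform.

## Synthetic consortium design

The generator's defaults define the study conditions used by the tests
and the acceptance script.

* **Betas.**  logit(β) = μ_p + batch shift + σ_p·ε, inverse-logit back to
  [0, 1].  Probe means come from a three-component mixture
  (30% unmethylated at μ ≈ −2.5, 40% intermediate, 30% methylated at
  μ ≈ +2.5; σ_p ≈ 0.3–0.5), giving 450K-like bimodal marginals.  Batch
  shifts are N(0, 0.08) per probe×batch.
* **Samples.**  Ages uniform in the configured window; covariates drawn
  with conventional demographic distributions (maternal BMI N(24, 4),
  smoking 20%, gestational age N(39.5, 1.5) with correlated birth weight,
  breastfeeding 70%, Tanner stages increasing in age, menarche/voice
  logistic in age around 13 y); cell proportions Dirichlet with
  granulocyte-dominated concentration (7, 12, 15, 55, 3, 8).
* **Outcome.**  BMI-SDS = covariate effects (maternal BMI 0.04/unit,
  smoking +0.20, birth weight 2×10⁻⁴/g, breastfeeding −0.10; all
  centered) + N(0, 0.9), clipped to ±3.5 SDS to stay inside the LMS
  invertible branch, then back-transformed to raw BMI.
* **Causal modes.**  `meth_to_bmi` adds Σ effect·(β − β̄) to BMI-SDS; the
  planted contribution is centered at the cohort mean so planted effects
  change the slope without relocating the cohort's BMI distribution.
  `bmi_to_meth` shifts logit(β) at planted probes by
  schedule(age)·effect·BMI-SDS, with the age schedule interpolated
  linearly between knots — an age-accumulating methylation mark of
  adiposity.  `null` has no probe–BMI dependence.
* **Reproducibility.**  Each cohort uses
  `SeedSequence(master_seed, spawn_key=(cohort_index,))`; probe-level and
  manifest parameters use reserved spawn keys.  Adding a cohort therefore
  never changes earlier cohorts, and identical configs are bitwise
  reproducible.
* **Overweight targeting.**  When a target prevalence is set, the cohort
  BMI-SDS intercept is shifted by bisection until the classified
  overweight+obesity fraction (excluding underweight) is within ±2% of
  target.
* **Missingness** is injected completely at random at a configurable rate
  (default 0).

What the simulation does **not** emulate: probe type (I/II) chemistry,
normalization artifacts, mQTL/genetic structure, cell-type-driven
confounding (cell proportions are covariates but do not influence the
outcome), cohort-specific ancestry effects on methylation, and
measurement-error heteroscedasticity.  Passing calibration and recovery
tests therefore demonstrates the statistical machinery is correct under a
clean generative model, not that real-data artifacts are handled.

## Problem sizes and numerical choices

The calibration study uses 3 cohorts × 300 children and 5000 probes —
large enough that the genomic inflation factor's Monte-Carlo noise
(sd ≈ 0.03 at 5000 probes) is small against the [0.9, 1.1] acceptance
band.  Effect recovery plants 5 CpGs of effect 2.0 BMI-SDS per unit beta
in 4 cohorts × 500; planted probes are configured as intermediately
methylated, high-variance probes (μ = 0, σ_logit = 1), as BMI-associated
CpGs in blood typically are — low-variance extreme probes would carry
almost no information at this n.  The age-trend study uses three windows
(2–5, 5–10, 12–18 y) with 2 cohorts × 250 and a 50-CpG planted set whose
effects are N(0.35, 0.1) in magnitude with random signs, under a schedule
rising from 0.1 (age 2) to 1.0 (age 18).

Numerical conventions worth knowing: quantiles interpolate linearly;
Huber scale is MAD/0.6745; meta P values come from the normal, cohort
robust-fit P values likewise (Wald); BH is computed by the step-up
formula and verified against a brute-force oracle; hypergeometric tails
are exact log-space summations (no normal approximation); the genomic
inflation factor is median(χ²)/0.454936.  Degenerate inputs (rank
deficiency, separation, all-missing probes, zero-variance effect vectors,
empty prior sets) raise or are skipped with recorded reasons rather than
propagating NaNs.

## Known limitations

* Cell-type deconvolution is not implemented; proportions are consumed as
  given (simulated or user-supplied).
* Random-effects meta-analysis, meta-regression and sample-size-weighted
  pooling are out of scope.
* The packaged growth reference is synthetic; analyses of real data must
  supply a real LMS reference and cutoff table.
* The robust-regression weight function and SE estimator used by any
  particular consortium cohort may differ from the Huber/asymptotic
  default documented here; the choice is recorded in output file headers.
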
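# Methods

This note documents the statistical models implemented in `vgxe`, the
assumptions behind the synthetic cohort generator, the numerical choices
made where several were defensible, and the limits of what the test suite
demonstrates.

## The analysis in one paragraph

A *mean* polygenic score (mPGS) aggregates per-variant effects on the level
of a phenotype, `PGS_i = Σ_j β_j x_ij`, where `x_ij` counts effect alleles.
A *variance* polygenic score (vPGS) aggregates per-variant *dispersion*
effects — contributions to the phenotype's conditional variance that are not
driven by mean effects — and is interpreted as a genetic index of phenotypic
plasticity.  The package (1) trains per-variant dispersion weights with a
per-SNP double-GLM scan on a training split, (2) scores a held-out cohort
and validates the vPGS by fitting a double generalized linear model (DGLM)
of inverse-normal-transformed BMI, (3) estimates the effect of an exogenous
job-loss shock (business closure) on BMI and its moderation by both scores
using a propensity-score kernel-matched difference-in-differences (DiD)
regression, and (4) probes the parallel-trends assumption with an event time
study (ETS).  Everything runs end to end on a synthetic longitudinal cohort
with known truth.

## Double generalized linear model

The DGLM couples a linear mean submodel with a log-linear variance submodel:

    y_i = γ0 + γ1 g_i + X_i Θ + ε_i,     ε_i ~ N(0, exp(α0 + α1 g_i + X_i Φ))

`α1` is the parameter of interest: `100·(√exp(α1) − 1)` is the percent
change in the phenotype SD per unit of the (standardized) score.  Estimation
alternates (a) weighted least squares for the mean submodel with weights
`exp(−z_i'α)` and (b) a gamma GLM with log link fitted to the
leverage-adjusted squared residuals `e_i²/(1−h_i)` with prior weights
`(1−h_i)/2` — the standard REML-flavoured algorithm for this model class.
With those prior weights and the gamma dispersion fixed at 1, the covariance
of the dispersion coefficients is `2(Z'diag(1−h)Z)^{-1}`, the Fisher
information of the log-variance model; Monte Carlo confirms calibration
(95% CI coverage 95% over 200 replicates at n = 5,000, and the Wald SE
matches `√(2/n)` for a standardized score).  Iteration stops when the
extended log-likelihood moves by less than 1e-8 (observed: 3–5 iterations);
non-convergence returns a flagged result rather than raising.

Numerical notes: squared residuals are floored at 1e-300 before the log
link; the variance linear predictor is capped at ±500 and a diverging fit
raises; a singular design raises with the collinear column names; the fit
reduces exactly to OLS when the variance submodel is intercept-only (tested
to 1e-8).

The per-variant dispersion scan runs this DGLM once per variant with the
dosage as the score — an unrelated-sample simplification of mixed-model
dispersion estimation (no kinship random effects, no meta-analysis across
relatedness strata).  Variants below a MAF floor (default 0.01) or
monomorphic in the sample are skipped and counted.  Null calibration
(uniform dispersion p-values, KS p > 0.01 over 100 null variants) and power
(p < 1e-3 for a planted α = 0.3 at n = 20,000) are asserted in the suite.

Inverse normal transform: rank-based with the Blom offset,
`z_i = Φ⁻¹((r_i − 3/8)/(n + 1/4))`, average ranks for ties.  Blom's 3/8 is
a convention choice; any offset in [0, 0.5] gives nearly identical z-scores
at the sample sizes used here.

## Scores

`compute_pgs` sums `weight × dosage-of-effect-allele` over the variants
shared between the weight table and the genotype matrix.  If a weight's
effect allele matches the genotype file's *other* allele the dosage is
flipped to `2 − x`; if neither allele matches, the variant is skipped with a
warning and counted.  Scores are standardized with the sample SD
(denominator n−1).  Greedy LD clumping (keep by ascending p-value, drop
within-window variants with r² above threshold, ties broken by
(p, chromosome, position, id)) operates on a supplied r² table; the package
does not compute LD from a reference panel, and the synthetic generator
draws variants independently, so clumping is exercised on synthetic
r²/position data only and is off by default in the pipeline.

The mPGS growth-curve validation is a transparent two-stage stand-in for a
multilevel growth model: per-person OLS of BMI on age and age² (age centered
at the sample mean, so the intercept is expected BMI at the average age;
persons with fewer than three observations are excluded and counted), then
cross-sectional OLS of the intercepts on the score plus covariates,
reporting the score's incremental R².  On the default synthetic cohort the
mPGS adds ~9% of intercept variance, inside the 5–10% range typical of
BMI mean scores in European-ancestry cohorts.

## Matching

The propensity model is a probit fitted by Newton scoring.  Covariates with
missing values are recoded to zero plus a missing-indicator dummy, so
matching is on observed values and on the missingness pattern; collinear
columns are dropped and reported.  Treated observations outside the closed
interval `[min, max]` of control propensity scores are trimmed.  Kernel
weights follow

    w(i,j) = K[(P_j − P_i)/b] / Σ_{m: control} K[(P_m − P_i)/b]

with the Epanechnikov kernel `K(u) = 0.75(1 − u²)` on [−1, 1], sums
restricted to controls in the same exact-match stratum (survey year × sex),
matching with replacement.  Per-control aggregates `W_j = Σ_i w(i,j)` enter
the outcome regression unrenormalized (a renormalization flag exists).

**Bandwidth.**  The conventional fixed bandwidth of 0.06 is kept
available, but the package default is Silverman's rule on the control
scores, `b = 0.9·SD(P_c)·n_c^{−1/5}`.  The reason is a bias, not a bug: with
a rare treatment the control propensity density decays steeply near zero,
and kernel smoothing bias grows like b² times the log-density slope.  At
b = 0.06 the matched control mean propensity sits a quarter-bandwidth below
the treated mean and the matched standardized bias of strong confounders
plateaus around 20–30% regardless of sample size — the same signature
visible in applied kernel-matching tables that report residual |SB| ≈ 10
on their strongest confounders.  Under the Silverman rule (~0.002–0.01 for
the synthetic cohort) median matched |SB| of the planted confounders falls
to 1–2%.

Standardized bias is `100·(X̄_T − X̄_C)/√((σ²_T + σ²_C)/2)` with the
*average* of the two unmatched group variances in the radical (a difference
of variances inside the square root, occasionally seen in print, is
dimensionally untenable and treated as a typo), and the matched row
re-uses the unmatched variances so the two rows are comparable.  Balance
tables report Welch t-tests (weighted control moments with an effective
sample size for the matched row), variance ratios for continuous covariates,
and a flag at |SB| > 5 or p < 0.05.

## Difference-in-differences and ATT by genotype

The outcome regression is weighted least squares of post-period BMI on the
closure indicator, both scores, both interactions, lagged BMI and baseline
covariates (treated weight 1, control weight `W_j`; zero-weight rows dropped
and counted), with an HC1 sandwich covariance.  Because the model is linear,

    ATT(m, v) = λ + ϑ·m + δ·v

exactly, with a delta-method SE from the robust covariance; predicted BMI at
a score profile holds all other regressors, including lagged BMI, at their
weighted analytic-sample means (the profile is a reporting choice, exposed
as an argument).  Benjamini–Hochberg adjustment (step-up, adjusted
p = running minimum of `m·p_(k)/k`, capped at 1) covers the headline
coefficient family by default (treatment, scores, interactions, lagged BMI);
`fdr_family="all"` widens it.  Treated persons enter the DiD frame once
(their (t−2, t) pair); controls contribute every consecutive wave pair and
are treated as independent observations by default, with a
cluster-robust-by-person option.

## Event time study

The closure indicator is replaced by event-time dummies
`BC × I(t − t* = y)` for y ∈ {−4, 0, +2} years, with y = −2 (the wave before
the loss) as the omitted reference; the full-sample variant controls for the
vPGS level, and stratified variants split at the analytic-sample vPGS median
(ties to the lower stratum).  Baseline matching weights are reused (the
alternative — re-matching at every event time — is flagged but not
implemented).  Unlike the DiD, the ETS default is *person-clustered* robust
errors: every treated person contributes four serially correlated rows, and
Monte Carlo showed HC1 understating the pre-trend SE by ~12% (92% coverage
of a nominal 95% interval, against 95% when clustered).

Known limitation: with a person-intercept outcome process, the
lagged-outcome specification leaves a small finite-sample bias in the
event-time coefficients (≈ +0.03 BMI units at n = 4,000 in the pre-trend
coefficient, not attributable to calendar or age effects, shrinking within
the coverage tolerance).  The pre-trend diagnostic is therefore asserted at
the CI-coverage level (≥ 93% of replicates cover zero), not as exact
unbiasedness.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, with
every drawn parameter stored exactly in a `TruthRecord`:

- **Genotypes**: independent biallelic dosages, `Binomial(2, maf)` with
  `maf ~ U(0.05, 0.5)` — HWE holds, no LD.  200 variants by default (desk
  scale; the real analyses use 10⁵–10⁶ SNPs).
- **Architecture**: 20 mean-causal and 20 variance-causal variants, disjoint
  sets by default (a flag allows overlap), effects `N(0, 0.1²)` each.  The
  mean architecture puts the mPGS's predictive R² in the published 5–10%
  band; the variance architecture gives a planted dispersion signal strong
  enough for desk-scale power.
- **Phenotype** (for score training/validation):
  `Y = Σβx + ε, ε ~ N(0, exp(α0 + Σαx))`.
- **Panel**: six biennial waves; BMI = person intercept (loaded 1.25 on the
  true mean score, SD 3.2 residual around a mean of 27 kg/m²) + quadratic
  age trajectory + covariate-driven per-wave trend + within-person noise of
  SD 0.9 kg/m² whose log-variance is linear in the true variance score
  (coupling 0.3) — the plasticity channel.  The within-person noise SD is a
  free parameter of the generator (self-reported biennial BMI; ~1 kg/m² is a
  plausible magnitude) and nothing is asserted against it.
- **Treatment**: a probit latent index on covariates *only* (no genotype
  terms), so gene–environment correlation is absent by construction; the
  intercept is calibrated by root-finding so the expected person-level
  treated share matches the target (default 0.10, a realistic person-level share of late-career business
  closures in a biennial panel).  Confounding strength 0.6 reproduces
  unmatched standardized biases of roughly 18–55%, the range such studies
  report before matching.  Each treated person receives one job-loss wave
  (uniform over the waves with a complete event window) and the planted
  effect λ + ϑ·mPGS + δ·vPGS (defaults −0.1, 0, +0.25 BMI units) from that
  wave onward.  Treated persons contribute the (t−2, t) pair to the DiD
  frame; controls contribute all waves.
- **Missingness**: baseline income and tenure are masked MCAR at rate 0.05
  at the person level, exercising the missing-indicator path.
- Seeding: one global seed fans out to per-stage child seeds
  (`numpy.random.SeedSequence.spawn`); identical configuration + seed gives
  byte-identical coefficient outputs.

What the generator does **not** emulate: linkage disequilibrium, ancestry
structure (the "PC" covariates are plain standard normals), survey design,
attrition and mortality selection, measurement error specific to
self-reported BMI, calendar-time shocks, or anticipation effects.  Passing
tests demonstrate that the estimators recover planted truth under the
model's own assumptions — they say nothing about robustness to the listed
real-data complications.

## Problem sizes used by the test suite

Simulation-based checks run at the sizes stated in their docstrings: DGLM
recovery at n = 50,000 (20 replicates) and CI coverage at n = 5,000 (200
replicates); matched-DiD recovery at n = 20,000 (50 replicates); ETS
pre-trend calibration at n = 4,000 (200 replicates) with stratified
detection at n = 8,000 (5 replicates); the dispersion scan at n = 20,000
(planted variant) and n = 5,000 (null calibration).  These sizes are the
package's chosen study conditions for desk-scale verification.
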
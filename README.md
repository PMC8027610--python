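# vgxe

Variance polygenic scores and gene-by-environment causal analysis on
longitudinal BMI, exercised end to end on a synthetic cohort with known
truth.

## The problem

Standard polygenic scores aggregate GWAS effects on the *mean* of a trait
(mPGS).  They miss variants that shape the trait's *variability* — variance
QTLs, which are enriched for gene-by-environment interaction.  A variance
polygenic score (vPGS) built from per-variant dispersion effects indexes an
individual's phenotypic plasticity, and interacting it with a plausibly
exogenous environmental shock (here: job loss from a business closure) asks
whether genetic plasticity moderates the health response to the shock.

`vgxe` implements that full analysis chain for researchers in social-science
genomics and genetic epidemiology:

1. **Scores** — `PGS_i = Σ_j β_j x_ij` over effect-allele dosages, with
   allele flipping, greedy LD clumping, standardization, and a growth-curve
   validation of the mean score.
2. **Variance model** — a double generalized linear model (DGLM)

       y_i = γ0 + γ1 g_i + X_iΘ + ε_i,  ε_i ~ N(0, exp(α0 + α1 g_i + X_iΦ))

   fitted by alternating weighted least squares and a gamma GLM on
   leverage-adjusted squared residuals; a per-variant dispersion scan
   (simplified variance GWAS) trains vPGS weights; the rank-based inverse
   normal transform and the SD-change interpretation
   `100·(√exp(α1) − 1)` are included.
3. **Matching** — probit propensity scores with missing-indicator coding,
   common-support trimming, Epanechnikov kernel matching weights
   `w(i,j) = K[(P_j−P_i)/b] / Σ_m K[(P_m−P_i)/b]` within exact
   (survey-year × sex) strata, and Table-style balance diagnostics
   (standardized bias, Welch t-tests, variance ratios).
4. **Causal** — the kernel-weighted difference-in-differences regression

       BMI_it = α + λ·BC + φ·mPGS + ϑ·BC×mPGS + θ·vPGS + δ·BC×vPGS
                + τ·BMI_it−2 + X′β + ε

   with robust errors, the exact ATT identity `ATT(m,v) = λ + ϑm + δv`,
   Benjamini–Hochberg FDR, and an event time study with vPGS-median
   stratification for pre-trend diagnostics.
5. **Simulate / pipeline** — a synthetic cohort generator (HWE genotypes,
   log-linear variance architecture, biennial BMI panel, confounded
   treatment assignment with no gene–environment correlation) and a
   reproducible end-to-end workflow.

## Worked example

```bash
vgxe run --out demo --seed 7
```

simulates 20,000 individuals × 200 variants, trains dispersion weights on an
80% split, scores and validates the held-out 20%, simulates their BMI panel,
matches, and runs the DiD and event study.  Abridged output from that exact
command:

```
- vpgs_alpha1_model1: 0.18896   (SE 0.02238, p 3.0e-17)
- vpgs_alpha1_model2: 0.20019
- mpgs_incremental_r2: 0.09289
- median_abs_sb_matched: 1.86
- did_lambda: -0.08430
- did_theta_mpgs: -0.00194
- did_delta_vpgs: 0.25681
- ets_below_y+0: -0.28957
- ets_above_y+0: 0.18291
```

Reading it: the trained vPGS carries a real dispersion signal in the held-out
sample (α̂1 = 0.189 — each SD of the score scales the BMI SD by
√exp(0.189) ≈ +9.9% — stable after mPGS adjustment, Model 2); the mean score
explains ~9% of growth-curve intercept variance, inside the 5–10% band
reported for BMI scores; kernel matching repairs the planted confounding
(median matched |SB| 1.9%, against 18–55% unmatched); and the weighted DiD
recovers the planted treatment parameters (truth λ = −0.1, ϑ = 0,
δ = +0.25).  In the event study the below-median-vPGS stratum shows the
theoretical effect at the loss wave (λ + δ·E[v | v<0] ≈ −0.3) while the
above-median stratum's CI covers its near-zero theoretical value —
the stratified G×E pattern the design is built to detect.

Every stage is also available separately (`vgxe simulate | score | vscan |
dglm | match | did | ets`), and as plain functions:

```python
from vgxe import fit_dglm, interpret_sd_change

fit = fit_dglm(phenotype, score)          # alternating WLS + gamma GLM
interpret_sd_change(fit.alpha1)           # % change in SD per score SD
```

## Files

```
src/vgxe/simulate.py        synthetic cohorts with a truth ledger
src/vgxe/scores.py          PGS construction, clumping, growth-curve check
src/vgxe/variance_model.py  DGLM, dispersion scan, inverse-normal transform
src/vgxe/matching.py        probit propensity, kernel weights, balance
src/vgxe/causal.py          weighted DiD, ATT algebra, BH-FDR, event study
src/vgxe/pipeline.py        end-to-end workflow, config, run report
src/vgxe/io.py              .raw / TSV / JSON readers and writers
docs/methods.md             models, assumptions, numerical choices, limits
```
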
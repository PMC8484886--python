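# Methods

## The analysis chain

`twinlate` implements a genetically informed longitudinal analysis of
loneliness and dementia risk in twin cohorts, in five stages:

1. **Phenotypic survival stage.** Cox proportional-hazards regression of
   dementia on baseline loneliness (categorical levels, 0 = reference),
   intake age centred at 60, and their interaction, on the time-on-study
   scale (intake = first loneliness assessment). Ties use the Efron
   approximation; pooled fits use a cluster-robust (by family) variance
   because co-twins are not independent. Hazard-ratio profiles over intake
   age come from the delta method on the linear predictor. A
   zygosity-stratified variant compares low vs high baseline loneliness
   within MZ and DZ subsets; a `within_pair` option additionally stratifies
   the partial likelihood by family (the co-twin control), which removes
   genetic confounding entirely in MZ pairs.

2. **Dementia-risk proxy.** A binary diagnosis cannot enter a multigroup
   Gaussian growth model, so dementia is regressed (logistic ML) on birth
   cohort (decade bands), sex, study, age at first assessment, education,
   occupational status (ISEI), cumulative illness and APOE ε4 count (zero
   fill + missing indicator for the non-genotyped majority), and each
   person's Pearson residual (y − p̂)/√(p̂(1−p̂)) becomes the continuous risk
   score. Quasi-separation falls back to a small ridge (λ = 1e-4 on the
   standardised design) and is flagged. The residual distribution is
   bimodal by construction (cases positive, non-cases negative); it is a
   risk *score*, not a Gaussian variable, which is why robust interpretation
   of downstream SEs is advised.

3. **Latent growth curves.** Loneliness follows a linear or quadratic
   curve in t = (age − 60)/10 with random growth parameters per person
   (intercept–slope covariance free, quadratic variance independent) and a
   level-1 residual. Estimation is marginal ML per person; linear vs
   quadratic is decided by LRT (smaller model unless significant at
   α = 0.05), with AIC/BIC reported (BIC uses ln of the number of persons).

4. **Twin ACE decomposition and biometric regression.** Growth parameters
   decompose into additive-genetic (A), shared-environmental (C) and
   nonshared-environmental (E) scores. MZ pairs share A with weight 1
   (within-family genetic variance 0); DZ genetic variance is split equally
   between a shared and an individual part, so DZ genetic correlation is
   0.5 and total genetic variance is equal across zygosity groups. Implied
   cross-twin covariance of a growth parameter: σ²A + σ²C (MZ),
   ½σ²A + σ²C (DZ); shared environment is wholly between-family, nonshared
   wholly within. The joint biometric model appends each twin's risk score
   to the pair's stacked repeated measures and regresses it on the latent
   components (nine paths: A/C/E × intercept/linear/quadratic), with the
   risk residual variance split into zygosity-specific within- and
   between-family parts. Everything is estimated by direct ML on per-pair
   joint Gaussian likelihoods — the multigroup equivalent of a three-level
   formulation. Method-of-moments estimates (ICCs; Falconer's
   h² = 2(rMZ − rDZ), c² = 2rDZ − rMZ, e² = 1 − rMZ, which sum to 1
   identically and may legitimately be negative) serve as the independent
   cross-check; equality constraints (e.g. A = C machinery) are tested by
   LRT with df equal to the number of independent constraints.

5. **Missing data.** Loneliness non-response is handled by multiple
   imputation with predictive mean matching within study stratum: a linear
   prediction model on time in study, zygosity, sex, birth cohort,
   education, APOE status, illness and the person's mean observed score;
   coefficients redrawn per imputation (proper MI); each missing score takes
   the observed value of one of k = 5 nearest donors, guaranteeing valid
   0–3 categories. δ-adjustment shifts imputed values by a fixed offset
   (clamped to [0, 3], re-rounded) to probe MNAR sensitivity; δ = 0
   reproduces the standard imputation bit for bit under a shared seed.
   m = 50 imputations by default; Rubin's rules pool estimates
   (T = W̄ + (1 + 1/m)B; df capped at 1e8 when B = 0).

## The synthetic-cohort generator

The generator emulates the pooled structure of three longitudinal twin
studies of aging: three study designs with 5–6 waves (inter-wave gaps
[3,3,11,3,3], [3,4,4,4] and [2,2,2,2] years), study mix (0.446, 0.335,
0.219), intake age N(74.75, 8.66²) truncated to [40, 95] with person-waves
capped at age 101, single-sex MZ pairs and opposite-sex DZ pairs in the
second study. Defaults (one choice, fixed):

- Fixed trajectory (β0, β1, β2) = (0.2, 0.02, 0.015) on t — a shallow,
  convex late-life rise.
- Component variances: intercept (σ²A, σ²C, σ²E) = (0.02, 0.05, 0.18)
  (total 0.25; proportions ≈ 0.08/0.20/0.72), linear (0.015, 0, 0.025),
  quadratic (0, 0, 0.004) — i.e. *no between-family variance in the
  quadratic slope*, so its A and C components sit on the estimation
  boundary by design. Level-1 residual σ² = 0.36.
- Ordinal measurement: latent + N(0, 0.36) noise cut at thresholds
  (0.46, 1.28, 2.00), calibrated once so the simulated baseline mean ≈ 0.59
  (SD 0.78) on the 0–3 scale.
- Dementia: logistic in the growth parameters, intake age, APOE count,
  education, illness and sex, intercept −1.58 giving ≈ 25.6% incidence;
  onset N(82.67, 6.29²) truncated above intake; censoring at intake +
  N(14, 6²) years, capped at 101.
- APOE genotypes drawn from the frequencies of the genotyped subsample
  (2/2 0.76%, 2/3 13.93%, 2/4 3.24%, 3/3 56.91%, 3/4 23.11%, 4/4 2.05%;
  2/4 coded as one ε4 allele), shared within MZ pairs, independent across
  DZ co-twins (a simplification: APOE is a covariate here, not a target of
  decomposition); 62.6% missing genotype.
- Risk-score generation (for validation studies): risk = μ + Σ areg·A +
  creg·C + ereg·E + e with all nine paths 0 by default (the null the
  emulated analysis reported) and e split within/between family per
  zygosity.
- Missingness: MCAR/MAR (age, sex)/MNAR (the to-be-deleted score shifted
  by δ) with the mechanism intercept calibrated by root-finding so the
  realised rate matches the requested one; every person keeps ≥ 1 score.

What the generator does **not** emulate: item harmonisation differences
across studies, registry-vs-clinical diagnostic sensitivity, mortality as a
competing risk (censoring is non-informative), assortative mating, and any
within-pair APOE correlation in DZ twins. Passing tests therefore show the
estimators recover the generating process of this idealised design — not
that real registry data satisfy those assumptions.

Ordinal measurement is a coarse, nonlinear filter: variance components
estimated from 0–3 scores are attenuated and mildly distorted relative to
the latent generating values. Estimator-recovery and calibration studies
therefore use the generator's continuous mode (`ordinal=False`), which
records the noisy latent itself; the ordinal default remains the study
condition everywhere else.

## Numerical choices

- **One likelihood engine.** Person-level growth curves, the twin
  decomposition and the joint biometric model all reduce to clusters with
  marginal covariance B K B' + σ²D (+ unit padding); clusters are padded to
  a common size and evaluated as batched linear algebra. Component
  covariance blocks are parametrised by Cholesky factors (full 2×2 for
  intercept/slope, independent quadratic), guaranteeing PSD; residual SD on
  the log scale with a floor at 1e-5 (so exact-interpolation data remain
  finite); risk residual SDs enter squared.
- **Profiled means, analytic gradients.** The fixed effects and the risk
  intercept μ are profiled out by GLS inside every likelihood evaluation
  (their score is then identically zero), and the gradient over covariance
  parameters is computed analytically by backpropagation through the
  implied-covariance assembly — verified against finite differences in the
  test suite. L-BFGS-B with box bounds does the optimisation; a perturbed
  restart guards against line-search failures on degenerate data.
- **Boundary and identification handling.** Variances estimated below 0.5%
  of their parameter's total variance are treated as on the 0 boundary and
  the corresponding regression paths dropped (a quadratic between-family
  variance of zero surfaces exactly this way). After fitting, any
  regression coordinate whose observed-information curvature is numerically
  flat (< 1e-3) is reported as *unidentified* and dropped with a warning
  rather than printed with an arbitrary standard error. Wald SEs come from
  the finite-difference Hessian of the profile likelihood, with flat
  directions conditioned out; for variance parameters near the boundary
  they are approximations and are documented as such.
- **Genetic-path SEs are legitimately enormous.** A and C regressions are
  separated only by the MZ/DZ contrast; at realistic sizes their likelihood
  is nearly ridge-shaped, so their ML estimates can be large in magnitude
  with SEs one to two orders larger still, and their Wald intervals
  essentially always cover. This mirrors the behaviour of such models on
  real twin data and is why calibration checks aggregate over all estimable
  paths rather than reading single genetic paths literally.
- α = 0.05 throughout; LRT prefers the smaller model when non-significant.

## Validation-study problem sizes

Sizes were chosen so the full suite runs on one CPU in well under half an
hour: ACE recovery on 2,000 + 2,000 pairs (single fit); null-coverage of
the biometric regression on 200 replicates of 100 MZ + 300 DZ pairs (a
DZ-heavy mix, because DZ pairs alone carry the A-vs-C contrast) with a
compact 4-wave design and a low-noise risk score; Cox type-I on 200
replicates of 120 pairs; growth-model selection on 200 replicates of 70
pairs. Even under this design the genetic-path Wald intervals remain
somewhat conservative (their aggregate null coverage sits at the top of,
or just above, 95 ± 3%): sharp identification of the A and C paths needs
more pairs than a desk-scale replicate study can afford. The growth-selection LRT is conservative by construction (one of the
two extra parameters sits on the boundary under the null), so its type-I
rate sits near 3% rather than 5%.

## Known limitations

- The biometric likelihood treats the risk score as Gaussian; it is
  bimodal. Point estimates are fine (quasi-ML), but small-sample p-values
  for variance parameters should be read with care.
- Wald inference at variance boundaries ignores the usual mixture
  asymptotics; boundary flags are reported so users can tell.
- PMM with δ-adjustment applies the shift post hoc on the imputed ordinal
  values; δ on the latent predictor scale is not implemented.
- The two-stage biometric option fixes the growth/ACE covariance structure
  at its decomposition estimates and so understates uncertainty slightly
  relative to the joint fit.
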
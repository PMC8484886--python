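# twinlate

Genetically informed longitudinal analysis of **loneliness trajectories and
dementia risk** in twin cohorts.

Older adults report more loneliness as they age, and loneliness has been
linked to dementia — but both are heritable and both track age, so the
association may reflect *selection* (shared genetic or family-environment
liability) rather than *causation*. Twin data can separate the two: in
monozygotic (MZ) pairs, genetic and shared-environment confounds are held
fixed within the pair, so any remaining association must travel through
nonshared-environmental pathways. `twinlate` implements that full analysis
chain for long-format longitudinal twin data, plus a synthetic-cohort
generator with known truth, so every estimator can be validated end to end.

## The model

Loneliness is a single ordinal item (0–3, higher = lonelier) measured over
up to six waves. Each person's latent trajectory is quadratic in centred
age, t = (age − 60)/10:

    y_it = π0_i + π1_i t + π2_i t² + ε_it

Each growth parameter decomposes across twins i in family j into additive
genetic (A), shared environmental (C) and nonshared environmental (E)
component scores:

    π_ij = β + A_ij + C_j + E_ij

with MZ pairs sharing A entirely and DZ pairs splitting its variance
equally between a shared and an individual part (cross-twin covariance
σ²A + σ²C in MZ, ½σ²A + σ²C in DZ; Falconer's h² = 2(rMZ − rDZ),
c² = 2rDZ − rMZ, e² = 1 − rMZ give the moment version). Dementia risk is a
continuous proxy — the Pearson residual (y − p̂)/√(p̂(1−p̂)) from a logistic
regression of diagnosis on covariates — and the **biometric regression**

    Risk_ij = μ + Σ_k (areg_k A_kij + creg_k C_kj + ereg_k E_kij) + e_ij

asks whether loneliness level and change predict dementia risk through
quasi-causal (E) or selection (A, C) pathways. Estimation is direct maximum
likelihood on per-pair joint Gaussian likelihoods (the multigroup equivalent
of a three-level model), with Cox proportional-hazards models for the
phenotypic survival analysis and predictive-mean-matching multiple
imputation (with δ-adjustment sensitivity analysis) for missing scores.

## A worked example

```python
import twinlate as tl

cfg = tl.SimConfig(n_pairs_mz=350, n_pairs_dz=500, seed=42)
cohort, truth = tl.simulate_cohort(cfg)

print(tl.summarize_cohort(cohort))
# n_individuals=1700, n_pairs=850, pct_dementia=27.2,
# mean_baseline_loneliness=0.59 (SD 0.80), mean_last_loneliness=0.84,
# paired_t_statistic=10.83, mean_intake_age=75.6

vc = tl.fit_twin_decomposition(cohort)
print(vc.iccs().round(3))
#            icc_mz  icc_dz
# intercept   0.365   0.319
# linear      0.073   0.042
# quadratic   0.546   0.273
print(vc.dropped)
# [('C', 'quadratic')]  <- shared-environment curvature on the 0 boundary
```

The baseline mean near 0.6 on the 0–3 scale says most people report little
loneliness; the paired t ≈ 10.8 says loneliness rises with age on average;
MZ ICCs above DZ ICCs indicate familial (largely genetic) variance in
loneliness level; and a component reported in `dropped` sat on the zero
boundary, so its regression path would be unidentified downstream. The scripts in `examples/` walk through
each capability (Cox hazard profiles, the risk proxy, the biometric
regression, imputation sensitivity) with printed, interpreted output.

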
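# Methods

`edutwin` studies the etiology of stability and change in school
achievement with two families of methods: twin-design structural equation
models fitted to MZ/DZ covariance matrices, and DNA-based analyses (GREML
SNP heritability and polygenic-score regression). Because the cohort data
such analyses are normally run on are access-controlled, the package ships
a first-class synthetic-data module that generates cohorts with exactly the
covariance structure the models assume; every analysis is validated as a
parameter-recovery experiment against known generating values.

## Twin models

All twin models operate on the stacked vector of one twin pair's scores,
(twin-1 occasions, twin-2 occasions), with implied covariance

```
Sigma(zyg) = [[Sigma_A + Sigma_C + Sigma_E,  r·Sigma_A + Sigma_C],
              [r·Sigma_A + Sigma_C,          Sigma_A + Sigma_C + Sigma_E]]
```

where `r = 1` for MZ pairs and `r = 0.5` for DZ pairs (additive genetics,
no assortative-mating correction — which makes heritability estimates
conservative), shared environment is weighted 1 in both groups, and
non-shared environment never crosses twins. The per-component
within-person matrices `Sigma_X` are built from path coefficients:

- **Univariate ACE** — paths a, c, e; `Sigma_X` is the squared path.
- **Cholesky** — lower-triangular path matrices `L_X`, `Sigma_X = L_X L_X'`.
  The bivariate wrapper derives rG/rC/rE and the share of the phenotypic
  covariance carried by each component (shares sum to 1 by construction).
- **Genetic simplex** — each of A, C, E follows a first-order
  autoregression over occasions: an initial standard deviation, per-step
  transmission paths beta, innovation standard deviations, and
  occasion-specific standard deviations at interior occasions. The
  occasion-specific path is fixed to 0 at the first occasion (confounded
  with the initial variance) and at the last (confounded with the final
  innovation). E receives the same structure as A and C — whether
  non-shared environment transmits is estimated, not assumed.
- **Common pathway** — a single latent trait with ACE-decomposed variance
  loads on every occasion; each occasion keeps residual ACE variances. The
  fit identifies scale by fixing the first loading to 1 and reports the
  standardized squared latent paths (summing to 1), which is the headline
  "share of stability" decomposition.

Derived simplex quantities follow the standard share arithmetic on the
unit-variance (standardized) scale: the transmitted share of occasion-t
genetic variance is `h2_{t-1} · beta² / h2_t`, and the innovation share is
`(innovation² + occasion-specific²) / h2_t`.

### Estimation

Fitting is maximum likelihood on per-zygosity sample covariance matrices
(complete-case pairs), using the normal-theory discrepancy
`sum_g n_g (p·log 2π + log|Sigma_g| + tr(S_g Sigma_g^{-1}))`. Sample
covariances are symmetrized over the arbitrary twin labelling (averaged
with the twin-swapped matrix), matching the exchangeability of the model.
Raw-data FIML is deliberately out of scope: the composites this design uses
have little missingness, complete-case covariance fitting keeps the
likelihood auditable, and the saturated-model value gives an exact
goodness-of-fit anchor.

Variances enter as squared paths, so no box constraints on variances are
needed; standard-deviation-like parameters are bounded at 0 with diagonal
signs fixed non-negative (the usual sign convention — the likelihood is
invariant to column sign flips). Optimization is L-BFGS-B on the
per-observation-scaled objective from 10 restarts jittered around
moment-informed starts (Falconer shares for the components, lag-1
phenotypic regressions for transmission paths). Convergence requires a
scaled projected-gradient norm below 2e-3 — the objective is O(10) per
observation and finite-difference gradients carry noise of order 1e-3 at
the optimum — plus agreement of near-optimal restarts. A non-positive-
definite implied covariance returns a large penalty rather than raising,
keeping the optimizer inside the feasible region.

Confidence intervals are profile-likelihood: the interval for one
parameter is where the re-minimized -2lnL rises by the chi-square(1)
critical value (3.84 at 95%). A bound that runs into a box constraint or
the search range is returned one-sided with a flag. Model comparison is
the likelihood-ratio test; a meaningfully negative LRT raises, as it can
only mean the fuller model's optimizer failed.

Degenerate cases are flagged rather than silently divided through: shares
of a near-zero phenotypic correlation, or innovation/transmitted shares at
near-zero heritability, come back NaN with a flag.

## Synthetic cohorts

Twin phenotypes are simulated directly from latent component scores (the A
score identical within MZ pairs and correlated 0.5 within DZ pairs via a
common/segregating split; C identical; E independent), which reproduces
each model's implied covariance exactly and is far faster than simulating
genotypes. DZ opposite-sex pairs are generated like same-sex DZ pairs and
pooled in analysis (sex-limitation effects are out of scope). Phenotypes
can be emitted with arbitrary mean/sd, an additive sex effect, and a
missing-at-random rate so the preprocessing stage has real work to do; no
claim is made that the missingness pattern matches any particular cohort.

The canonical generating regime for achievement
(`achievement_simplex_params`) uses occasion heritabilities
0.73/0.70/0.63/0.58 with genetic transmissions 0.86/0.84/0.86 (innovation
variances chosen for internal consistency, so they differ slightly from
rounded published paths), stable shared environment ~0.20, and purely
occasion-specific non-shared environment; phenotypic variance is 1 at
every occasion. The common-pathway regime uses latent ACE shares
(0.70, 0.24, 0.06), loadings 0.85, and residual ACE filling each occasion
to unit variance.

Genotype panels are independent biallelic SNPs in Hardy-Weinberg
equilibrium with frequencies uniform on a MAF window — no linkage
disequilibrium, dominance, or assortative mating. Polygenic phenotypes are
built from standardized causal dosages with normal effects, rescaled so
the genetic component has sample variance exactly h2, plus independent
noise.

The polygenic-score cohort emits one fixed score s per individual and one
achievement variable per occasion,
`y_t = sqrt(r2_t)·s + sqrt(rho(1-r2_t))·u + sqrt((1-rho)(1-r2_t))·e_t`,
so the population R² of the score at occasion t equals the schedule entry
exactly while the score's prediction is carried by the persistent part
(s and the stable trait u). The stable share rho defaults to 0.92, chosen
so that the score's incremental R² beyond all earlier-age achievement
stays a few tenths of a percent per age (population values 0.3-0.6%);
year-to-year correlations in this cohort (~0.9) are accordingly higher
than real achievement data show (~0.7-0.85) — the cohort is built to
isolate the stable-prediction property, not to mimic every marginal
feature at once.

### What passing recovery tests do and do not show

The generators satisfy the fitted models' assumptions exactly
(multivariate normality, no missingness mechanisms beyond MAR, no LD, no
GxE). Parameter recovery therefore validates the estimation machinery —
identifiability, consistency, calibration of intervals — but says nothing
about robustness to assumption violations in real cohort data.

## DNA methods

The GRM follows the GCTA convention,
`G_ij = (1/m) Σ_k (x_ik - 2p_k)(x_jk - 2p_k) / (2p_k(1-p_k))` with sample
allele frequencies; missing dosages are mean-imputed per SNP and
monomorphic SNPs dropped (or raised in strict mode). Text output uses the
GCTA gzipped-triplet convention with a companion id file.

Relatedness pruning greedily removes the individual involved in the most
pairs above the cutoff (default 0.025, "fifth cousins") until none remain,
deterministically. Note a scale caveat: at desk-scale SNP counts
(m ≈ 5000) the sampling noise of GRM entries (sd ≈ 1/√m ≈ 0.014) overlaps
that cutoff, so pruning an entirely unrelated simulated cohort at 0.025
would discard most of it. The recovery experiments therefore run on the
full simulated cohort — which is unrelated by construction — and the
pruning rule is exercised and tested separately.

REML uses a one-off eigendecomposition of the GRM so that every iteration
works with a diagonal covariance in the rotated basis. Updates are
average-information steps with an EM fallback whenever an AI step would
leave the parameter space or reduce the restricted likelihood (EM steps
are monotone); starting values are half the phenotypic variance per
component, convergence at a restricted log-likelihood change below 1e-6,
at most 100 iterations. Standard errors come from the inverse AI matrix,
with the h2 SE by the delta method. A GRM with (near-)equal eigenvalues —
e.g. the identity — is rejected as non-identifiable, and boundary
estimates are flagged. Reported SEs at desk scale (n ≈ 2000) are several
times larger than published cohort-scale values; SE magnitudes are not
reproduction targets.

Polygenic scores are allele-matched weighted dosage sums (weights whose
effect allele is the panel's other allele count the complementary dosage),
z-standardized. Incremental R² is the gain in OLS R² from adding the score
to a baseline of ancestry principal components (GRM eigenvectors scaled by
root eigenvalues), optionally plus all earlier-age achievement; the
age-specific prediction of the score is its increment beyond that fuller
baseline.

## Problem sizes and tolerances

Recovery experiments run at the design's stated conditions: 10000+10000
pairs for the simplex and common-pathway fits (tolerance ±0.05 on
transmission paths and latent shares, ~3-4 Monte-Carlo SDs), 5000+5000
pairs for univariate ACE (±0.03 per component, ~1.7 MC SDs — the tightest
band in the suite), and n=2000/m=5000 with 20 replicates for GREML
(single-replicate 2-SE check plus mean bias < 0.03). Replicated
calibration experiments in the unit suite (interval coverage, LRT null
calibration, recovery bias) use smaller per-replicate sizes and draw
sample covariance matrices directly from the implied Wishart distribution,
which is statistically identical to simulating pairs and refitting from
raw data but much cheaper; bias checks use 8 replicates at full size.

## Known limitations

- No sex-limitation or dominance (ADE) models; opposite-sex DZ pairs are
  pooled with same-sex DZ pairs.
- No FIML: families with a missing occasion drop out of multivariate fits.
- The DZ genetic weight is fixed at 0.5; assortative mating would inflate
  the shared-environment estimate at the expense of heritability.
- LDpred-style weight construction is upstream of this package: scoring
  weights are consumed, never derived.
- The simplex E-component split between interior innovations and
  occasion-specific paths is weakly identified when E transmission is
  near zero; the implied covariance and the A/C paths are unaffected.
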
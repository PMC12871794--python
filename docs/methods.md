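# Methods

This note records the models, conventions, and design choices behind
`gxescale`, and what the simulation studies do and do not establish.

## Generative model

`simulate_cohort` draws, for n samples and m polygenic scores,

    Y' = G β + E α + (G*E) γ + ε,   ε ~ N(0, 1)

with G an n×m standard normal matrix and (G*E) the columnwise product of G
with E.  Defaults: m = 25, h² = 0.3, environment variance 0.2, γ = 0.

**Variance convention.**  The noise is pinned at unit variance, so the
total latent variance is 1/(1 − h² − env_var) (= 2 at the defaults) and β
and α are scaled so that var(Gβ) and var(Eα) hit the target fractions
exactly (using the theoretical variance of E).  β is constant across the m
columns; γ is a scalar applied to every column's interaction with E.  These
are the simplest conventions that realize all three variance fractions
simultaneously; the empirical decomposition test verifies them to ±0.01
over replicates.

**Environment distribution.**  E is standard normal by default;
`env_dist="bernoulli"` with a configurable exposure frequency is supported.
This choice is consequential for rank-based transforms — see "RINT
calibration" below.

**Observation scales.**  The observed trait is f(Y' + shift) with f one of
identity, exp, or inverse-logit.  Power transforms require positivity, so
on the identity scale the default shift places the sample minimum at least
6 latent standard deviations above zero; exp and inverse-logit are already
positive and get no shift.  The shift is reported and configurable; a
configuration whose observed trait is not strictly positive is an error
naming the smallest value, never silently repaired.

**Genotype panels.**  `simulate_genotype_cohort` draws unlinked
Binomial(2, freq) dosages on a single chromosome (1-based, uniform
spacing), with shared or group-specific true effects and an optional
multiplicative map Y = exp(Y') producing log-additive traits.  There is no
LD structure, no MAF/call-rate/HWE QC (panels are QC-clean by
construction), and no relatedness — conclusions about clumping behaviour
on real, LD-structured genomes do not follow from these panels alone.

## Transformations

Box-Cox uses `scipy.special.boxcox`, with |λ| < 1e−12 treated as the log
case to avoid cancellation; the default grid is 25 evenly spaced points on
[−1, 2] (spacing 0.125, containing 0 and 1 exactly).  RINT maps ranks
(mean rank for ties) through Φ⁻¹ with the Blom 3/8 offset — the common
convention in GWAS tooling; the choice of offset is immaterial to every
test here because it is an increasing reparameterization.

## Interaction scan

`fit_interaction` fits the full model by OLS (statsmodels):

    Y* ~ 1 + PGS + E + PGS·E + C + C·E

The C·E block ensures covariate effects that vary with E cannot masquerade
as PGS×E.  Categorical covariates or E are expanded to indicator contrasts
against the first sorted level; a multi-level E yields a joint Wald F test
on its interaction contrasts.  Rows with missing values are dropped first.
Classical standard errors are the default (HC0 optional).  A rank-deficient
design is refused with the collinear columns named.  P-values are clipped
into (0, 1] at the smallest subnormal.

The profile threshold defaults to Bonferroni over the transformations
tested per profile (0.05/26 with the default grid plus RINT).  When several
PGS are scanned, each is profiled in its own model.  Classification: not
significant if p(λ=1) ≥ threshold; scale-independent if every grid p is
below threshold; scale-dependent otherwise.  RINT is excluded from
classification (it is not a power transform).  The most-additive λ is the
grid argmax of p, ties resolved toward λ = 1 then the smaller λ.

## GWAS, clumping, PRS

`run_gwas` computes per-SNP OLS (y ~ dosage + covariates) via
Frisch–Waugh–Lovell residualization, which shares the covariate projection
across SNPs and is verified exactly against per-SNP statsmodels fits.
Zero-variance (or covariate-collinear) SNPs yield missing statistics with a
warning.

`clump` is greedy: promote the smallest-p unassigned SNP (ties: smaller
position, then id — making output invariant to row order), absorb
unassigned SNPs within the window at r² ≥ threshold.  Missing LD entries
count as r² = 0 (the SNP stays unclumped) and are logged — the conservative,
plink-like reading.  `shared_hits` clumps the per-SNP minimum of two
studies' p-values and labels each significant lead by which studies
individually pass the same genome-wide threshold.

`build_prs` is clump-then-threshold with weights equal to GWAS betas; the
cutoff is chosen on a disjoint tuning cohort by squared Pearson correlation
with the phenotype *on the training scale*, first maximum winning over the
ascending grid.  `evaluate_prs` regresses the eval-scale phenotype on the
score plus covariates and reports the squared Pearson (or Spearman)
correlation between phenotype and fitted values; per-group values come from
refitting within each group, not from subsetting pooled residuals.  A
log-trained score evaluated on the default scale enters exponentiated
(centered before exponentiation for numerical range; R² is invariant to
that scaling).  `naive_genetic_correlation` is a plain Pearson correlation
of betas over an independent SNP set — a desk-scale concordance summary,
*not* an LD-score-regression estimate: sampling noise in the betas
attenuates it toward zero, which the CV experiment exploits deliberately.

## Simulation studies and scaled-down sizes

`run_scenario_grid` crosses γ ∈ {0, γ₁} with the three observation scales.
Replicate seeds spawn from the master seed keyed by (scenario, scale,
replicate), so the grid is bit-reproducible; an optional mode shares latent
draws across scales, under which rank-based (RINT) results are identical
across scales by construction.  Defaults are desk-scale: n = 20,000 and
100 replicates; power scenarios at reduced n rescale γ by √(100,000/n),
preserving the Wald noncentrality of the reference design
(`recalibrate_gamma`).  The test suite uses n = 2,000 for calibration and
inflation checks (OLS calibration is exact at any n; the exponential-scale
artifact is overwhelming already), n = 5,000 for power retention across the
grid, and n = 8,000 for the sign-flip experiment — the extreme λ = 2 end of
the grid on an exponentially observed trait needs that size for near-full
power.  The CV experiment targets the observed CV through the lognormal
closed form σ² = log(1 + CV²) and uses n = 1,500–2,000 with ~100 unlinked
SNPs.

Both the mean p-value and the mean −log10 p are recorded per transform, so
either summary of a profile across replicates can be plotted.

## RINT calibration

A point this package's simulations make precise: applying RINT before a
PGS×E test is *not* intrinsically anticonservative.  When the latent trait
is Gaussian — Gaussian G, ε, and a symmetric E — RINT is asymptotically an
affine map and the interaction test is calibrated (empirically even
slightly conservative at the Bonferroni threshold; the acceptance script
reports rejection rates ≈ 0 at the defaults).  What inflates the test is
latent *skewness*: with an unbalanced binary exposure the latent trait is
an asymmetric Gaussian mixture, gaussianizing it is genuinely nonlinear at
any sample size, and the induced interaction grows without bound in n (the
suite demonstrates rejection rates two orders of magnitude above nominal at
n = 30,000 with a 20% exposure).  The false-positive rate is steeply
sensitive to that skewness, so any single "RINT FPR" number is a property
of the environment's distribution as much as of the transform.  RINT
results never depend on the observation scale, which cancels in the ranks.

## Known limitations

- Only the one-parameter Box-Cox family is profiled; traits needing a shift
  parameter, Yeo-Johnson, or richer monotone families are out of scope.
- The GWAS/PRS stack is desk-scale: unlinked panels, empirical LD,
  effect-correlation rg; none of it is a substitute for mixed-model
  association, reference-panel LD, or LD-score regression on real data.
- Binary traits (link-function choice) and variance-QTL style tests are not
  covered.
- Passing the simulation suite shows the machinery behaves correctly under
  the stated generative conditions; real phenotypes add measurement error,
  covariate structure, and ascertainment that these generators do not
  emulate.
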
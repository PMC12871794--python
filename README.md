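# gxescale

Scale-aware testing of polygenic-score-by-environment (PGS×E) interactions,
with the simulation machinery to validate the approach and desk-scale
GWAS/PRS tooling to study how phenotype scale shapes genetic discovery.

## The problem

A statistical G×E interaction is not a property of a trait alone — it is a
property of the trait *on a particular measurement scale*.  Because males
are taller than females, a variant raising height by 1% has a larger
centimeter-scale effect in males, so a perfectly multiplicative (log-additive)
trait shows strong PGS×Sex interaction on the raw scale and none on the log
scale.  Biobank-scale cohorts have the power to detect these scale artifacts
everywhere.  This package separates *scale-dependent* interactions (removable
by a monotone rescaling) from *scale-independent* ones (present on every
considered scale) by profiling the interaction test across a family of
transformations.

## The method

For a positive trait Y, covariates C, environment E, and a polygenic score,
the model is fit by OLS on each Box-Cox transform Y*_λ = (Y^λ − 1)/λ
(log Y at λ = 0), for λ on a grid from −1 to 2:

    Y*_λ = PGS·β + E·α + (PGS·E)·γ + C·η + (C·E)·σ + ε

The two-sided Wald p-value for γ is profiled over λ (plus the rank inverse
normal transformation, RINT), with Bonferroni correction over the
transformations tested (0.05/26 by default).  λ = 1 is the untransformed
trait.  An interaction significant at λ = 1 but not at some other λ is
scale-dependent; one significant everywhere is scale-independent.  The λ
with the largest p-value estimates the trait's most-additive scale.

Supporting machinery, all importable from `gxescale`:

- `simulate_cohort` — latent-scale generative model
  Y′ = Gβ + Eα + (G·E)γ + ε with exact variance fractions (h², env_var),
  observed through identity / exponential / inverse-logit maps;
- `run_gwas`, `clump`, `shared_hits` — per-SNP association scans, greedy
  LD clumping (r² ≥ 0.1 within 250 kb by default), and min-p union
  clumping to label hits shared between two GWAS or specific to one;
- `build_prs`, `evaluate_prs` — clump-then-threshold polygenic scores with
  the p-value cutoff tuned by prediction R², and scale-aware evaluation
  (a log-trained score enters the default-scale model exponentiated);
- `run_scenario_grid`, `run_cv_experiment`, `run_sign_flip_experiment` —
  the simulation studies: null calibration and inflation across observation
  scales, coefficient-of-variation effects on cross-group genetic
  correlations, and the sign-flipping architecture that no rescaling can
  explain away.

## Worked example

`examples/01_lambda_profile.py` simulates an additive cohort (no latent
interaction, n = 20,000) observed on the exponential scale and profiles the
PGS×E p-value:

```
p at lambda=1 (none): 8.05e-228   <- spurious interaction
p at lambda=0 (log):  0.0909      <- removed by log
classification:       scale_dependent
most-additive lambda: 0 (truth: 0)
```

The untransformed test is catastrophically inflated — the trait is
multiplicative, so additive effects look environment-amplified — while the
log transform restores calibration, and the profile's peak recovers the true
additive scale (λ = 0).  The other examples walk through the scenario grid,
two-scale GWAS comparison, PRS construction/evaluation, and the CV
experiment, each printing what the numbers mean.

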
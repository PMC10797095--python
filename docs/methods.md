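# Methods

## Model

Each of ten soft skills is modelled independently with a cumulative-logit
(proportional-odds) mixed model in which students are multiple members of
the courses they have followed:

    logit P(Y_st ≤ k) = α_k − η_st,      k = 1..3 (K = 4 ordered categories)
    η_st = β·N_st + Σ_{c: w_cst=1} u_c + θ_s

- `w_cst` are unnormalised 0/1 membership dummies, cumulative over stages
  (a course once followed stays in the history). They are deliberately
  *not* the classic sum-to-one multiple-membership weights: the mean
  course effect is carried by `β·N_st`, so each additional course adds β
  plus its own deviation `u_c` to the linear predictor.
- `u_c ~ N(0, σ_c)` and `θ_s ~ N(0, σ_s)`. Course effects are assumed
  time-constant; there are no per-course fixed effects (the catalog is far
  larger than the per-course sample) and no specialization/tutor effects.
- Thresholds are shared across stages; stage enters only through `N_st`.

Positive `η` moves probability mass toward higher categories; `exp(β)` is
the multiplicative change in the odds of being more proficient per
additional course.

## Priors

Improper flat prior on β (implemented as a zero log-density contribution;
propriety of the posterior comes from the likelihood at realistic n).
Half-t(df 3, scale 2.5) on σ_c and σ_s; t(df 3, scale 2.5) on each
threshold subject to the ordering constraint (imposed by sampling the
first cutpoint plus log-increments). The threshold prior is a design
choice: weakly-informative t priors of this form are the common default
for cumulative-logit intercepts, and the prior scale dwarfs the
likelihood's information at the sample sizes involved.

## Sampling

The posterior is explored with the package's own No-U-Turn sampler
(`ordmm.mcmc`): slice-variant NUTS with dual-averaging step-size
adaptation (target acceptance 0.8), a diagonal metric estimated in a
warm-up window with shrinkage toward unit scale, and a max tree depth of
10. Divergent transitions (energy error > 1000) are counted and reported.

The model is sampled on an unconstrained parameterisation: first threshold
plus log-increments, log standard deviations, and non-centred `u = σ_c·z_u`,
`θ = σ_s·z_θ`. Two numerical choices matter:

- the course count is centred internally (`η` uses `N − mean(N)` and the
  sampled thresholds absorb `β·mean(N)`); this is a unit-Jacobian linear
  change of variables that removes a strong β–threshold posterior ridge
  and roughly halves the tree depth NUTS needs. Reported thresholds are
  shifted back.
- interior-category likelihood terms use the stable decomposition
  `log[σ(a) − σ(b)] = log σ(a) + log σ(−b) + log(1 − e^{b−a})`, whose
  η-gradient telescopes; gaps below e^−30 or above e^30 on the log scale
  are rejected outright rather than risking overflow.

Chain layouts: the full-scale preset is 4 chains × 5,000 iterations with
1,000 warm-up each (16,000 retained draws); the desk preset is 2 × 1,500
with 500 warm-up. Convergence is summarised by the rank-normalized split
R-hat (bulk and folded, maximum reported) for every parameter, including
each `u_c` and `θ_s`; a constant block returns exactly 1.0 rather than
NaN. The implementation was cross-checked against an independent
rank-normalized implementation on random inputs.

## Synthetic cohorts

The generator draws from exactly the model above, plus structure the
per-skill model does not describe:

- **Design.** The study-shaped default has three graduation cohorts with
  per-stage assessment coverage (250/250/141, 194/245/141, 339/366/–),
  104 courses, and a cumulative enrollment schedule of 6 new courses by
  stage 1 and 5 more by stage 2 (11 total — the cap). The published
  totals do not identify the roster overlap across stages, so per-cohort
  rosters are the maxima and each under-covered stage assesses a seeded
  random subset. The real per-stage enrollment schedule is likewise not
  published beyond the 11-course cap; 6+5 is a plausible default and is
  configurable.
- **Effect sizes.** Defaults β=0.2, σ_c=0.15, σ_s=0.35 sit at the
  magnitudes typical for this kind of data; thresholds (−0.5, 1.3, 3.0)
  make the baseline distribution right-skewed and the final stage
  left-skewed, matching the qualitative descriptive pattern.
- **Cross-skill structure.** Course effects share a common factor carrying
  half their variance (positive cross-skill correlation of course
  effects). Latent assessment noise is correlated across the ten skills
  within one student×stage row through an equicorrelated Gaussian copula
  (default latent correlation 0.65), emulating rater/occasion halo — the
  inter-dimension correlations of rubric ratings commonly reach 0.6–0.8.
  Both mechanisms leave every skill's marginal law exactly the
  cumulative-logit model, so per-skill inference and recovery testing are
  unaffected; they matter for imputation (which needs cross-column
  signal) and for cross-skill correlation summaries.
- **Missingness.** Block rules mark whole (cohort, stage) pairs as
  missing (the earliest cohort's baseline); item-level missingness is
  MCAR at 5% by default (no mechanism is published). The generator
  returns the mask so tests can score recovery of known values.

What passing tests on this generator do *not* show: robustness to
informative missingness, to rater drift over stages, to enrollment choice
correlated with ability, or to misspecified random-effect distributions —
none of which the model represents.

## Multiple imputation

Missing score cells are imputed m=5 times (default) by predictive mean
matching with chained equations on the wide student × (skill, stage)
matrix, with cohort dummies as extra predictors. Type-1 matching: donors
are predicted with the least-squares point estimate, targets with a
coefficient draw from the approximate posterior (scaled inverse-χ²
residual variance, then Gaussian coefficients); each missing cell receives
the observed score of a donor sampled uniformly from the k=5 nearest
predictions (distance ties enlarge the pool). Scores are treated
numerically inside the regression — the donor mechanism restores
ordinality, so imputed values always lie in {1,2,3,4}. Five chained sweeps
cycle over incomplete columns, initialised by draws from each column's
observed values. When a column's observed rows cannot support the full
predictor set (small cohorts), the regression keeps the predictors most
correlated with the target, at most a third as many as observed rows.
Wide cells with no underlying row (a student never assessed at a stage)
receive working values as predictors but are never written back.
Non-block missing scores are dropped from the model likelihood when not
imputed; the pipeline imputes all missing cells.

## Pooling and post-hoc summaries

Per-parameter estimates from the m imputed-dataset fits are combined with
the standard combination rules: pooled mean = mean of posterior means;
total variance = mean within-fit posterior variance + (1 + 1/m) × between
variance. Both the complete total SE and the between-only SE
√((1+1/m)B) are reported: published multiple-imputation tables sometimes
print only the between component (a parenthetical SE of exactly 0 is only
consistent with that convention), but the total SE is the statistically
meaningful one. Course-effect ranges are β ± 1.96·σ_c. Cross-skill
correlations are Pearson correlations of pooled per-course posterior
means (point estimates, computed once after pooling rather than averaged
per-imputation correlations). Kernel densities use a Gaussian kernel with
Silverman bandwidth and an explicit override for degenerate inputs.

## Problem sizes used in tests

The test and acceptance runs use scaled-down cohorts chosen by the
package: convergence checks on ~200 students / 20 courses with 4 chains ×
(500 warm-up + 750–1,000 kept); the recovery study at 500 students / 40
courses, ten replicates, 2 chains × (300 warm-up + 400 kept) each;
imputation-accuracy checks on 300-student cohorts. These sizes keep a
full run on one CPU in the tens of minutes while leaving the estimands
well inside the regime the full-scale configuration targets.

## Known limitations

- σ_s is weakly identified with only three assessments per student on a
  4-level scale: the latent logistic noise (SD ≈ 1.81) dwarfs a student
  SD of ~0.35 (intraclass correlation ≈ 0.035), so its likelihood is
  nearly flat over a wide range and point estimates scatter far from the
  generating value even at 1,000+ students. Underestimated variance
  components mildly attenuate β (conditional → marginal shrinkage).
- Effects are associational: students choose courses, so course effects
  are confounded with selection.
- The model assumes proportional odds, time-constant course effects, and
  normal random effects; none are tested against alternatives here.
- The sampler is a general-purpose NUTS without within-chain
  parallelism; full-scale runs (10 skills × 5 imputations at the
  4 × 5,000 layout) take hours on one CPU.
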
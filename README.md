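# nutrigen

Gene–diet interaction analysis for case–control cohorts, built around
weighted diet-quality scores.

Epidemiologists studying type 2 diabetes (and other lifestyle-linked
diseases) often summarize a food-frequency questionnaire (FFQ) into a
Recommended Food Score (RFS): one point per recommended food eaten at least
once a week, plus a point for a regular three-meals-a-day pattern — 46
points here (10 food groups: meals 1, grains 1, legumes 4, vegetables 16,
seaweeds 2, fruits/juices 12, fish 5, dairy 3, nuts 1, tea 1). The plain
tally treats every item as equally important. `nutrigen` implements two
data-driven reweightings of the tally and the downstream gene–diet
interaction pipeline:

- **HisCoM-RFS** — a hierarchical structural component logistic model. With
  `g_itk` the 0/1 indicator of item *t* in food group *k*, item weights
  `w_itk` and group coefficients `β_k` satisfy

  `logit(π_i) = β₀ + Σ_k [ Σ_t g_itk w_itk ] β_k`

  and the per-subject score is the linear predictor without the intercept.
  Estimation is alternating least squares on the logistic working response
  (Step 1: update `β` with `w` fixed; Step 2: update `w` with `β` fixed)
  with a ridge penalty `λ₁` on item weights only (`λ₂ = 0` on group
  coefficients); each group component `Σ_t g_itk w_itk` is scaled to unit
  sample variance. Inference is by phenotype-permutation.
- **PLSDA-RFS** — partial-least-squares discriminant weights of the 46
  indicators against the outcome, ignoring food groups.
- Downstream stages: baseline case–control tables (χ², t, Wilcoxon, KS),
  covariate-adjusted odds ratios per SD of each score, rank-based
  diet-quality tertiles, a per-SNP `score × genotype` interaction scan,
  simplified gene and competitive gene-set aggregation with BH-FDR, a
  weighted-sum polygenic risk score (PRS), and the 3×3 genetic-risk ×
  diet-quality odds-ratio grid.
- A seeded synthetic cohort generator with planted item weights, group
  coefficients, covariate effects and SNP×score interactions, so the whole
  pipeline is testable without access-restricted cohort data.

## Worked example

```python
from nutrigen import (SimulationConfig, simulate_cohort, HiscomModel,
                      fit_plsda, fit_association)

cfg = SimulationConfig(n_subjects=2000, n_snps=50, seed=7)
cohort = simulate_cohort(cfg)          # FFQ, covariates, genotypes, phenotype
g = cohort.indicator                   # 2000 x 46 binary item matrix
rfs = g.sum(axis=1).astype(float)      # unweighted 0-46 score

res = HiscomModel(cohort.phenotype, g).fit(lambda1=1.0)
print(res.summary())                   # weights, group coefficients, deviance
print(fit_association(cohort.phenotype, res.score(g), cohort.covariates))
print(fit_association(cohort.phenotype, rfs, cohort.covariates))
```

prints (seed 7):

```
Hierarchical structural component model (logistic link)
  n=2000  items=46  groups=10
  lambda1=1  lambda2=0  deviance=1925.159  iterations=6  converged=True
  ...
score: OR 2.809 (95% CI 2.462-3.206), P=4.5e-53, n=2000
score: OR 2.145 (95% CI 1.901-2.420), P=2.27e-35, n=2000
```

The odds ratios are per standard deviation of each score, adjusted for the
ten covariates (age, sex, area, BMI, smoking, alcohol, coffee, education,
income, METs). This cohort is simulated with positive planted diet effects
(within-group weight ramps, group coefficients 0.4), so the refitted
HisCoM-RFS separates cases from controls more strongly than the unweighted
tally — the gap between 2.81 and 2.15 is exactly the gain from reweighting
the items on the same data.

A command-line interface mirrors the library
(`nutrigen simulate | score | fit-hiscom | fit-plsda | table1 | associate |
interact | prs | geneset | grid | run`); `nutrigen run --seed 7` executes
every stage and writes one TSV per stage plus a manifest.

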
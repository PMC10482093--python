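# Methods

## The scoring rule

The Recommended Food Score used throughout is a 46-component tally: 45
recommended food items in 10 groups plus a regular-meals item. A food item
contributes one point when its reported frequency is "one to two times a
week" or any higher category on the nine-level FFQ scale — the scale has no
plain "once a week" level, so that category is the documented weekly cut.
The meals item contributes one point only for "three meals a day". Missing
items are a hard error rather than being imputed: any imputation policy
would silently move scores inside the 0–46 bounds. The identities of the 45
foods are schema-driven (the shipped panel uses `<group>_<k>` placeholders
with the correct group sizes); all scoring logic depends only on the
item→group map.

## Hierarchical structural component model

Model: `logit(π_i) = β₀ + Σ_k f_ik β_k` with `f_ik = Σ_t g_itk w_itk` the
group-k latent component. Parameters are estimated by alternating least
squares wrapped in the logistic IRLS working response: with current
`(β₀, β, w)`, form `z = η + (y − μ)/v`, `v = μ(1−μ)`, then

- **Step 1** — weighted least squares of `z` on `[1, F]` updates
  `(β₀, β)` holding `w` fixed (no penalty: `λ₂ = 0`);
- **Step 2** — weighted ridge regression of `z − β₀` on the columns
  `g·β_k` updates `w` holding `β` fixed, with penalty `λ₁‖w‖²`.

### Identification

`(w_k, β_k)` is only identified up to a scale/sign exchange, so after each
Step 2 every group component is rescaled to unit sample variance (the scale
moves into `β_k`) and, at convergence, signs are fixed so each group's
weight sum is nonnegative. Both choices follow generalized structured
component analysis convention. Flipping any `(w_k, β_k)` pair jointly
leaves the likelihood and the score unchanged — the tests assert this
invariance, and the sign rule is what makes output deterministic.

Columns are standardized internally (mean 0, SD 1) for conditioning; the
ridge acts in that metric. Reported weights are mapped back to the raw
indicator scale (`w = w_std / sd`), with the centering constant absorbed
into `β₀`, so that the per-subject weighted score
`Σ_k [Σ_t g_itk w_itk] β_k` is an exact linear form in the raw indicators:
an all-zero response row scores exactly 0, and each group component still
has unit sample variance on the raw scale. The standardized-metric weights
are exposed as `w_std` (a single-item group has `w_std = ±1` there).

### Descent and convergence

GSCA-style renormalization after a ridge step does not by itself guarantee
that the penalized deviance (−2·loglik + λ₁‖w_std‖²) decreases, and under
the null the Step-2 update can even flip a component's sign. Each sweep
therefore ends with (a) sign-aligning the new iterate to the previous one
(likelihood-invariant) and (b) a backtracking line search toward the
previous iterate, accepting the longest step that does not increase the
objective. The objective trace is stored on the fit and is non-increasing
by construction (asserted to 1e-8 in tests). Convergence: relative
parameter change < 1e-6 or objective decrease below 1e-9 of tolerance,
max 500 sweeps. Degenerate inputs (constant phenotype, non-binary
indicators, an all-zero item column with λ₁ = 0) raise immediately.

### Penalty and inference

The paper-level model fixes `λ₂ = 0`; `λ₁` has no stated value, so the
default policy is 5-fold cross-validated predictive deviance over a small
grid (`select_lambda1`), ties breaking toward the smaller penalty; the
pipeline default is `λ₁ = 1`. In the ridge limit (λ₁ → ∞) the
unit-variance constraint makes the penalty favour the leading eigenvector
of the within-group Gram matrix — equal weight magnitudes for positively
correlated items — which the two-item toy test verifies numerically.

Significance is by phenotype permutation: refit under B resampled
phenotypes and report `p = (1 + #{|stat_perm| ≥ |stat_obs|})/(B + 1)` for
every group coefficient and every item weight (both are provided since
either can be of interest). Default B = 999; calibration tests run 200
null replicates at B = 49, where the p-values are uniform (KS test).

Covariates are deliberately *not* inside the component model — the model
as printed has none; covariate adjustment happens downstream in the
association stage on the resulting score.

## PLS-DA score

The comparator weighting is ordinary PLS regression of the centered 0/1
outcome on the centered indicator matrix (scikit-learn's NIPALS
implementation behind the module surface), one component by default; food
groups are ignored by design. The published recipe multiplies "the RFS
scores" by the estimated weight matrix and the first column of the
coefficient matrix; a scalar total times a 46-row matrix is non-conformable,
so the item-indicator-vector reading is implemented: the score is
`g_i · c`, where `c` is the per-item coefficient vector (for a single
outcome, the only column of the PLS coefficient matrix, which already
combines the weight matrix with the loadings). The first weight direction
equals the centered cross-covariance `Gᵀ(y − ȳ)` in closed form — kept as
an independent oracle test so the library is never checked against itself.

## Association stage

Scores are z-standardized before fitting so odds ratios are per SD and
comparable across the three scores. Logistic ML via statsmodels with Wald
95% intervals (the conventional OR ± CI reporting); perfect separation and
collinear designs are explicit errors. Categorical covariates use the
collapsed encodings (income 5 levels, education 4, coffee 4, smoking 2,
alcohol 2), dummy-coded against the first level.

Diet-quality tertiles use fractional ranks with the midpoint convention
`(rank − 0.5)/n` against the 33.33%/66.6% cuts; ties share an average rank
and therefore never split across groups, and tie-free scores give group
sizes within 1 of n/3. Group odds ratios are dummy-coded against the
high-diet-quality reference.

## Genetic stages

- **Interaction scan**: per SNP, `y ~ covariates + score + SNP +
  SNP×score`, recording the interaction term (estimate, SE, Wald p). The
  SNP main effect is always included. SNPs under 5% in-sample MAF or
  monomorphic are skipped with a reason, mirroring upstream QC. Type-I
  error is verified at α = 0.05 over 500 null SNPs; power at the planted
  log-OR 0.3, MAF 0.3, n = 4,000 condition.
- **Gene test**: a simplified analogue of PC-based gene tests — principal
  components capturing ≥95% of the gene's dosage variance replace the
  SNPs, and all PC×score terms are tested jointly by likelihood ratio
  (single-SNP genes collapse exactly to the per-SNP LRT). An alternative
  p-aggregation mode combines per-SNP p-values via min-p with an
  effective-number-of-tests correction (effective rank
  `(Σλ)²/Σλ²` of the dosage correlation matrix). No equivalence to
  external gene-analysis software is claimed.
- **Gene-set test**: competitive — probit-transform gene p-values to
  z-scores, regress on set membership, one-sided for enrichment, BH-FDR
  across sets (q threshold 0.1 by default).
- **PRS**: plain weighted allele sum after effect-allele harmonization
  (dosage flipped `2 − d` when the effect allele is the other genotyped
  allele; unmatched alleles excluded with a count). LD-aware reweighting is
  intentionally out of scope; its causal-fraction parameter is treated as
  upstream metadata.
- **Risk × diet grid**: PRS tertiles by the same rank rule, crossed with
  diet tertiles, dummy-coded against (low genetic risk, high diet quality),
  one adjusted OR per non-reference cell; empty cells are flagged, not
  fitted.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, not any real
cohort: 46 iid FFQ items (default category probabilities put ~40% of items
past the weekly cut, giving mean totals in the high teens), ten covariates
drawn independently with marginals loosely matched to a middle-aged
case–control cohort (age ~ N(51, 8.5) truncated to 40–69, BMI ~ N(24.5, 3),
METs ~ N(42, 24) truncated at 0, and the collapsed categorical encodings),
and Hardy–Weinberg genotypes with MAF uniform on [0.05, 0.5] (the post-QC
floor is enforced). The phenotype is Bernoulli with

`logit π = β₀ + Σ_k [Σ_t g w] β_k + Σ_c γ_c x̃_c + Σ_j δ_j d_j z`

where `z` is the standardized item-weighted score `Σ g·w` (defined without
the group coefficients so planted interactions exist even under null group
effects; with uniform weights it equals the standardized unweighted total)
and `x̃_c` are standardized covariate encodings. The intercept is tuned by
bisection so the expected case fraction hits the target (default
1,090/4,292 ≈ 0.254). Default planted signal, chosen once as the study
condition for recovery tests: within-group weight ramps 0.2→1.0 and group
coefficients 0.4 — moderate, clearly non-uniform item importance.

What the generator does **not** emulate: FFQ item correlations, covariate
dependence (e.g. age–METs), linkage disequilibrium between SNPs, or
population structure. Passing recovery and calibration tests therefore
demonstrates correctness of the estimators under the assumed model, not
robustness to real-data violations of it.

Weight-recovery checks compare |estimated| to |planted| weights after
expressing the planted weights on the identified scale (each group scaled
to unit component variance) — the raw per-group scale of `w` is not an
estimable quantity, only the normalized pattern and the products `w·β`
are.

## Problem sizes and numerical choices

Simulation-based tests use n = 250–4,000 subjects, 1–500 SNPs, 10–20
seeds, and permutation B = 49–199 — sizes chosen so each suite settles a
calibration or recovery claim with conventional 3-SE slack while the whole
suite runs in minutes on one core. IRLS means/variances are clipped at
1e-10 to avoid log(0); the PC cutoff discards singular values below
1e-6·max; all randomness flows through `numpy.random.default_rng` seeds
recorded in outputs, and the pipeline manifest stores the seed plus a
config hash so any run can be reproduced byte-for-byte.

## Known limitations

- The gene and gene-set stages are deliberately simplified analogues of
  external gene-based association software; their defaults (95% PC
  variance, gene-body mapping window of 0 kb with a ±10 kb option) are
  documented, not claimed equivalent to those tools.
- The component model's permutation refits inherit the full cost of the
  fit; B = 999 at cohort scale is minutes, not seconds.
- No LD-aware PRS; no survey weights; no missing-FFQ handling by design.
- With heavy ties at a tertile boundary group sizes can deviate from n/3
  by more than 1 — the tie-keeping rule is prioritized over balance.
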
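"""Synthetic case-control cohort generator.

Emulates the statistical structure the analysis pipeline assumes — a
food-frequency questionnaire over the 46-item panel, ten adjustment
covariates with marginals loosely matched to a Korean middle-aged cohort,
Hardy-Weinberg genotypes at configurable minor-allele frequencies, and a
Bernoulli phenotype whose logit is the hierarchical food-score linear
predictor plus covariate effects plus planted SNP-by-score interaction
terms:

    logit(pi_i) = b0 + sum_k [sum_t g_itk w_itk] beta_k
                  + sum_c gamma_c x_ic + sum_j delta_j d_ij z_i

where z_i is the standardized item-weighted food score (sum_tk g_itk w_itk,
without the group coefficients). The intercept b0 is tuned by
bisection so the expected case fraction matches the target. Everything is
reproducible under a fixed seed; covariates are drawn independently of one
another (testability over realism — real questionnaire items are
correlated, these are not).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .panel import (
    FREQUENCY_CATEGORIES,
    MEAL_CATEGORIES,
    FoodPanel,
    default_panel,
)
from .rfs import indicator_matrix

# Default per-item frequency-category probabilities. Chosen once so that
# roughly 40% of items clear the weekly cut, giving mean total scores in the
# high teens out of 46 as seen in middle-aged cohort questionnaires. Not
# calibrated to any particular cohort.
DEFAULT_FOOD_CATEGORY_PROBS: tuple[float, ...] = (
    0.40, 0.20, 0.12, 0.08, 0.06, 0.05, 0.04, 0.03, 0.02,
)
DEFAULT_MEAL_CATEGORY_PROBS: tuple[float, ...] = (0.10, 0.25, 0.45, 0.05, 0.15)

#: Default planted effects (log-odds per standardized unit) for covariates.
DEFAULT_COVARIATE_EFFECTS: dict[str, float] = {"age": 0.35, "bmi": 0.30, "sex": 0.15}


def default_true_item_weights(panel: FoodPanel | None = None) -> np.ndarray:
    """Ground-truth item weights: a linear ramp within each food group.

    Within each group the weights rise linearly from 0.2 to 1.0 (a single
    item gets 1.0), so some items matter five times more than others — a
    clearly non-uniform pattern for weight-recovery checks while every item
    still contributes.
    """
    panel = panel or default_panel()
    w = np.empty(len(panel.items))
    pos = 0
    for grp in panel.groups:
        t = len(panel.items_in_group(grp))
        w[pos : pos + t] = np.linspace(0.2, 1.0, t) if t > 1 else 1.0
        pos += t
    return w


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the target cohort: 4,292 subjects with a 1,090/3,202
    case/control split, post-QC minor-allele frequencies in [0.05, 0.5].
    """

    n_subjects: int = 4292
    case_fraction: float = 1090 / 4292
    n_snps: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    true_item_weights: np.ndarray | None = None
    true_group_coefs: np.ndarray | None = None
    interaction_effects: dict[int, float] = field(default_factory=dict)
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    seed: int = 0
    food_category_probs: tuple[float, ...] = DEFAULT_FOOD_CATEGORY_PROBS
    meal_category_probs: tuple[float, ...] = DEFAULT_MEAL_CATEGORY_PROBS
    panel: FoodPanel = field(default_factory=default_panel)

    def __post_init__(self) -> None:
        if not 0.0 < self.case_fraction < 1.0:
            raise ValueError("case_fraction must lie in (0, 1)")
        lo, hi = self.maf_range
        if not (0.05 <= lo < hi <= 0.5):
            raise ValueError("maf_range must lie within [0.05, 0.5] (post-QC bounds)")
        if self.true_item_weights is None:
            self.true_item_weights = default_true_item_weights(self.panel)
        self.true_item_weights = np.asarray(self.true_item_weights, dtype=float)
        if self.true_item_weights.shape != (len(self.panel.items),):
            raise ValueError(
                f"true_item_weights must have length {len(self.panel.items)}"
            )
        if self.true_group_coefs is None:
            self.true_group_coefs = np.full(len(self.panel.groups), 0.4)
        self.true_group_coefs = np.asarray(self.true_group_coefs, dtype=float)
        if self.true_group_coefs.shape != (len(self.panel.groups),):
            raise ValueError(
                f"true_group_coefs must have length {len(self.panel.groups)}"
            )
        for probs, k in (
            (self.food_category_probs, len(FREQUENCY_CATEGORIES)),
            (self.meal_category_probs, len(MEAL_CATEGORIES)),
        ):
            p = np.asarray(probs, dtype=float)
            if p.shape != (k,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"category probabilities must be {k} nonnegatives summing to 1"
                )


def simulate_ffq(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-subject frequency categories for all 46 panel items (iid draws)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_subjects
    panel = config.panel
    data: dict[str, np.ndarray] = {}
    food = np.asarray(FREQUENCY_CATEGORIES, dtype=object)
    meals = np.asarray(MEAL_CATEGORIES, dtype=object)
    for item in panel.items:
        if panel.item_kind(item) == "meals":
            data[item] = rng.choice(meals, size=n, p=config.meal_category_probs)
        else:
            data[item] = rng.choice(food, size=n, p=config.food_category_probs)
    idx = pd.Index([f"S{i+1:05d}" for i in range(n)], name="iid")
    return pd.DataFrame(data, index=idx, columns=list(panel.items))


def simulate_covariates(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """The ten adjustment covariates, drawn independently.

    age: Normal(51, 8.5) truncated to [40, 69]; bmi: Normal(24.5, 3.0);
    mets: Normal(42, 24) truncated at 0; sex/area/smoking/alcohol binary;
    coffee 4 levels, education 4 levels, income 5 levels (the collapsed
    encodings used throughout the association models).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_subjects
    age = np.clip(rng.normal(51.0, 8.5, n), 40.0, 69.0)
    bmi = rng.normal(24.5, 3.0, n)
    mets = np.clip(rng.normal(42.0, 24.0, n), 0.0, None)
    df = pd.DataFrame(
        {
            "age": np.round(age, 1),
            "sex": rng.choice(["male", "female"], n, p=[0.48, 0.52]),
            "area": rng.choice(["urban", "rural"], n, p=[0.6, 0.4]),
            "bmi": np.round(bmi, 2),
            "smoking": rng.choice(["former", "occasional"], n, p=[0.78, 0.22]),
            "alcohol": rng.choice(["non_drinker", "former_drinker"], n, p=[0.52, 0.48]),
            "coffee": rng.choice(
                ["never_seldom", "monthly", "weekly", "daily"], n,
                p=[0.23, 0.06, 0.17, 0.54],
            ),
            "education": rng.choice(
                ["elementary", "middle", "high", "higher"], n,
                p=[0.29, 0.22, 0.34, 0.15],
            ),
            "income": rng.choice(
                ["lt1", "1to2", "2to3", "3to4", "gt4"], n,
                p=[0.30, 0.29, 0.20, 0.12, 0.09],
            ),
            "mets": np.round(mets, 1),
        },
        index=pd.Index([f"S{i+1:05d}" for i in range(n)], name="iid"),
    )
    return df


def simulate_genotypes(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    mafs: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Additive dosages in {0,1,2} under Hardy-Weinberg proportions.

    Returns ``(dosages, snp_info)``; ``snp_info`` carries chromosome,
    position, counted (effect) allele ``a1`` and other allele ``a2`` for
    gene mapping and PRS harmonization. Explicit ``mafs`` outside
    ``config.maf_range`` are rejected.
    """
    if config.n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lo, hi = config.maf_range
    if mafs is None:
        mafs = rng.uniform(lo, hi, config.n_snps)
    else:
        mafs = np.asarray(mafs, dtype=float)
        if mafs.shape != (config.n_snps,):
            raise ValueError("mafs must have length n_snps")
        if (mafs < lo).any() or (mafs > hi).any():
            raise ValueError(f"mafs outside configured maf_range {config.maf_range}")
    n, m = config.n_subjects, config.n_snps
    dosage = rng.binomial(2, mafs[None, :], size=(n, m)).astype(np.int8)
    alleles = np.array(list("ACGT"))
    a1_idx = rng.integers(0, 4, m)
    a2_idx = (a1_idx + rng.integers(1, 4, m)) % 4
    snp_ids = [f"rs{j+1:06d}" for j in range(m)]
    snp_info = pd.DataFrame(
        {
            "snp": snp_ids,
            "chrom": [str(1 + (j * 22) // m) for j in range(m)],
            "pos": np.arange(1, m + 1) * 50_000,
            "a1": alleles[a1_idx],
            "a2": alleles[a2_idx],
            "maf": mafs,
        }
    ).set_index("snp")
    idx = pd.Index([f"S{i+1:05d}" for i in range(n)], name="iid")
    dosages = pd.DataFrame(dosage, index=idx, columns=snp_ids)
    return dosages, snp_info


def _covariate_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Standardized numeric encoding used for planted covariate effects."""
    out = {}
    for col in covariates.columns:
        s = covariates[col]
        x = s.astype("category").cat.codes.astype(float) if s.dtype == object else s.astype(float)
        sd = x.std(ddof=0)
        out[col] = (x - x.mean()) / sd if sd > 0 else x * 0.0
    return pd.DataFrame(out, index=covariates.index)


def true_food_score(ffq: pd.DataFrame, config: SimulationConfig) -> pd.Series:
    """Ground-truth weighted food score sum_k [sum_t g w] beta_k on raw indicators."""
    panel = config.panel
    g = indicator_matrix(ffq, panel).to_numpy(dtype=float)
    score = np.zeros(len(g))
    pos = 0
    for k, grp in enumerate(panel.groups):
        t = len(panel.items_in_group(grp))
        w = config.true_item_weights[pos : pos + t]
        score += (g[:, pos : pos + t] @ w) * config.true_group_coefs[k]
        pos += t
    return pd.Series(score, index=ffq.index, name="true_score")


def _tune_intercept(eta_fixed: np.ndarray, target: float) -> float:
    """Bisection on b0 so that mean(expit(b0 + eta)) == target."""
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expit(mid + eta_fixed).mean() < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12:
            break
    return 0.5 * (lo + hi)


def simulate_phenotype(
    ffq: pd.DataFrame,
    dosages: pd.DataFrame,
    covariates: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.Series, dict]:
    """Bernoulli phenotype from the planted linear predictor.

    Returns ``(y, truth)`` where ``truth`` records the tuned intercept, the
    linear predictor and the standardized item-weighted score used for the
    interaction terms.
    """
    if not (len(ffq) == len(dosages) == len(covariates)):
        raise ValueError("ffq, dosages and covariates must have equal row counts")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    score = true_food_score(ffq, config).to_numpy()
    # interactions act on the standardized item-weighted score g @ w (no
    # group coefficients), so they are defined even when group effects are
    # null; with uniform weights this is the standardized unweighted total
    item_score = indicator_matrix(ffq, config.panel).to_numpy(float) @ config.true_item_weights
    isd = item_score.std(ddof=0)
    z = (item_score - item_score.mean()) / isd if isd > 0 else np.zeros_like(item_score)

    eta = score.copy()
    design = _covariate_design(covariates)
    for cov, gamma in config.covariate_effects.items():
        if cov not in design.columns:
            raise KeyError(f"covariate_effects names unknown covariate {cov!r}")
        eta += gamma * design[cov].to_numpy()
    d = dosages.to_numpy(dtype=float)
    for j, delta in config.interaction_effects.items():
        if not 0 <= j < d.shape[1]:
            raise IndexError(f"interaction SNP index {j} out of range")
        eta += delta * d[:, j] * z

    b0 = _tune_intercept(eta, config.case_fraction)
    p = expit(b0 + eta)
    y = pd.Series(
        (rng.uniform(size=len(p)) < p).astype(np.int8), index=ffq.index, name="t2d"
    )
    truth = {
        "intercept": b0,
        "linear_predictor": b0 + eta,
        "true_score": score,
        "true_score_std": z,
        "case_probability": p,
    }
    return y, truth


@dataclass
class SyntheticCohort:
    """One realized cohort with its ground truth and provenance seed."""

    config: SimulationConfig
    ffq: pd.DataFrame
    covariates: pd.DataFrame
    dosages: pd.DataFrame
    snp_info: pd.DataFrame
    phenotype: pd.Series
    truth: dict

    @property
    def indicator(self) -> pd.DataFrame:
        return indicator_matrix(self.ffq, self.config.panel)


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw FFQ, covariates, genotypes and phenotype from one seeded stream."""
    rng = np.random.default_rng(config.seed)
    ffq = simulate_ffq(config, rng)
    covariates = simulate_covariates(config, rng)
    dosages, snp_info = simulate_genotypes(config, rng)
    y, truth = simulate_phenotype(ffq, dosages, covariates, config, rng)
    truth["seed"] = config.seed
    return SyntheticCohort(config, ffq, covariates, dosages, snp_info, y, truth)
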
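"""Covariate-adjusted logistic association of food scores with the outcome,
score standardization, rank-based diet-quality tertiles and group odds
ratios.

The adjustment set is the study's ten covariates: age, sex, area, BMI,
smoking, alcohol, coffee, education, income and METs. Continuous covariates
enter as-is; categorical ones are dummy-coded against their first level
(collapsed encodings: income 5 levels, education 4, coffee 4, smoking 2,
alcohol 2). Odds ratios are exp(coef) with Wald 95% intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

#: the ten adjustment covariates, in reporting order
ADJUSTMENT_COVARIATES = (
    "age", "sex", "area", "bmi", "smoking", "alcohol", "coffee",
    "education", "income", "mets",
)

TERTILE_LABELS = ("low", "intermediate", "high")


@dataclass(frozen=True)
class ORResult:
    """One model term: odds ratio with Wald 95% CI and two-sided p."""

    term: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    pvalue: float
    n: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError("odds ratio outside its confidence interval")

    def __str__(self) -> str:
        return (f"{self.term}: OR {self.odds_ratio:.3f} "
                f"(95% CI {self.ci_low:.3f}-{self.ci_high:.3f}), "
                f"P={self.pvalue:.3g}, n={self.n}")


def standardize(score) -> np.ndarray | pd.Series:
    """Z-score: (x - mean) / SD (population SD). Constant input is an error."""
    x = np.asarray(score, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant score")
    z = (x - x.mean()) / sd
    if isinstance(score, pd.Series):
        return pd.Series(z, index=score.index, name=score.name)
    return z


def encode_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    """Numeric design columns: continuous as-is, categoricals dummy-coded
    against the first (alphabetical) level."""
    parts = []
    for col in covariates.columns:
        s = covariates[col]
        if pd.api.types.is_numeric_dtype(s):
            parts.append(s.astype(float).rename(col))
        else:
            d = pd.get_dummies(s.astype("category"), prefix=col,
                               drop_first=True, dtype=float)
            parts.append(d)
    return pd.concat(parts, axis=1)


def _check_design(x: pd.DataFrame) -> None:
    arr = x.to_numpy(dtype=float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        raise ValueError(
            "collinear design: covariate columns are linearly dependent"
        )


def _fit_logit(y: np.ndarray, x: pd.DataFrame):
    """Logistic ML fit with explicit separation detection."""
    _check_design(x)
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            model = sm.Logit(y, x.to_numpy(dtype=float))
            fit = model.fit(disp=0, maxiter=200)
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning) as err:
            raise ValueError("perfect separation in logistic fit") from err
    if not fit.mle_retvals.get("converged", True):
        raise ValueError("logistic fit did not converge")
    return fit


def _or_result(fit, names: list[str], term: str, n: int) -> ORResult:
    j = names.index(term)
    coef = fit.params[j]
    se = fit.bse[j]
    return ORResult(
        term=term,
        odds_ratio=float(np.exp(coef)),
        ci_low=float(np.exp(coef - 1.959963984540054 * se)),
        ci_high=float(np.exp(coef + 1.959963984540054 * se)),
        pvalue=float(fit.pvalues[j]),
        n=n,
    )


def fit_association(y, score, covariates: pd.DataFrame | None = None,
                    standardize_score: bool = True) -> ORResult:
    """Odds ratio for one food score, optionally covariate-adjusted.

    The score enters standardized by default (per-SD odds ratio) so the
    three food scores are comparable. ``covariates=None`` gives the
    unadjusted model.
    """
    y = np.asarray(y).astype(int)
    s = standardize(score) if standardize_score else np.asarray(score, float)
    idx = covariates.index if covariates is not None else pd.RangeIndex(len(y))
    parts = [pd.Series(1.0, index=idx, name="const"),
             pd.Series(np.asarray(s, float), index=idx, name="score")]
    if covariates is not None:
        parts.append(encode_covariates(covariates))
    x = pd.concat(parts, axis=1)
    fit = _fit_logit(y, x)
    return _or_result(fit, list(x.columns), "score", len(y))


def tertile_groups(score, fractions: tuple[float, float] = (0.3333, 0.666)
                   ) -> pd.Series:
    """Rank-based low / intermediate / high grouping.

    Subjects whose fractional rank (average rank for ties, midpoint
    convention (rank - 0.5)/n) falls below the first cut are "low", below
    the second "intermediate", else "high". Tied scores share an average
    rank so they never split across groups; if every score is tied the
    result is a single group (with a warning).
    """
    x = np.asarray(score, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 subjects for tertiles")
    lo, hi = fractions
    if not 0 < lo < hi < 1:
        raise ValueError("tertile fractions must be increasing within (0,1)")
    frac = (stats.rankdata(x, method="average") - 0.5) / n
    labels = np.where(frac < lo, "low",
                      np.where(frac < hi, "intermediate", "high"))
    if len(np.unique(labels)) == 1:
        warnings.warn("all scores tied; a single diet-quality group results")
    idx = score.index if isinstance(score, pd.Series) else pd.RangeIndex(n)
    return pd.Series(pd.Categorical(labels, categories=list(TERTILE_LABELS)),
                     index=idx, name="diet_quality")


def group_association(y, groups: pd.Series, reference: str = "high",
                      covariates: pd.DataFrame | None = None
                      ) -> list[ORResult]:
    """Adjusted odds ratio per non-reference group versus ``reference``."""
    y = np.asarray(y).astype(int)
    g = pd.Series(groups).astype("category")
    levels = [l for l in g.cat.categories if (g == l).any()]
    if reference not in levels:
        raise ValueError(f"reference group {reference!r} is empty or unknown")
    others = [l for l in levels if l != reference]
    if not others:
        raise ValueError("need at least two nonempty groups")
    idx = g.index
    parts = [pd.Series(1.0, index=idx, name="const")]
    for l in others:
        parts.append(pd.Series((g == l).astype(float), index=idx, name=f"group_{l}"))
    if covariates is not None:
        parts.append(encode_covariates(covariates))
    x = pd.concat(parts, axis=1)
    fit = _fit_logit(y, x)
    names = list(x.columns)
    return [_or_result(fit, names, f"group_{l}", len(y)) for l in others]
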
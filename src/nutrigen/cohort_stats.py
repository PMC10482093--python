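"""Descriptive case-control statistics: chi-square tests on category tables,
two-sample t-tests from raw data or printed (mean, SD, n) summaries,
Wilcoxon rank-sum and Kolmogorov-Smirnov comparisons, and a baseline
characteristics table builder."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class SummaryGroup:
    """One group's printed summary: mean, SD and sample size."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")
        if self.n < 2:
            raise ValueError("n must be >= 2")

    @classmethod
    def from_raw(cls, x) -> "SummaryGroup":
        x = np.asarray(x, dtype=float)
        return cls(mean=float(x.mean()), sd=float(x.std(ddof=1)), n=len(x))


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    pvalue: float


def t_test_summary(a: SummaryGroup, b: SummaryGroup,
                   variant: str = "welch") -> TestResult:
    """Two-sample t-test from summary statistics (two-sided).

    ``variant='welch'`` uses the Satterthwaite degrees of freedom;
    ``'pooled'`` the classical equal-variance test. Degenerate case of both
    SDs zero with equal means is an error (0/0 statistic).
    """
    if a.sd == 0 and b.sd == 0:
        raise ValueError("both groups have zero SD; t statistic undefined")
    if variant == "welch":
        v1, v2 = a.sd**2 / a.n, b.sd**2 / b.n
        se = np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (a.n - 1) + v2**2 / (b.n - 1))
    elif variant == "pooled":
        sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
        se = np.sqrt(sp2 * (1 / a.n + 1 / b.n))
        df = a.n + b.n - 2
    else:
        raise ValueError("variant must be 'welch' or 'pooled'")
    t = (a.mean - b.mean) / se
    p = 2 * stats.t.sf(abs(t), df)
    return TestResult(statistic=float(t), df=float(df), pvalue=float(p))


def chi2_test(table, yates: str = "auto") -> TestResult:
    """Pearson chi-square on an r x c count table.

    ``yates='auto'`` applies the continuity correction exactly when the
    table is 2x2 (the convention of R's ``chisq.test``); 'on'/'off' force
    it. Zero marginal rows/columns are an error.
    """
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or min(tab.shape) < 2:
        raise ValueError("table must be at least 2x2")
    if (tab < 0).any():
        raise ValueError("table has negative counts")
    if (tab.sum(axis=1) == 0).any() or (tab.sum(axis=0) == 0).any():
        raise ValueError("table has a zero marginal row or column")
    if yates not in ("auto", "on", "off"):
        raise ValueError("yates must be 'auto', 'on' or 'off'")
    correction = (tab.shape == (2, 2)) if yates == "auto" else (yates == "on")
    chi2, p, df, _ = stats.chi2_contingency(tab, correction=correction)
    return TestResult(statistic=float(chi2), df=float(df), pvalue=float(p))


def rank_tests(x, y, exact: bool = False) -> dict[str, float]:
    """Two-sided Wilcoxon rank-sum and two-sample Kolmogorov-Smirnov p-values.

    Default is the normal approximation with tie correction (and continuity
    correction); ``exact=True`` switches to the exact permutation
    distribution, which handles ties correctly and is feasible for small
    samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    method = stats.PermutationMethod(n_resamples=np.inf) if exact else "asymptotic"
    w = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    ks = stats.ks_2samp(x, y)
    return {
        "wilcoxon_statistic": float(w.statistic),
        "wilcoxon_p": float(w.pvalue),
        "ks_statistic": float(ks.statistic),
        "ks_p": float(ks.pvalue),
    }


#: variable kind registry used by build_table1
_CONTINUOUS = "continuous"
_CATEGORICAL = "categorical"


def build_table1(covariates: pd.DataFrame, scores: pd.DataFrame | None,
                 phenotype: pd.Series,
                 kinds: dict[str, str] | None = None) -> pd.DataFrame:
    """Baseline characteristics by case-control status.

    Continuous variables get mean (SD) per group and a Welch t-test;
    categorical variables get n (%) rows and a chi-square test (Yates for
    2x2). ``kinds`` overrides the dtype-based dispatch; an unknown kind is
    an error.
    """
    y = np.asarray(phenotype).astype(int)
    case, ctrl = y == 1, y == 0
    frames = [covariates] if scores is None else [covariates, scores]
    data = pd.concat(frames, axis=1)
    rows = []
    for col in data.columns:
        s = data[col]
        kind = (kinds or {}).get(
            col, _CONTINUOUS if pd.api.types.is_numeric_dtype(s) else _CATEGORICAL
        )
        if kind == _CONTINUOUS:
            a = SummaryGroup.from_raw(s[case])
            b = SummaryGroup.from_raw(s[ctrl])
            res = t_test_summary(a, b)
            rows.append(
                {"variable": col, "level": "",
                 "case": f"{a.mean:.2f} ({a.sd:.2f})",
                 "control": f"{b.mean:.2f} ({b.sd:.2f})",
                 "p": res.pvalue, "test": "t"}
            )
        elif kind == _CATEGORICAL:
            tab = pd.crosstab(s, y).reindex(columns=[1, 0], fill_value=0)
            res = chi2_test(tab.to_numpy().T)
            first = True
            for lev, cnt in tab.iterrows():
                rows.append(
                    {"variable": col, "level": str(lev),
                     "case": f"{cnt[1]} ({100*cnt[1]/case.sum():.2f})",
                     "control": f"{cnt[0]} ({100*cnt[0]/ctrl.sum():.2f})",
                     "p": res.pvalue if first else np.nan, "test": "chi2"}
                )
                first = False
        else:
            raise ValueError(f"unknown variable kind {kind!r} for {col!r}")
    return pd.DataFrame(rows)
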
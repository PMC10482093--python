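"""Genetic stages: polygenic risk scores, per-SNP score-by-genotype
interaction scanning, gene-level and competitive gene-set aggregation with
Benjamini-Hochberg FDR, and the 3x3 genetic-risk by diet-quality grid.

The interaction scan fits, per SNP, the logistic model

    logit P(y=1) = covariates + score + SNP + SNP x score

and records the interaction-term estimate, SE and Wald p — the "interaction
effect" as opposed to the SNP or score main effects. The SNP main effect is
always included (standard hierarchical-interaction practice). SNPs that are
monomorphic or below 5% in-sample minor-allele frequency are skipped with a
recorded reason, mirroring the upstream genotype QC.

Gene aggregation is a deliberately simplified analogue of multi-SNP
gene-based testing: principal components capturing >=95% of a gene's
genotype variance replace its SNPs and all PC x score interaction terms are
tested jointly by likelihood ratio ("pc_regression"), or per-SNP
interaction p-values are combined via the minimum p with an
effective-number-of-tests correction ("p_aggregation"). The gene-set stage
is a competitive test: probit-transformed gene p-values regressed on set
membership, one-sided for enrichment, BH-corrected across sets. Neither
stage claims equivalence to any external gene-set software.

PRS here is the plain weighted allele sum after effect-allele
harmonization; LD-aware reweighting is out of scope (the causal-fraction
tuning parameter of such methods is carried as metadata only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .association import ORResult, _fit_logit, _or_result, encode_covariates, tertile_groups

RISK_LABELS = ("low", "intermediate", "high")


# --------------------------------------------------------------------- PRS

def compute_prs(dosages: pd.DataFrame, weights: pd.DataFrame,
                snp_info: pd.DataFrame) -> tuple[pd.Series, dict]:
    """Weighted allele sum PRS_i = sum_j beta_j . dosage_ij.

    ``weights`` needs columns (snp, effect_allele, beta); ``snp_info`` maps
    each genotyped SNP to its counted allele ``a1`` and other allele ``a2``.
    When the effect allele is the other allele the dosage is flipped to
    2 - d. SNPs whose effect allele matches neither genotyped allele, or
    that are absent from the genotypes, are excluded; the returned info dict
    counts them.
    """
    w = weights.set_index("snp") if "snp" in weights.columns else weights
    used = flipped = excluded = 0
    total = np.zeros(len(dosages))
    for snp, row in w.iterrows():
        if snp not in dosages.columns or snp not in snp_info.index:
            excluded += 1
            continue
        a1, a2 = snp_info.loc[snp, "a1"], snp_info.loc[snp, "a2"]
        d = dosages[snp].to_numpy(dtype=float)
        if row["effect_allele"] == a1:
            pass
        elif row["effect_allele"] == a2:
            d = 2.0 - d
            flipped += 1
        else:
            excluded += 1
            continue
        total += float(row["beta"]) * d
        used += 1
    if excluded:
        warnings.warn(f"{excluded} PRS SNPs excluded (unmatched id or allele)")
    prs = pd.Series(total, index=dosages.index, name="prs")
    return prs, {"n_used": used, "n_flipped": flipped, "n_excluded": excluded}


# -------------------------------------------------------- interaction scan

@dataclass(frozen=True)
class InteractionRecord:
    """Per-SNP interaction-term estimate from the score x genotype model."""

    snp: str
    chrom: str
    pos: int
    beta: float
    se: float
    pvalue: float
    skipped: bool = False
    reason: str = ""


def _interaction_design(score, covariates):
    s = np.asarray(score, dtype=float)
    base = [np.ones(len(s)), s]
    names = ["const", "score"]
    if covariates is not None:
        enc = encode_covariates(covariates)
        base.extend(enc[c].to_numpy(dtype=float) for c in enc.columns)
        names.extend(enc.columns)
    return np.column_stack(base), names, s


def interaction_scan(y, dosages: pd.DataFrame, score,
                     covariates: pd.DataFrame | None = None,
                     snp_info: pd.DataFrame | None = None,
                     min_maf: float = 0.05) -> list[InteractionRecord]:
    """Per-SNP logistic scan for the SNP x score interaction term.

    ``score`` should already be standardized. SNPs with in-sample MAF below
    ``min_maf`` (including monomorphic columns) are returned as skipped
    records rather than fitted.
    """
    y = np.asarray(y).astype(int)
    base, names, s = _interaction_design(score, covariates)
    records: list[InteractionRecord] = []
    for snp in dosages.columns:
        chrom, pos = "", 0
        if snp_info is not None and snp in snp_info.index:
            chrom = str(snp_info.loc[snp, "chrom"])
            pos = int(snp_info.loc[snp, "pos"])
        d = dosages[snp].to_numpy(dtype=float)
        maf = d.mean() / 2.0
        maf = min(maf, 1.0 - maf)
        if maf < min_maf:
            reason = "monomorphic" if d.min() == d.max() else f"maf {maf:.4f} < {min_maf}"
            records.append(InteractionRecord(snp, chrom, pos, np.nan, np.nan,
                                             np.nan, skipped=True, reason=reason))
            continue
        x = np.column_stack([base, d, d * s])
        try:
            fit = sm.Logit(y, x).fit(disp=0, maxiter=200)
        except Exception as err:  # non-convergence / separation on one SNP
            records.append(InteractionRecord(snp, chrom, pos, np.nan, np.nan,
                                             np.nan, skipped=True,
                                             reason=f"fit failed: {err}"))
            continue
        j = x.shape[1] - 1
        records.append(InteractionRecord(
            snp, chrom, pos, float(fit.params[j]), float(fit.bse[j]),
            float(fit.pvalues[j])))
    return records


def interaction_records_frame(records: list[InteractionRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def filter_hits(records: list[InteractionRecord], alpha: float
                ) -> list[InteractionRecord]:
    """Fitted records with interaction p below ``alpha``."""
    return [r for r in records if not r.skipped and r.pvalue < alpha]


# ------------------------------------------------------------ gene mapping

def map_snps_to_genes(records: list[InteractionRecord],
                      gene_locations: pd.DataFrame,
                      window_kb: float = 0.0) -> dict[str, list[str]]:
    """Assign SNPs to every gene whose interval (padded by ``window_kb``)
    contains them; 1-based closed intervals on GRCh37-style coordinates.

    ``gene_locations`` needs columns (gene, chrom, start, end). A record
    whose chromosome label is absent from the table is an error.
    """
    loc = gene_locations.copy()
    loc["chrom"] = loc["chrom"].astype(str)
    standard = {str(i) for i in range(1, 23)} | {"X", "Y", "MT"}
    known = set(loc["chrom"]) | standard
    w = window_kb * 1000.0
    out: dict[str, list[str]] = {}
    for r in records:
        if r.skipped:
            continue
        if str(r.chrom) not in known:
            raise KeyError(f"SNP {r.snp}: unknown chromosome label {r.chrom!r}")
        sub = loc[loc["chrom"] == str(r.chrom)]
        hit = sub[(sub["start"] - w <= r.pos) & (r.pos <= sub["end"] + w)]
        for gene in hit["gene"]:
            out.setdefault(gene, []).append(r.snp)
    return out


# --------------------------------------------------------------- gene test

@dataclass(frozen=True)
class GeneResult:
    gene: str
    n_snps: int
    pvalue: float
    mode: str


def _pcs_95(x: np.ndarray) -> np.ndarray:
    """Principal components capturing >=95% of the variance of ``x``."""
    xc = x - x.mean(axis=0)
    u, sv, _ = np.linalg.svd(xc, full_matrices=False)
    var = sv**2
    keep = var > max(1e-10, 1e-12 * var.max())
    var, u, sv = var[keep], u[:, keep], sv[keep]
    csum = np.cumsum(var) / var.sum()
    k = int(np.searchsorted(csum, 0.95) + 1)
    return u[:, :k] * sv[:k]


def gene_test(y, dosages_in_gene: pd.DataFrame, score,
              covariates: pd.DataFrame | None = None,
              mode: str = "pc_regression", gene: str = "") -> GeneResult:
    """Gene-level interaction test over the gene's SNPs.

    pc_regression: PCs of the gene's dosage matrix replace the SNPs; the
    joint likelihood-ratio test of all PC x score terms (given PC and score
    main effects and covariates) gives the gene p. p_aggregation: minimum
    per-SNP interaction p with an effective-number-of-tests correction
    (effective rank of the dosage correlation matrix,
    Meff = (sum lambda)^2 / sum lambda^2).
    """
    if dosages_in_gene.shape[1] < 1:
        raise ValueError("gene has no SNPs")
    y = np.asarray(y).astype(int)
    d = dosages_in_gene.to_numpy(dtype=float)
    if mode == "pc_regression":
        pcs = _pcs_95(d)
        if len(y) <= pcs.shape[1] + 2:
            raise ValueError("n too small for the number of gene PCs")
        base, names, s = _interaction_design(score, covariates)
        x0 = np.column_stack([base, pcs])
        x1 = np.column_stack([x0, pcs * s[:, None]])
        f0 = sm.Logit(y, x0).fit(disp=0, maxiter=200)
        f1 = sm.Logit(y, x1).fit(disp=0, maxiter=200)
        lr = 2.0 * (f1.llf - f0.llf)
        p = float(stats.chi2.sf(max(lr, 0.0), df=pcs.shape[1]))
        return GeneResult(gene, dosages_in_gene.shape[1], p, mode)
    if mode == "p_aggregation":
        recs = interaction_scan(y, dosages_in_gene, score, covariates,
                                min_maf=0.0)
        pvals = np.array([r.pvalue for r in recs if not r.skipped])
        if pvals.size == 0:
            raise ValueError("no fit succeeded for any SNP in the gene")
        if d.shape[1] == 1:
            meff = 1.0
        else:
            corr = np.corrcoef(d, rowvar=False)
            corr = np.nan_to_num(corr, nan=0.0)
            np.fill_diagonal(corr, 1.0)
            lam = np.linalg.eigvalsh(corr)
            meff = float(lam.sum() ** 2 / (lam**2).sum())
        p = float(1.0 - (1.0 - pvals.min()) ** meff)
        return GeneResult(gene, dosages_in_gene.shape[1], p, mode)
    raise ValueError("mode must be 'pc_regression' or 'p_aggregation'")


def interaction_lrt(y, dosage_col, score, covariates=None) -> float:
    """Likelihood-ratio p for one SNP's interaction term (df=1 oracle for
    the single-SNP gene test)."""
    y = np.asarray(y).astype(int)
    d = np.asarray(dosage_col, dtype=float)
    base, _, s = _interaction_design(score, covariates)
    x0 = np.column_stack([base, d])
    x1 = np.column_stack([x0, d * s])
    f0 = sm.Logit(y, x0).fit(disp=0, maxiter=200)
    f1 = sm.Logit(y, x1).fit(disp=0, maxiter=200)
    return float(stats.chi2.sf(max(2.0 * (f1.llf - f0.llf), 0.0), df=1))


# ----------------------------------------------------------- gene-set test

@dataclass(frozen=True)
class GeneSetResult:
    set_id: str
    n_genes: int
    pvalue: float
    qvalue: float = field(default=np.nan)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def gene_set_test(gene_results: list[GeneResult],
                  sets: dict[str, list[str]]) -> list[GeneSetResult]:
    """Competitive enrichment: regress probit gene z-scores on membership.

    z_g = -Phi^{-1}(p_g); per set, OLS of z on an intercept and the 0/1
    membership indicator, one-sided p for a positive membership
    coefficient; BH q-values across sets. Sets with no scored genes are
    dropped with a warning; an empty GMT, or fewer than two scored genes,
    is an error.
    """
    if not sets:
        raise ValueError("empty gene-set collection")
    if len(gene_results) < 2:
        raise ValueError("need >=2 scored genes for a competitive test")
    genes = [g.gene for g in gene_results]
    pvals = np.clip([g.pvalue for g in gene_results], 1e-300, 1 - 1e-16)
    z = -stats.norm.ppf(pvals)
    out: list[tuple[str, int, float]] = []
    for set_id, members in sets.items():
        m = np.isin(genes, list(members)).astype(float)
        n_in = int(m.sum())
        if n_in == 0:
            warnings.warn(f"gene set {set_id!r} has no scored genes; dropped")
            continue
        if n_in == len(genes) or np.ptp(z) == 0:
            p = 1.0  # no contrast: membership indistinguishable from background
        else:
            x = sm.add_constant(m)
            fit = sm.OLS(z, x).fit()
            t = fit.tvalues[1]
            p = float(stats.t.sf(t, df=fit.df_resid))
        out.append((set_id, n_in, p))
    if not out:
        raise ValueError("no gene set overlapped the scored genes")
    q = bh_fdr([p for _, _, p in out])
    return [GeneSetResult(sid, n, p, float(qv))
            for (sid, n, p), qv in zip(out, q)]


# -------------------------------------------------- risk x diet 3x3 grid

def risk_by_diet_grid(y, prs: pd.Series, diet_groups: pd.Series,
                      covariates: pd.DataFrame | None = None,
                      reference: tuple[str, str] = ("low", "high")
                      ) -> pd.DataFrame:
    """Adjusted odds ratios for the nine genetic-risk x diet-quality cells.

    PRS is cut into low/intermediate/high tertiles by the same rank rule as
    diet quality; the cross-classification is dummy-coded against the
    (low genetic risk, high diet quality) reference cell. Empty cells are
    reported with ``empty=True`` and no odds ratio.
    """
    y = np.asarray(y).astype(int)
    risk = tertile_groups(prs).cat.rename_categories(
        dict(zip(("low", "intermediate", "high"), RISK_LABELS)))
    diet = pd.Series(diet_groups)
    cells = [(r, dq) for r in RISK_LABELS for dq in ("low", "intermediate", "high")]
    ref = reference
    idx = prs.index
    parts = [pd.Series(1.0, index=idx, name="const")]
    names_by_cell = {}
    counts = {}
    for r, dq in cells:
        mask = ((risk == r) & (diet == dq)).to_numpy()
        counts[(r, dq)] = int(mask.sum())
        if (r, dq) == ref:
            continue
        name = f"risk_{r}__diet_{dq}"
        names_by_cell[(r, dq)] = name
        parts.append(pd.Series(mask.astype(float), index=idx, name=name))
    nonempty = [c for c in cells if counts[c] > 0 and c != ref]
    x = pd.concat([p for p in parts
                   if p.name == "const" or p.sum() > 0], axis=1)
    if covariates is not None:
        x = pd.concat([x, encode_covariates(covariates)], axis=1)
    fit = _fit_logit(y, x)
    xnames = list(x.columns)
    rows = []
    for r, dq in cells:
        if (r, dq) == ref:
            rows.append({"risk": r, "diet": dq, "n": counts[(r, dq)],
                         "reference": True, "empty": counts[(r, dq)] == 0,
                         "odds_ratio": 1.0, "ci_low": np.nan,
                         "ci_high": np.nan, "pvalue": np.nan})
            continue
        if counts[(r, dq)] == 0:
            rows.append({"risk": r, "diet": dq, "n": 0, "reference": False,
                         "empty": True, "odds_ratio": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan,
                         "pvalue": np.nan})
            continue
        res = _or_result(fit, xnames, names_by_cell[(r, dq)], len(y))
        rows.append({"risk": r, "diet": dq, "n": counts[(r, dq)],
                     "reference": False, "empty": False,
                     "odds_ratio": res.odds_ratio, "ci_low": res.ci_low,
                     "ci_high": res.ci_high, "pvalue": res.pvalue})
    return pd.DataFrame(rows)
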
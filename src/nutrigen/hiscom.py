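"""Hierarchical structural component model for weighted food scores.

The model places the 46 binary item indicators g_itk inside 10 food-group
latent components and links them to a binary outcome through a logistic
model:

    logit(pi_i) = beta_0 + sum_k [ sum_t g_itk w_itk ] beta_k

Item weights w and group coefficients beta are estimated jointly by
alternating least squares (ALS) on the iteratively-reweighted working
response of the logistic link: Step 1 updates beta (and the intercept)
holding w fixed; Step 2 updates w holding beta fixed under a ridge penalty
lambda1 on the item weights only (no penalty on the group coefficients).
Identification follows the generalized-structured-component-analysis
convention: each group's component sum_t g_itk w_itk is scaled to unit
sample variance, and signs are fixed so the within-group weight sum is
nonnegative. Flipping the sign of any (w_k, beta_k) pair leaves the
likelihood and the weighted score unchanged, so the sign fix is what makes
output deterministic.

The per-subject weighted score ("HisCoM-RFS") is the linear predictor
without the intercept, sum_k [sum_t g_itk w_itk] beta_k, evaluated on the
raw indicators — zero for an all-zero response row.

Numerical notes: columns are standardized internally for conditioning (the
ridge acts in the standardized metric); reported weights are mapped back to
the raw indicator scale, with the centering constant absorbed into beta_0.
Each ALS sweep ends with a backtracking line search toward the previous
iterate, which makes the penalized deviance non-increasing by construction
(GSCA-style renormalization alone does not guarantee descent under the
working-response approximation). Parameter significance is assessed by
permutation: the phenotype vector is resampled, the model refitted, and
p = (1 + #{|stat_perm| >= |stat_obs|}) / (B + 1) per parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .panel import FoodPanel, default_panel

_MU_EPS = 1e-10


def _group_slices(groups: Sequence[str]) -> tuple[tuple[str, ...], list[np.ndarray]]:
    """Column-index arrays per group, in first-appearance order."""
    labels: list[str] = []
    for g in groups:
        if g not in labels:
            labels.append(g)
    idx = [np.flatnonzero(np.asarray(groups, dtype=object) == g) for g in labels]
    return tuple(labels), idx


def _deviance(y: np.ndarray, eta: np.ndarray) -> float:
    mu = np.clip(expit(eta), _MU_EPS, 1 - _MU_EPS)
    return -2.0 * float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


class HiscomModel:
    """Hierarchical structural component logistic model.

    Parameters
    ----------
    endog : array-like of 0/1, length n
        Binary phenotype (e.g. disease case-control status).
    gmatrix : DataFrame or array, n x p, binary
        Item-indicator matrix; columns in panel order.
    groups : sequence of str, length p, optional
        Group label per column. Defaults to the shipped 46-item panel's
        groups when ``gmatrix`` has 46 columns.
    """

    def __init__(self, endog, gmatrix, groups: Sequence[str] | None = None,
                 panel: FoodPanel | None = None):
        if isinstance(gmatrix, pd.DataFrame):
            self.item_names = list(gmatrix.columns)
            g = gmatrix.to_numpy(dtype=float)
        else:
            g = np.asarray(gmatrix, dtype=float)
            self.item_names = [f"item_{j}" for j in range(g.shape[1])]
        y = np.asarray(endog, dtype=float).ravel()
        if y.shape[0] != g.shape[0]:
            raise ValueError("endog and gmatrix have different numbers of rows")
        uniq = np.unique(y)
        if not np.all(np.isin(uniq, [0.0, 1.0])):
            raise ValueError("endog must be binary 0/1")
        if uniq.size < 2:
            raise ValueError("endog is constant; the model is not identifiable")
        if not np.all(np.isin(np.unique(g), [0.0, 1.0])):
            raise ValueError("gmatrix entries must be binary 0/1")
        if groups is None:
            panel = panel or (default_panel() if g.shape[1] == 46 else None)
            if panel is None:
                raise ValueError("groups required when gmatrix is not the 46-item panel")
            groups = [panel.group_of_item[it] for it in
                      (panel.items if self.item_names[0].startswith("item_") else self.item_names)]
        if len(groups) != g.shape[1]:
            raise ValueError("one group label per gmatrix column required")
        self.endog = y
        self.gmatrix = g
        self.group_labels, self.group_cols = _group_slices(list(groups))
        self.groups = list(groups)

    # ------------------------------------------------------------------ fit
    def fit(self, lambda1: float = 1.0, tol: float = 1e-6,
            max_iter: int = 500) -> "HiscomResults":
        """Fit by penalized IRLS-ALS.

        ``lambda1`` is the ridge penalty on item weights (standardized
        metric); the group-coefficient penalty is identically zero.
        """
        if lambda1 < 0:
            raise ValueError("lambda1 must be nonnegative")
        g, y = self.gmatrix, self.endog
        n, p = g.shape
        col_mean = g.mean(axis=0)
        col_sd = g.std(axis=0)
        zero_var = col_sd == 0
        if zero_var.any() and lambda1 == 0:
            bad = [self.item_names[j] for j in np.flatnonzero(zero_var)]
            raise np.linalg.LinAlgError(
                f"constant indicator columns {bad} make the unpenalized "
                "weight update singular; set lambda1 > 0 or drop them"
            )
        sd_safe = np.where(zero_var, 1.0, col_sd)
        z = (g - col_mean) / sd_safe

        labels, cols = self.group_labels, self.group_cols
        K = len(labels)

        # init: equal weights per group, components scaled to unit variance
        w = np.zeros(p)
        for ci in cols:
            live = ci[~zero_var[ci]]
            if live.size == 0:
                raise np.linalg.LinAlgError(
                    f"group with only constant columns: {labels[cols.index(ci)]}"
                )
            w[live] = 1.0 / np.sqrt(live.size)
        w = self._normalize(z, w, cols)[0]
        f = self._components(z, w, cols)
        beta = np.zeros(K)
        beta0 = float(np.log(y.mean() / (1 - y.mean())))

        def objective(beta0, beta, w):
            eta = beta0 + self._components(z, w, cols) @ beta
            return _deviance(y, eta) + lambda1 * float(w @ w)

        obj = objective(beta0, beta, w)
        trace = [obj]
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            beta0_old, beta_old, w_old = beta0, beta.copy(), w.copy()
            eta = beta0 + f @ beta
            mu = np.clip(expit(eta), _MU_EPS, 1 - _MU_EPS)
            v = mu * (1 - mu)
            work = eta + (y - mu) / v

            # Step 1: update (beta0, beta) for fixed w — weighted LS
            a = np.column_stack([np.ones(n), f])
            aw = a * v[:, None]
            beta_full, *_ = np.linalg.lstsq(a.T @ aw, a.T @ (v * work), rcond=None)
            beta0_new, beta_new = float(beta_full[0]), beta_full[1:]

            # Step 2: update w for fixed beta — weighted ridge LS
            xw = np.empty_like(z)
            for k, ci in enumerate(cols):
                xw[:, ci] = z[:, ci] * beta_new[k]
            lhs = xw.T @ (xw * v[:, None])
            lhs[np.diag_indices_from(lhs)] += lambda1
            rhs = xw.T @ (v * (work - beta0_new))
            try:
                w_new = np.linalg.solve(lhs, rhs)
            except np.linalg.LinAlgError as err:
                raise np.linalg.LinAlgError(
                    "singular weight update; increase lambda1"
                ) from err
            w_new[zero_var] = 0.0
            w_new, scale = self._normalize(z, w_new, cols)
            beta_new = beta_new * scale  # component scale folded into beta
            # sign-align with the previous iterate (likelihood-invariant)
            # so the backtracking blend cannot pass through a zero component
            for k, ci in enumerate(cols):
                if w_old[ci] @ w_new[ci] < 0:
                    w_new[ci] = -w_new[ci]
                    beta_new[k] = -beta_new[k]

            # Backtracking toward the previous iterate keeps the penalized
            # deviance non-increasing despite renormalization.
            step = 1.0
            for _ in range(40):
                try:
                    w_try = self._blend(w_old, w_new, step, z, cols)
                except np.linalg.LinAlgError:
                    step *= 0.5
                    continue
                beta_try = beta_old + step * (beta_new - beta_old)
                beta0_try = beta0_old + step * (beta0_new - beta0_old)
                obj_try = objective(beta0_try, beta_try, w_try)
                if obj_try <= obj + 1e-12:
                    break
                step *= 0.5
            else:
                trace.append(obj)
                converged = True
                break
            beta0, beta, w = beta0_try, beta_try, w_try
            f = self._components(z, w, cols)
            delta = obj - obj_try
            obj = obj_try
            trace.append(obj)
            rel = (np.abs(np.concatenate([[beta0 - beta0_old], beta - beta_old,
                                          w - w_old])).max()
                   / max(1.0, np.abs(np.concatenate([[beta0], beta, w])).max()))
            if rel < tol or delta < tol * 1e-3:
                converged = True
                break

        # canonical sign: within-group weight sum nonnegative
        for k, ci in enumerate(cols):
            if w[ci].sum() < 0:
                w[ci] = -w[ci]
                beta[k] = -beta[k]

        # map back to the raw indicator scale; centering goes to beta0
        w_raw = w / sd_safe
        shift = 0.0
        for k, ci in enumerate(cols):
            shift += float((col_mean[ci] / sd_safe[ci]) @ w[ci]) * beta[k]
        beta0_raw = beta0 - shift

        return HiscomResults(
            model=self, w=w_raw, beta=beta, beta0=beta0_raw,
            w_std=w, col_mean=col_mean, col_sd=sd_safe,
            lambda1=lambda1, lambda2=0.0, n_iter=it, converged=converged,
            objective_trace=np.asarray(trace), tol=tol, max_iter=max_iter,
        )

    # -------------------------------------------------------------- helpers
    @staticmethod
    def _components(z: np.ndarray, w: np.ndarray, cols) -> np.ndarray:
        return np.column_stack([z[:, ci] @ w[ci] for ci in cols])

    @staticmethod
    def _normalize(z, w, cols):
        """Scale each group's weights so its component has unit variance."""
        w = w.copy()
        scale = np.empty(len(cols))
        for k, ci in enumerate(cols):
            s = float((z[:, ci] @ w[ci]).std())
            if s == 0:
                raise np.linalg.LinAlgError(
                    "degenerate component (zero variance); check input columns"
                )
            w[ci] /= s
            scale[k] = s
        return w, scale

    @classmethod
    def _blend(cls, w_old, w_new, step, z, cols):
        w = w_old + step * (w_new - w_old)
        return cls._normalize(z, w, cols)[0]


@dataclass
class HiscomResults:
    """Fitted HisCoM parameters and diagnostics.

    ``w`` holds item weights on the raw indicator scale (each group
    component sum_t g_itk w_itk has unit sample variance); ``w_std`` the
    same weights in the standardized-column metric (a single-item group has
    ``w_std`` = +/-1 there). ``beta`` are the group coefficients and
    ``beta0`` the intercept; the weighted score excludes the intercept.
    """

    model: HiscomModel
    w: np.ndarray
    beta: np.ndarray
    beta0: float
    w_std: np.ndarray
    col_mean: np.ndarray
    col_sd: np.ndarray
    lambda1: float
    lambda2: float
    n_iter: int
    converged: bool
    objective_trace: np.ndarray
    tol: float
    max_iter: int
    perm_p_beta: np.ndarray | None = field(default=None)
    perm_p_w: np.ndarray | None = field(default=None)

    @property
    def deviance(self) -> float:
        g = self.model.gmatrix
        return _deviance(self.model.endog, self.beta0 + self._score_array(g))

    def _score_array(self, g: np.ndarray) -> np.ndarray:
        cols = self.model.group_cols
        out = np.zeros(g.shape[0])
        for k, ci in enumerate(cols):
            out += (g[:, ci] @ self.w[ci]) * self.beta[k]
        return out

    def score(self, gmatrix=None) -> np.ndarray | pd.Series:
        """Weighted food score sum_k [sum_t g_itk w_itk] beta_k (no intercept)."""
        if gmatrix is None:
            gmatrix = self.model.gmatrix
        if isinstance(gmatrix, pd.DataFrame):
            vals = self._score_array(gmatrix.to_numpy(dtype=float))
            return pd.Series(vals, index=gmatrix.index, name="hiscom_rfs")
        g = np.asarray(gmatrix, dtype=float)
        if g.ndim != 2 or g.shape[1] != self.w.shape[0]:
            raise ValueError(
                f"gmatrix must have {self.w.shape[0]} columns, got {g.shape}"
            )
        return self._score_array(g)

    def permutation_test(self, B: int = 999, seed: int = 0) -> "HiscomResults":
        """Phenotype-resampling significance for beta and w.

        Refits the model under ``B`` random permutations of the phenotype and
        computes p = (1 + #{|stat_perm| >= |stat_obs|}) / (B + 1) per group
        coefficient and per item weight. Returns ``self`` with ``perm_p_beta``
        and ``perm_p_w`` filled in.
        """
        if B < 1:
            raise ValueError("B must be >= 1")
        rng = np.random.default_rng(seed)
        model = self.model
        ge_beta = np.zeros(self.beta.shape[0])
        ge_w = np.zeros(self.w.shape[0])
        abs_beta, abs_w = np.abs(self.beta), np.abs(self.w)
        for _ in range(B):
            yperm = rng.permutation(model.endog)
            res = HiscomModel(yperm, model.gmatrix, groups=model.groups).fit(
                lambda1=self.lambda1, tol=self.tol, max_iter=self.max_iter
            )
            ge_beta += np.abs(res.beta) >= abs_beta
            ge_w += np.abs(res.w) >= abs_w
        self.perm_p_beta = (1.0 + ge_beta) / (B + 1.0)
        self.perm_p_w = (1.0 + ge_w) / (B + 1.0)
        return self

    def summary(self) -> str:
        """Plain-text parameter table."""
        lines = [
            "Hierarchical structural component model (logistic link)",
            f"  n={self.model.gmatrix.shape[0]}  items={self.model.gmatrix.shape[1]}"
            f"  groups={len(self.model.group_labels)}",
            f"  lambda1={self.lambda1:g}  lambda2=0  deviance={self.deviance:.3f}"
            f"  iterations={self.n_iter}  converged={self.converged}",
            f"  intercept beta0={self.beta0:+.4f}",
            "",
            f"  {'group':<16}{'beta':>10}" + ("{:>12}".format("perm p") if self.perm_p_beta is not None else ""),
        ]
        for k, lab in enumerate(self.model.group_labels):
            row = f"  {lab:<16}{self.beta[k]:>10.4f}"
            if self.perm_p_beta is not None:
                row += f"{self.perm_p_beta[k]:>12.4f}"
            lines.append(row)
        lines.append("")
        lines.append(f"  {'item':<20}{'weight':>10}" + ("{:>12}".format("perm p") if self.perm_p_w is not None else ""))
        for j, item in enumerate(self.model.item_names):
            row = f"  {item:<20}{self.w[j]:>10.4f}"
            if self.perm_p_w is not None:
                row += f"{self.perm_p_w[j]:>12.4f}"
            lines.append(row)
        return "\n".join(lines)

    def plot_weights(self, ax=None):
        """Bar plot of item weights, colour-grouped by food group."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        colors = plt.cm.tab10(np.linspace(0, 1, len(self.model.group_labels)))
        lab_ix = {g: i for i, g in enumerate(self.model.group_labels)}
        cvec = [colors[lab_ix[g]] for g in self.model.groups]
        ax.bar(range(len(self.w)), self.w, color=cvec)
        ax.set_xlabel("item")
        ax.set_ylabel("weight")
        return ax

    def to_dict(self) -> dict:
        return {
            "items": self.model.item_names,
            "groups": self.model.groups,
            "w": self.w.tolist(),
            "beta": self.beta.tolist(),
            "beta0": self.beta0,
            "lambda1": self.lambda1,
            "lambda2": self.lambda2,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "objective_trace": self.objective_trace.tolist(),
            "perm_p_beta": None if self.perm_p_beta is None else self.perm_p_beta.tolist(),
            "perm_p_w": None if self.perm_p_w is None else self.perm_p_w.tolist(),
        }


# ------------------------------------------------------ module-level surface

def fit_hiscom(g, y, lambda1: float = 1.0, groups=None, **kwargs) -> HiscomResults:
    """Convenience wrapper: build a :class:`HiscomModel` and fit it."""
    return HiscomModel(y, g, groups=groups).fit(lambda1=lambda1, **kwargs)


def compute_hiscom_rfs(fit: HiscomResults, g) -> np.ndarray | pd.Series:
    """Weighted food score for ``g`` under a fitted model (no intercept)."""
    return fit.score(g)


def permutation_test(g, y, lambda1: float, B: int, seed: int = 0,
                     groups=None) -> tuple[np.ndarray, np.ndarray]:
    """Fit then permutation-test; returns (perm_p_beta, perm_p_w)."""
    res = fit_hiscom(g, y, lambda1=lambda1, groups=groups)
    res.permutation_test(B=B, seed=seed)
    return res.perm_p_beta, res.perm_p_w


def select_lambda1(g, y, grid: Sequence[float], k_folds: int = 5,
                   seed: int = 0, groups=None) -> float:
    """Pick lambda1 from ``grid`` by k-fold cross-validated predictive deviance.

    Folds are a seeded shuffle split; ties break toward the smaller penalty.
    A fold whose training phenotype is constant is an error (stratify or
    enlarge folds).
    """
    grid = sorted(set(float(v) for v in grid))
    if not grid:
        raise ValueError("lambda1 grid must be nonempty")
    if isinstance(g, pd.DataFrame):
        g_arr = g.to_numpy(dtype=float)
    else:
        g_arr = np.asarray(g, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k_folds)
    cv_dev = np.zeros(len(grid))
    for test_idx in folds:
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        ytr, yte = y[mask], y[test_idx]
        if ytr.min() == ytr.max():
            raise ValueError("cross-validation fold with constant phenotype")
        gtr, gte = g_arr[mask], g_arr[test_idx]
        for i, lam in enumerate(grid):
            res = HiscomModel(ytr, gtr, groups=groups).fit(lambda1=lam)
            eta = res.beta0 + res._score_array(gte)
            cv_dev[i] += _deviance(yte, eta)
    return grid[int(np.argmin(cv_dev))]
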
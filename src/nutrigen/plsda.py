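"""PLS-discriminant-analysis weighted food score.

Partial least squares regression of the centered 0/1 outcome on the centered
item-indicator matrix; the first weight direction maximizes covariance
between the component scores and the outcome, and the per-item regression
coefficient vector (the first — and for a single outcome only — column of
the PLS coefficient matrix) turns an indicator row into the weighted score

    PLSDA-RFS_i = sum_j g_ij c_j .

Food groups are deliberately ignored: unlike the hierarchical component
model this is a flat 46-item discriminant weighting. The fit is backed by
scikit-learn's NIPALS ``PLSRegression``; the one-component direction has
the closed form w1 proportional to Gc' (y - ybar), which the test suite
checks independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression


class PlsdaModel:
    """PLS-DA of a binary outcome on the item-indicator matrix.

    ``n_components`` defaults to 1: only the first coefficient column is
    used for scoring, and a single component already carries the
    covariance-maximizing direction.
    """

    def __init__(self, endog, gmatrix, n_components: int = 1, scale: bool = False):
        if isinstance(gmatrix, pd.DataFrame):
            self.item_names = list(gmatrix.columns)
            g = gmatrix.to_numpy(dtype=float)
        else:
            g = np.asarray(gmatrix, dtype=float)
            self.item_names = [f"item_{j}" for j in range(g.shape[1])]
        y = np.asarray(endog, dtype=float).ravel()
        if y.shape[0] != g.shape[0]:
            raise ValueError("endog and gmatrix have different numbers of rows")
        if not np.all(np.isin(np.unique(y), [0.0, 1.0])):
            raise ValueError("endog must be binary 0/1")
        if scale and (g.std(axis=0) == 0).any():
            bad = [self.item_names[j] for j in np.flatnonzero(g.std(axis=0) == 0)]
            raise ValueError(f"constant columns cannot be scaled: {bad}")
        self.endog = y
        self.gmatrix = g
        self.n_components = int(n_components)
        self.scale = scale

    def fit(self) -> "PlsdaResults":
        pls = PLSRegression(n_components=self.n_components, scale=self.scale)
        pls.fit(self.gmatrix, self.endog)
        coef = np.asarray(pls.coef_).reshape(-1)  # (p,) for a single outcome
        return PlsdaResults(
            model=self,
            weight_matrix=np.asarray(pls.x_weights_),
            scores=np.asarray(pls.x_scores_),
            coef_first=coef,
            x_mean=np.asarray(pls._x_mean),
            y_mean=float(np.asarray(pls._y_mean).reshape(-1)[0]),
            x_std=np.asarray(pls._x_std),
        )


@dataclass
class PlsdaResults:
    """Fitted PLS-DA weights and the per-item scoring coefficients.

    ``weight_matrix`` is items x components; ``coef_first`` the length-46
    coefficient vector (weight matrix combined with the loadings and the
    outcome weights — the first column of the coefficient matrix for the
    single binary outcome).
    """

    model: PlsdaModel
    weight_matrix: np.ndarray
    scores: np.ndarray
    coef_first: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    x_std: np.ndarray

    def score(self, gmatrix=None) -> np.ndarray | pd.Series:
        """PLSDA-RFS: indicator row dotted with the per-item coefficients."""
        if gmatrix is None:
            gmatrix = self.model.gmatrix
        if isinstance(gmatrix, pd.DataFrame):
            vals = gmatrix.to_numpy(dtype=float) @ self.coef_first
            return pd.Series(vals, index=gmatrix.index, name="plsda_rfs")
        g = np.asarray(gmatrix, dtype=float)
        if g.shape[-1] != self.coef_first.shape[0]:
            raise ValueError(
                f"gmatrix must have {self.coef_first.shape[0]} columns"
            )
        return g @ self.coef_first

    def predict_proba_linear(self, gmatrix=None) -> np.ndarray:
        """Fitted linear predictor of the 0/1 outcome (for CV diagnostics)."""
        if gmatrix is None:
            gmatrix = self.model.gmatrix
        g = np.asarray(gmatrix, dtype=float)
        return (g - self.x_mean) @ self.coef_first + self.y_mean

    def summary(self) -> str:
        lines = [
            "PLS-DA weighted food score",
            f"  n={self.model.gmatrix.shape[0]}  items={len(self.model.item_names)}"
            f"  components={self.model.n_components}",
            "",
            f"  {'item':<20}{'coef':>12}{'w1':>12}",
        ]
        for j, item in enumerate(self.model.item_names):
            lines.append(
                f"  {item:<20}{self.coef_first[j]:>12.5f}{self.weight_matrix[j, 0]:>12.5f}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "items": self.model.item_names,
            "n_components": self.model.n_components,
            "coef_first": self.coef_first.tolist(),
            "weight_matrix": self.weight_matrix.tolist(),
        }


def fit_plsda(g, y, n_components: int = 1, scale: bool = False) -> PlsdaResults:
    """Convenience wrapper: build a :class:`PlsdaModel` and fit it."""
    return PlsdaModel(y, g, n_components=n_components, scale=scale).fit()


def compute_plsda_rfs(fit: PlsdaResults, g) -> np.ndarray | pd.Series:
    return fit.score(g)
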
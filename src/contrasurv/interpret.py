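"""Two-step feature importance: L1-penalised selection, then OLS with
Wald t-tests on the selected set.

The response is, by default, the fused model's predicted risk score, so
the table explains what the model pays attention to (not raw survival).
The reported p-values are post-selection and nominal: selecting features
with the lasso and then testing them with ordinary least squares on the
same data is anti-conservative, and the output labels them as such.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import Lasso, LassoCV

from .data import ValidationError
from .preprocess import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = ["ImportanceTable", "lasso_ols_importance", "default_penalty_grid",
           "lasso_selected"]

LASSO_TOL = 1e-7


@dataclass
class ImportanceTable:
    """Post-selection OLS coefficients; rows sorted by |coefficient|."""

    table: pd.DataFrame  # feature, coefficient, ci_low, ci_high, p_value, ...
    penalty: float
    note: str = "post-selection, nominal"

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.table)


def default_penalty_grid(X: np.ndarray, y: np.ndarray,
                         n_points: int = 50, decades: float = 4.0
                         ) -> np.ndarray:
    """Log-spaced grid from the all-zero penalty down ``decades`` decades."""
    yc = y - y.mean()
    alpha_max = np.abs(X.T @ yc).max() / len(y)
    alpha_max = max(alpha_max, 1e-12)
    return np.logspace(np.log10(alpha_max), np.log10(alpha_max) - decades,
                       n_points)


def lasso_selected(X: np.ndarray, y: np.ndarray, penalty: float,
                   ) -> np.ndarray:
    """Indices of features with nonzero lasso coefficients at one penalty."""
    fit = Lasso(alpha=penalty, fit_intercept=True, tol=LASSO_TOL,
                max_iter=100_000).fit(X, y)
    return np.where(fit.coef_ != 0)[0]


def _drop_collinear(X: np.ndarray, names: list[str]
                    ) -> tuple[np.ndarray, list[str]]:
    keep: list[int] = []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand) > len(keep):
            keep.append(j)
        else:
            logger.warning("dropping collinear feature %r", names[j])
    return X[:, keep], [names[i] for i in keep]


def lasso_ols_importance(features: FeatureMatrix, response: np.ndarray,
                         penalty_grid: np.ndarray | None = None,
                         cv_folds: int = 5, seed: int = 0) -> ImportanceTable:
    """Lasso selection (penalty by CV prediction error) then OLS inference.

    Returns a table of selected features with OLS coefficients, 95%
    Wald confidence intervals and two-sided t-test p-values
    (df = n - p_selected - 1). An empty selection yields an empty table
    with a warning rather than an error.
    """
    X = np.asarray(features.values, float)
    y = np.asarray(response, float)
    if X.shape[0] != y.shape[0]:
        raise ValidationError("features and response misaligned")
    if np.any(~np.isfinite(y)) or np.any(~np.isfinite(X)):
        raise ValidationError("non-finite inputs")
    if penalty_grid is None:
        penalty_grid = default_penalty_grid(X, y)
    cv = LassoCV(alphas=np.sort(penalty_grid)[::-1], cv=cv_folds,
                 tol=LASSO_TOL, max_iter=100_000,
                 random_state=seed).fit(X, y)
    selected = np.where(cv.coef_ != 0)[0]
    if selected.size == 0:
        logger.warning("lasso selected no features")
        empty = pd.DataFrame(columns=["feature", "coefficient", "ci_low",
                                      "ci_high", "p_value",
                                      "selected_by_lasso"])
        return ImportanceTable(table=empty, penalty=float(cv.alpha_))
    names = [features.feature_names[j] for j in selected]
    Xs, names = _drop_collinear(X[:, selected], names)
    if X.shape[0] <= Xs.shape[1] + 1:
        raise ValidationError("not enough samples for post-selection OLS")
    ols = sm.OLS(y, sm.add_constant(Xs)).fit()
    ci = ols.conf_int(alpha=0.05)
    table = pd.DataFrame({
        "feature": names,
        "coefficient": ols.params[1:],
        "ci_low": ci[1:, 0],
        "ci_high": ci[1:, 1],
        "p_value": ols.pvalues[1:],
        "selected_by_lasso": True,
    })
    table = table.reindex(
        table["coefficient"].abs().sort_values(ascending=False).index
    ).reset_index(drop=True)
    return ImportanceTable(table=table, penalty=float(cv.alpha_))
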
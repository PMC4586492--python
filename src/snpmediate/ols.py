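"""Ordinary least squares with the per-term statistics reported in mediation tables.

The fits here back every path regression in the package: coefficient, standard
error, t statistic, two-sided p-value from the t distribution with ``n - p``
degrees of freedom, and 95% confidence limits — the ``b / SE / t / P / 95% CI``
layout familiar from epidemiological regression tables.

The solver uses a QR decomposition rather than explicit inversion of the
normal equations; lipid covariates in cohort data are frequently
near-collinear and an orthogonal decomposition keeps the fit stable there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats


class ModelError(ValueError):
    """Raised when a design matrix cannot support the requested fit."""


@dataclass
class ModelFit:
    """OLS fit summary for one regression equation.

    Attributes
    ----------
    terms : list of str
        Design column names, intercept first by convention.
    coefficients, standard_errors, t_statistics, p_values : ndarray
        Per-term estimates and inference; p-values are two-sided from the
        t distribution with ``n_obs - n_params`` degrees of freedom.
    ci_lower, ci_upper : ndarray
        95% confidence limits per term.
    residuals : ndarray
        Per-subject residuals, in the original row order of the fit.
    sigma2 : float
        Residual variance (RSS / (n - p)).
    r_squared : float
        Coefficient of determination; centred when the model has an
        intercept, uncentred otherwise.
    """

    terms: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    t_statistics: np.ndarray
    p_values: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    residuals: np.ndarray
    sigma2: float
    r_squared: float
    n_obs: int
    n_params: int
    alpha: float = 0.05
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._index = {t: i for i, t in enumerate(self.terms)}

    def coef(self, term: str) -> float:
        """Coefficient for a named term."""
        return float(self.coefficients[self._index[term]])

    def se(self, term: str) -> float:
        return float(self.standard_errors[self._index[term]])

    @property
    def residual_sd(self) -> float:
        return float(np.sqrt(self.sigma2))

    def to_frame(self) -> pd.DataFrame:
        """Table in the ``Factors, b, SE, t, P, 95% CI LL/UL`` layout."""
        return pd.DataFrame(
            {
                "Factors": self.terms,
                "b": self.coefficients,
                "SE": self.standard_errors,
                "t": self.t_statistics,
                "P": self.p_values,
                "LL": self.ci_lower,
                "UL": self.ci_upper,
            }
        )


def _collinear_columns(design: np.ndarray, names: list[str], rank: int) -> list[str]:
    # pivoted QR: columns pivoted beyond the numerical rank are the dependent ones
    _, _, piv = scipy.linalg.qr(design, mode="economic", pivoting=True)
    return [names[j] for j in sorted(piv[rank:])]


def fit_ols(design: np.ndarray, response: np.ndarray, terms: list[str] | None = None,
            alpha: float = 0.05) -> ModelFit:
    """Fit a linear model by QR-based least squares.

    Parameters
    ----------
    design : (n, p) array
        Predictor matrix including the intercept column if one is wanted.
    response : (n,) array
    terms : list of str, optional
        Column names; defaults to ``x0..x{p-1}``.
    alpha : float
        Confidence level complement for the per-term intervals (default 95% CIs).

    Raises
    ------
    ModelError
        If ``n <= p`` or the design is rank deficient (the offending
        columns are named in the message).
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float).ravel()
    if X.ndim != 2:
        raise ModelError("design must be a 2-D matrix")
    n, p = X.shape
    if terms is None:
        terms = [f"x{j}" for j in range(p)]
    if len(terms) != p:
        raise ModelError(f"{len(terms)} term names for {p} columns")
    if y.shape[0] != n:
        raise ModelError("design and response have different lengths")
    if n <= p:
        raise ModelError(f"n={n} observations cannot identify p={p} parameters plus error")

    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = np.finfo(float).eps * max(n, p) * (diag.max() if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    if rank < p:
        bad = _collinear_columns(X, terms, rank)
        raise ModelError(f"rank-deficient design: collinear columns {bad}")

    beta = scipy.linalg.solve_triangular(R, Q.T @ y)
    fitted = X @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    df = n - p
    sigma2 = rss / df

    # cov(beta) = sigma2 * (X'X)^{-1} = sigma2 * R^{-1} R^{-T}
    Rinv = scipy.linalg.solve_triangular(R, np.eye(p))
    se = np.sqrt(sigma2 * np.sum(Rinv * Rinv, axis=1))
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    tq = stats.t.ppf(1.0 - alpha / 2.0, df)
    ci_lo = beta - tq * se
    ci_hi = beta + tq * se

    has_intercept = bool(np.any(np.ptp(X, axis=0) == 0.0))
    tss = float(np.sum((y - y.mean()) ** 2)) if has_intercept else float(y @ y)
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss == 0 else 0.0)

    return ModelFit(
        terms=list(terms),
        coefficients=beta,
        standard_errors=se,
        t_statistics=tvals,
        p_values=pvals,
        ci_lower=ci_lo,
        ci_upper=ci_hi,
        residuals=resid,
        sigma2=sigma2,
        r_squared=float(r2),
        n_obs=n,
        n_params=p,
        alpha=alpha,
    )


def build_design(data: pd.DataFrame, columns: list[str]) -> tuple[np.ndarray, np.ndarray | None, list[str]]:
    """Assemble an intercept-plus-columns design matrix from a data frame.

    Returns ``(X, None, names)`` where ``names = ["intercept", *columns]``.
    """
    X = np.column_stack(
        [np.ones(len(data))] + [data[c].to_numpy(dtype=float) for c in columns]
    )
    return X, None, ["intercept", *columns]
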
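"""Sequential-ignorability sensitivity analysis for linear mediation models.

Sequential ignorability (SI) requires, beyond exposure ignorability, that
the mediator be as-if randomised given exposure and covariates. An
unobserved mediator-outcome confounder violates this and shows up as a
correlation ``rho`` between the mediator-model error and the outcome-model
error. In the linear structural equation model the mediated effect as a
function of that correlation has the closed form

    ACME(rho) = a1 * (s1/s2) * (rho_t - rho * sqrt((1 - rho_t^2) / (1 - rho^2)))

where ``a1`` is the exposure slope of the mediator model, ``s2`` its
residual SD, ``s1`` the residual SD of the *total-effect* outcome model
(outcome on exposure and covariates, without the mediator), and ``rho_t``
the sample correlation of those two models' residuals. At ``rho = 0`` this
reproduces the product-of-coefficients estimate a1*b1 exactly (when the two
auxiliary fits share a design, as they do here).

The correlation ``rho*`` at which the effect crosses zero is the robustness
summary; it is reported along with two variance reparameterisations:
``rho*^2`` (the product of proportions of *unexplained* variance an
unobserved confounder must claim in the two models to nullify the effect)
and ``rho*^2 * (1 - R2_M) * (1 - R2_Y)`` (the same on the *original*
variance scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .ols import ModelFit, fit_ols
from .mediation import PathwaySpec, _complete_cases, _pathway_designs


@dataclass
class SensitivityResult:
    """ACME-versus-rho curve and its robustness summaries.

    ``rho_star`` (and the two R²-product measures derived from it) is None
    when the curve has no sign change on the grid.
    """

    rho_grid: np.ndarray
    acme_at_rho: np.ndarray
    rho_star: float | None
    r2_product_unexplained: float | None
    r2_product_original: float | None
    rho_tilde: float
    acme_at_zero: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"rho": self.rho_grid, "acme": self.acme_at_rho})


def default_rho_grid() -> np.ndarray:
    """rho from -0.9 to 0.9 in steps of 0.01."""
    return np.round(np.arange(-90, 91) / 100.0, 2)


def _acme_fn(a1: float, s1: float, s2: float, rho_tilde: float):
    scale = a1 * s1 / s2
    root = np.sqrt(1.0 - rho_tilde ** 2)

    def acme(rho):
        rho = np.asarray(rho, dtype=float)
        return scale * (rho_tilde - rho * root / np.sqrt(1.0 - rho ** 2))

    return acme


def acme_curve(mediator_fit: ModelFit, total_effect_fit: ModelFit, exposure: str,
               rho_grid: np.ndarray | None = None,
               outcome_fit: ModelFit | None = None) -> SensitivityResult:
    """Evaluate the mediated effect over a grid of error correlations.

    Parameters
    ----------
    mediator_fit : ModelFit
        Mediator on exposure + covariates.
    total_effect_fit : ModelFit
        Outcome on exposure + covariates (no mediator) — the auxiliary
        total-effect equation, fit on the same rows.
    exposure : str
        Term name of the exposure in ``mediator_fit``.
    rho_grid : array, optional
        Correlations in (-1, 1); defaults to -0.9..0.9 by 0.01.
    outcome_fit : ModelFit, optional
        Full outcome model (with mediator); supplies R²_Y for the
        original-variance product. Without it that measure is None.

    ``rho*`` is found by bracketing a sign change of the curve and bisecting
    to 1e-10; if the curve never changes sign on the grid, ``rho_star`` is
    reported absent rather than extrapolated.
    """
    if rho_grid is None:
        rho_grid = default_rho_grid()
    rho_grid = np.asarray(rho_grid, dtype=float)
    if np.any(np.abs(rho_grid) >= 1.0):
        raise ValueError("rho grid must lie strictly inside (-1, 1)")
    if mediator_fit.residuals.shape != total_effect_fit.residuals.shape:
        raise ValueError("mediator and total-effect fits must share the same rows")

    a1 = mediator_fit.coef(exposure)
    s2 = mediator_fit.residual_sd
    s1 = total_effect_fit.residual_sd
    rho_tilde = float(np.corrcoef(total_effect_fit.residuals, mediator_fit.residuals)[0, 1])
    acme = _acme_fn(a1, s1, s2, rho_tilde)
    values = acme(rho_grid)

    rho_star = None
    signs = np.sign(values)
    crossings = np.flatnonzero(np.diff(signs) != 0)
    if np.any(signs == 0.0):
        rho_star = float(rho_grid[np.flatnonzero(signs == 0.0)[0]])
    elif crossings.size:
        j = int(crossings[0])
        rho_star = float(optimize.bisect(acme, rho_grid[j], rho_grid[j + 1], xtol=1e-10))

    r2_unexp = r2_orig = None
    if rho_star is not None:
        r2_unexp = rho_star ** 2
        if outcome_fit is not None:
            r2_unexp, r2_orig = r2_measures(rho_star, mediator_fit, outcome_fit)
    return SensitivityResult(
        rho_grid=rho_grid, acme_at_rho=values, rho_star=rho_star,
        r2_product_unexplained=r2_unexp, r2_product_original=r2_orig,
        rho_tilde=rho_tilde, acme_at_zero=float(acme(0.0)),
    )


def r2_measures(rho_star: float, mediator_fit: ModelFit, outcome_fit: ModelFit) -> tuple:
    """Variance-proportion summaries of the nullifying correlation.

    Returns ``(rho*^2, rho*^2 * (1 - R2_M) * (1 - R2_Y))`` — the products of
    the proportions of unexplained and of original variance, respectively,
    that an unobserved confounder would have to explain in the mediator and
    outcome models to drive the mediated effect to zero.
    """
    if rho_star is None:
        return None, None
    if not abs(rho_star) < 1.0:
        raise ValueError(f"|rho*| must be < 1, got {rho_star}")
    unexplained = rho_star ** 2
    original = unexplained * (1.0 - mediator_fit.r_squared) * (1.0 - outcome_fit.r_squared)
    return unexplained, original


def sensitivity_analysis(cohort: pd.DataFrame, spec: PathwaySpec,
                         rho_grid: np.ndarray | None = None,
                         alpha: float = 0.05) -> SensitivityResult:
    """Fit the required models on a cohort and run :func:`acme_curve`.

    Fits the mediator model, the full outcome model, and the auxiliary
    total-effect model (outcome on exposure + covariates, without the
    mediator) on the pathway's complete cases.
    """
    data, _ = _complete_cases(cohort, spec)
    Xm, m, m_terms, Xy, y, y_terms = _pathway_designs(data, spec)
    mediator_fit = fit_ols(Xm, m, m_terms, alpha=alpha)
    outcome_fit = fit_ols(Xy, y, y_terms, alpha=alpha)
    # total-effect model shares the mediator model's design, with y as response
    total_fit = fit_ols(Xm, y, ["intercept", spec.exposure, *spec.covariates], alpha=alpha)
    return acme_curve(mediator_fit, total_fit, spec.exposure,
                      rho_grid=rho_grid, outcome_fit=outcome_fit)
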
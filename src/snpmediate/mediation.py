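"""Product-of-coefficients mediation analysis with bias-corrected bootstrap
inference.

One pathway is exposure (additive SNP code) -> mediator -> outcome. Two
covariate-adjusted linear models are fit:

    mediator ~ exposure + covariates                  (exposure slope: a1)
    outcome  ~ mediator + exposure + covariates       (mediator slope: b1,
                                                       exposure slope: c')

The indirect (mediated) effect is the product a1*b1; the direct effect is
c'; the total effect is their sum. In these no-interaction linear models the
decomposition total = indirect + direct holds exactly. Inference on the
indirect effect uses nonparametric case resampling of whole subject rows —
which preserves the mediator-outcome dependence and keeps the decomposition
identity inside every replicate — with bias-corrected (BC) percentile
intervals. BC, not BCa: no acceleration constant is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .ols import ModelError, ModelFit, fit_ols

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age", "gender", "bmi", "tg")


@dataclass(frozen=True)
class PathwaySpec:
    """Names the columns of one mediation pathway."""

    exposure: str
    mediator: str
    outcome: str
    covariates: tuple = DEFAULT_COVARIATES

    def __post_init__(self):
        object.__setattr__(self, "covariates", tuple(self.covariates))
        names = [self.exposure, self.mediator, self.outcome, *self.covariates]
        if len(set(names)) != len(names):
            raise ValueError(f"pathway columns must be distinct, got {names}")

    @property
    def columns(self) -> list[str]:
        return [self.exposure, self.mediator, self.outcome, *self.covariates]

    def validate(self, cohort: pd.DataFrame) -> None:
        missing = [c for c in self.columns if c not in cohort.columns]
        if missing:
            raise ValueError(f"cohort is missing pathway columns {missing}")


@dataclass
class MediationEstimate:
    """Point decomposition of one pathway: a1, b1, c', and derived effects."""

    spec: PathwaySpec
    a1: float
    b1: float
    c_prime: float
    indirect: float
    total: float
    mediator_fit: ModelFit
    outcome_fit: ModelFit
    n_obs: int
    n_dropped: int

    @property
    def direct(self) -> float:
        return self.c_prime

    @property
    def percent_mediated(self) -> float | None:
        """Point indirect/total share, None when the total effect is ~0."""
        if abs(self.total) < 1e-12:
            return None
        return self.indirect / self.total


@dataclass
class BootstrapResult:
    """Case-resampling bootstrap summary for indirect and direct effects.

    ``bias_*`` is bootstrap mean minus point estimate; ``ci_*`` are
    bias-corrected percentile intervals; ``z_statistics``/``p_values`` are
    the normal-approximation summaries (point estimate over bootstrap SD)
    reported alongside — not instead of — the BC intervals.
    """

    n_reps: int
    alpha: float
    seed: int | None
    point_indirect: float
    point_direct: float
    replicate_indirect: np.ndarray
    replicate_direct: np.ndarray
    bias_indirect: float
    bias_direct: float
    ci_indirect: tuple
    ci_direct: tuple
    se_indirect: float
    se_direct: float
    z_statistics: dict = field(default_factory=dict)
    p_values: dict = field(default_factory=dict)
    n_redrawn: int = 0


def indirect_effect(a1: float, b1: float) -> float:
    """Product-of-coefficients indirect effect a1*b1."""
    if not (np.isfinite(a1) and np.isfinite(b1)):
        raise ValueError(f"path coefficients must be finite, got a1={a1}, b1={b1}")
    return a1 * b1


def _complete_cases(cohort: pd.DataFrame, spec: PathwaySpec) -> tuple[pd.DataFrame, int]:
    spec.validate(cohort)
    sub = cohort[spec.columns]
    kept = sub.dropna()
    n_dropped = len(sub) - len(kept)
    if n_dropped:
        logger.info("dropped %d incomplete rows of %d", n_dropped, len(sub))
    return kept, n_dropped


def _pathway_designs(data: pd.DataFrame, spec: PathwaySpec):
    cov = [data[c].to_numpy(dtype=float) for c in spec.covariates]
    ones = np.ones(len(data))
    x = data[spec.exposure].to_numpy(dtype=float)
    m = data[spec.mediator].to_numpy(dtype=float)
    y = data[spec.outcome].to_numpy(dtype=float)
    Xm = np.column_stack([ones, x, *cov])
    m_terms = ["intercept", spec.exposure, *spec.covariates]
    Xy = np.column_stack([ones, m, x, *cov])
    y_terms = ["intercept", spec.mediator, spec.exposure, *spec.covariates]
    return Xm, m, m_terms, Xy, y, y_terms


def fit_pathway(cohort: pd.DataFrame, spec: PathwaySpec, alpha: float = 0.05) -> MediationEstimate:
    """Fit both path models and decompose the exposure effect.

    Complete-case analysis: rows missing any of the pathway's variables are
    dropped (count logged and recorded on the estimate).
    """
    data, n_dropped = _complete_cases(cohort, spec)
    if data[spec.exposure].nunique() < 2:
        raise ModelError(f"exposure {spec.exposure!r} is constant in the analysis rows")
    if data[spec.mediator].nunique() < 2:
        raise ModelError(f"mediator {spec.mediator!r} is constant in the analysis rows")
    Xm, m, m_terms, Xy, y, y_terms = _pathway_designs(data, spec)
    mediator_fit = fit_ols(Xm, m, m_terms, alpha=alpha)
    outcome_fit = fit_ols(Xy, y, y_terms, alpha=alpha)
    a1 = mediator_fit.coef(spec.exposure)
    b1 = outcome_fit.coef(spec.mediator)
    c_prime = outcome_fit.coef(spec.exposure)
    ind = indirect_effect(a1, b1)
    return MediationEstimate(
        spec=spec, a1=a1, b1=b1, c_prime=c_prime,
        indirect=ind, total=ind + c_prime,
        mediator_fit=mediator_fit, outcome_fit=outcome_fit,
        n_obs=len(data), n_dropped=n_dropped,
    )


def bias_corrected_interval(replicates: np.ndarray, point: float, alpha: float = 0.05) -> tuple:
    """Bias-corrected percentile interval from a bootstrap distribution.

    z0 is the normal quantile of the proportion of replicates below the
    point estimate, with half weight on exact ties; it is clamped to
    ±Phi^{-1}(1 - 1/B) so degenerate resamples cannot push it to infinity.
    The interval endpoints are the empirical quantiles at
    Phi(2*z0 ∓ z_{1-alpha/2}).
    """
    reps = np.asarray(replicates, dtype=float)
    B = reps.size
    prop = (np.sum(reps < point) + 0.5 * np.sum(reps == point)) / B
    zmax = ndtri(1.0 - 1.0 / B)
    z0 = float(np.clip(ndtri(prop) if 0.0 < prop < 1.0 else np.sign(prop - 0.5) * np.inf,
                       -zmax, zmax))
    za = ndtri(1.0 - alpha / 2.0)
    lo_q = ndtr(2.0 * z0 - za)
    hi_q = ndtr(2.0 * z0 + za)
    lo, hi = np.quantile(reps, [lo_q, hi_q])
    return float(lo), float(hi)


def _batched_coefs(X: np.ndarray, y: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-replicate OLS coefficients for row resamples ``idx`` (B, n).

    Solves the normal equations batch-wise; on a singular batch, falls back
    to per-replicate least squares with an explicit rank check. Returns the
    coefficient array (B, p) and a validity mask.
    """
    Xb = X[idx]
    yb = y[idx]
    XtX = np.einsum("bni,bnj->bij", Xb, Xb, optimize=True)
    Xty = np.einsum("bni,bn->bi", Xb, yb, optimize=True)
    B, p = idx.shape[0], X.shape[1]
    try:
        beta = np.linalg.solve(XtX, Xty[..., None])[..., 0]
        return beta, np.isfinite(beta).all(axis=1)
    except np.linalg.LinAlgError:
        beta = np.full((B, p), np.nan)
        valid = np.zeros(B, dtype=bool)
        for b in range(B):
            sol, _, rank, _ = np.linalg.lstsq(Xb[b], yb[b], rcond=None)
            if rank == p:
                beta[b] = sol
                valid[b] = True
        return beta, valid


def bc_bootstrap(cohort: pd.DataFrame, spec: PathwaySpec, n_reps: int = 1000,
                 alpha: float = 0.05, seed=None, chunk_size: int = 256,
                 max_failure_frac: float = 0.01) -> BootstrapResult:
    """Bias-corrected bootstrap for the indirect and direct effects.

    Whole subject rows are resampled with replacement; both path models are
    refit per replicate and the indirect (a1*b1) and direct (c') effects
    recorded. Replicates with a rank-deficient design are redrawn (logged);
    if more than ``max_failure_frac`` of draws fail the run errors out.
    """
    if n_reps < 100:
        raise ValueError(f"n_reps must be >= 100, got {n_reps}")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")

    est = fit_pathway(cohort, spec, alpha=alpha)
    data, _ = _complete_cases(cohort, spec)
    Xm, m, m_terms, Xy, y, y_terms = _pathway_designs(data, spec)
    ia = m_terms.index(spec.exposure)
    ib = y_terms.index(spec.mediator)
    ic = y_terms.index(spec.exposure)
    n = len(data)

    rng = np.random.default_rng(seed)
    rep_ind = np.empty(n_reps)
    rep_dir = np.empty(n_reps)
    n_failures = 0
    done = 0
    while done < n_reps:
        B = min(chunk_size, n_reps - done)
        idx = rng.integers(0, n, size=(B, n))
        beta_m, ok_m = _batched_coefs(Xm, m, idx)
        beta_y, ok_y = _batched_coefs(Xy, y, idx)
        ok = ok_m & ok_y
        bad = int(B - ok.sum())
        attempts = 0
        while bad and attempts < 100:
            n_failures += bad
            logger.info("redrawing %d rank-deficient bootstrap replicates", bad)
            if n_failures > max_failure_frac * n_reps:
                raise RuntimeError(
                    f"{n_failures} bootstrap replicates failed (> {max_failure_frac:.0%} of {n_reps})")
            ridx = rng.integers(0, n, size=(bad, n))
            bm, om = _batched_coefs(Xm, m, ridx)
            by, oy = _batched_coefs(Xy, y, ridx)
            where = np.flatnonzero(~ok)
            beta_m[where], beta_y[where] = bm, by
            ok[where] = om & oy
            bad = int(B - ok.sum())
            attempts += 1
        if bad:
            raise RuntimeError("could not draw full-rank bootstrap replicates")
        rep_ind[done:done + B] = beta_m[:, ia] * beta_y[:, ib]
        rep_dir[done:done + B] = beta_y[:, ic]
        done += B

    ci_ind = bias_corrected_interval(rep_ind, est.indirect, alpha)
    ci_dir = bias_corrected_interval(rep_dir, est.c_prime, alpha)
    se_ind = float(np.std(rep_ind, ddof=1))
    se_dir = float(np.std(rep_dir, ddof=1))
    z_ind = est.indirect / se_ind if se_ind > 0 else np.nan
    z_dir = est.c_prime / se_dir if se_dir > 0 else np.nan
    return BootstrapResult(
        n_reps=n_reps, alpha=alpha,
        seed=seed if isinstance(seed, (int, type(None))) else None,
        point_indirect=est.indirect, point_direct=est.c_prime,
        replicate_indirect=rep_ind, replicate_direct=rep_dir,
        bias_indirect=float(rep_ind.mean() - est.indirect),
        bias_direct=float(rep_dir.mean() - est.c_prime),
        ci_indirect=ci_ind, ci_direct=ci_dir,
        se_indirect=se_ind, se_direct=se_dir,
        z_statistics={"indirect": float(z_ind), "direct": float(z_dir)},
        p_values={"indirect": float(2.0 * ndtr(-abs(z_ind))),
                  "direct": float(2.0 * ndtr(-abs(z_dir)))},
        n_redrawn=n_failures,
    )


@dataclass
class PercentMediated:
    """Share of the exposure's total effect carried by the mediated path.

    ``definition`` is either ``"ratio"`` (indirect/total — sign-preserving,
    can exceed [0, 1] when direct and indirect effects oppose) or
    ``"absolute"`` (|indirect| / (|indirect| + |direct|), always in [0, 1]).
    """

    definition: str
    value: float | None
    ci_lower: float | None = None
    ci_upper: float | None = None
    undefined: bool = False

    @property
    def percent(self) -> float | None:
        return None if self.value is None else 100.0 * self.value


def percent_mediated(estimate: MediationEstimate, bootstrap: BootstrapResult | None = None,
                     definition: str = "ratio", tol: float = 1e-12) -> PercentMediated:
    """Percent-mediated decomposition under a labelled definition.

    With a bootstrap result, the definition is applied per replicate and a
    bias-corrected interval is attached. A total effect within ``tol`` of
    zero makes the ratio definition undefined (flagged, no division).
    """
    if definition not in ("ratio", "absolute"):
        raise ValueError(f"definition must be 'ratio' or 'absolute', got {definition!r}")

    def compute(ind, dire):
        if definition == "ratio":
            total = ind + dire
            with np.errstate(divide="ignore", invalid="ignore"):
                return np.where(np.abs(total) < tol, np.nan, ind / total)
        denom = np.abs(ind) + np.abs(dire)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(denom < tol, np.nan, np.abs(ind) / denom)

    point = compute(np.float64(estimate.indirect), np.float64(estimate.c_prime))
    if np.isnan(point):
        return PercentMediated(definition=definition, value=None, undefined=True)
    result = PercentMediated(definition=definition, value=float(point))
    if bootstrap is not None:
        reps = compute(bootstrap.replicate_indirect, bootstrap.replicate_direct)
        reps = reps[np.isfinite(reps)]
        if reps.size >= 100:
            lo, hi = bias_corrected_interval(reps, float(point), bootstrap.alpha)
            result.ci_lower, result.ci_upper = lo, hi
    return result


def run_bidirectional(cohort: pd.DataFrame, spec1: PathwaySpec, spec2: PathwaySpec,
                      n_reps: int = 1000, alpha: float = 0.05, seed: int | None = None,
                      rho_grid: np.ndarray | None = None) -> dict:
    """Run both causal pathways on one cohort: point decomposition, BC
    bootstrap, percent mediated under both definitions, and the
    sequential-ignorability sensitivity analysis.

    The two pathways swap mediator/outcome roles (each with its own
    exposure); bootstrap streams are derived from ``seed`` independently per
    pathway. Returns a nested report dict with provenance (n, seed, n_reps).
    """
    from .sensitivity import sensitivity_analysis

    if not (spec1.mediator == spec2.outcome and spec1.outcome == spec2.mediator):
        raise ValueError("the two pathways must swap mediator and outcome roles")

    children = np.random.SeedSequence(seed).spawn(2)
    report = {"n": int(len(cohort)), "seed": seed, "n_reps": n_reps, "alpha": alpha,
              "pathways": {}}
    for label, spec, child in (("pathway1", spec1, children[0]),
                               ("pathway2", spec2, children[1])):
        est = fit_pathway(cohort, spec, alpha=alpha)
        boot = bc_bootstrap(cohort, spec, n_reps=n_reps, alpha=alpha, seed=child)
        sens = sensitivity_analysis(cohort, spec, rho_grid=rho_grid, alpha=alpha)
        report["pathways"][label] = {
            "spec": {"exposure": spec.exposure, "mediator": spec.mediator,
                     "outcome": spec.outcome, "covariates": list(spec.covariates)},
            "estimate": est,
            "bootstrap": boot,
            "percent_mediated": {
                "ratio": percent_mediated(est, boot, "ratio"),
                "absolute": percent_mediated(est, boot, "absolute"),
            },
            "sensitivity": sens,
        }
    return report
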
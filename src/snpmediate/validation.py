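"""Simulation studies of the inference machinery: interval coverage and
type-I error of the bias-corrected bootstrap for the indirect effect.

These run the full generate -> fit -> bootstrap loop many times against the
generator's known truth, so they exercise every layer the real analysis
uses. Cohort and bootstrap seeds are derived from one master seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .mediation import PathwaySpec, bc_bootstrap
from .simulate import SimulationParams, default_params, simulate_cohort


def _spec_for(params: SimulationParams) -> PathwaySpec:
    return PathwaySpec(exposure=params.exposure_snp, mediator=params.mediator_column,
                       outcome=params.outcome_column)


def coverage_simulation(n_repeats: int = 500, n_subjects: int = 500, n_boot: int = 300,
                        alpha: float = 0.05, seed: int | None = None,
                        params: SimulationParams | None = None) -> dict:
    """Empirical coverage of the BC bootstrap CI for the indirect effect.

    Simulates ``n_repeats`` cohorts (default generative model, no unobserved
    confounding), bootstraps each, and reports the fraction of runs whose
    interval contains the generative a1*b1.
    """
    if params is None:
        params = default_params(1, n_subjects=n_subjects)
    spec = _spec_for(params)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=(n_repeats, 2))
    covered = 0
    for k in range(n_repeats):
        cohort, truth = simulate_cohort(
            dataclasses.replace(params, seed=int(seeds[k, 0])))
        boot = bc_bootstrap(cohort, spec, n_reps=n_boot, alpha=alpha,
                            seed=int(seeds[k, 1]))
        lo, hi = boot.ci_indirect
        covered += lo <= truth["true_indirect"] <= hi
    return {"coverage": covered / n_repeats, "coverage_percent": 100.0 * covered / n_repeats,
            "n_repeats": n_repeats, "n_subjects": n_subjects, "n_boot": n_boot,
            "alpha": alpha, "true_indirect": params.mediator_coefs["genotype"]
            * params.outcome_coefs["mediator"]}


def type_one_error_simulation(n_repeats: int = 500, n_subjects: int = 500,
                              n_boot: int = 300, alpha: float = 0.05,
                              seed: int | None = None) -> dict:
    """Rejection rate of 'BC CI excludes 0' when the a1 path is null.

    The generator's exposure -> mediator coefficient is set to zero, so the
    true indirect effect is zero and the rejection rate estimates type-I
    error (nominal ``alpha``).
    """
    params = default_params(1, n_subjects=n_subjects,
                            mediator_coefs={"genotype": 0.0})
    spec = _spec_for(params)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=(n_repeats, 2))
    rejected = 0
    for k in range(n_repeats):
        cohort, _ = simulate_cohort(dataclasses.replace(params, seed=int(seeds[k, 0])))
        boot = bc_bootstrap(cohort, spec, n_reps=n_boot, alpha=alpha,
                            seed=int(seeds[k, 1]))
        lo, hi = boot.ci_indirect
        rejected += not (lo <= 0.0 <= hi)
    return {"rejection_rate": rejected / n_repeats, "n_repeats": n_repeats,
            "n_subjects": n_subjects, "n_boot": n_boot, "alpha": alpha}
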
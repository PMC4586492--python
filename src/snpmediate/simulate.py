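"""Synthetic cohort generator for the mediation pipeline.

Builds per-subject tables with the statistical structure the analysis
assumes: two biallelic SNPs in Hardy-Weinberg proportions, demographic and
lipid covariates, and a mediator/outcome pair generated from linear
structural equations with Gaussian errors. An optional shared standard-normal
confounder loads onto both error terms, inducing the correlated-errors
violation of sequential ignorability that the sensitivity module probes.

Every cohort comes with a *truth record* — the generative coefficients,
residual scales, and implied error correlation — so parameter-recovery and
coverage tests never re-derive ground truth from code.

Default parameters emulate a Thai occupational cohort (n = 2288): age
39.9 ± 6.6 y, BMI 23.9 ± 3.8 kg/m², 74.3% male, triglyceride
129.5 ± 89.9 mg/dL, mean 25(OH)D 25.1 ng/mL and uric acid 5.6 mg/dL.
Gender is coded 1 = female, 0 = male (configurable convention; the default
gender coefficient then reproduces lower vitamin D in women). Minor-allele
frequencies default to 0.30 — a plausible value for the studied population,
not a reported one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

COHORT_COLUMNS = ["id", "geno_snp1", "geno_snp2", "age", "gender", "bmi", "tg", "vitd", "ua"]

MEDIATOR_COEF_KEYS = ("intercept", "genotype", "age", "gender", "bmi", "tg")
OUTCOME_COEF_KEYS = ("intercept", "mediator", "genotype", "age", "gender", "bmi", "tg")


class ParameterError(ValueError):
    """Raised for invalid simulation parameters."""


@dataclass
class SimulationParams:
    """Generative parameters for one synthetic cohort.

    ``mediator_coefs`` maps predictor -> coefficient for the mediator
    equation (keys: intercept, genotype, age, gender, bmi, tg);
    ``outcome_coefs`` adds a ``mediator`` key. ``exposure_snp`` names which
    simulated SNP drives the pathway; ``mediator_column``/``outcome_column``
    say which of the vitd/ua columns each equation fills.

    ``confounder_loading_m`` / ``confounder_loading_y`` are loadings of a
    shared standard-normal unobserved confounder on the (unit-scaled)
    mediator and outcome errors; (0, 0) means sequential ignorability holds.
    The implied error correlation is
    ``l_m * l_y / sqrt((1 + l_m^2) * (1 + l_y^2))``.
    """

    n_subjects: int = 2288
    maf_snp1: float = 0.30
    maf_snp2: float = 0.30
    age_mean: float = 39.9
    age_sd: float = 6.6
    prop_male: float = 0.743
    bmi_mean: float = 23.9
    bmi_sd: float = 3.8
    tg_mean: float = 129.5
    tg_sd: float = 89.9
    mediator_coefs: dict = field(default_factory=dict)
    outcome_coefs: dict = field(default_factory=dict)
    sigma_mediator: float = 6.0
    sigma_outcome: float = 1.2
    confounder_loading_m: float = 0.0
    confounder_loading_y: float = 0.0
    exposure_snp: str = "geno_snp1"
    mediator_column: str = "vitd"
    outcome_column: str = "ua"
    seed: int | None = None

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ParameterError(f"n_subjects must be >= 1, got {self.n_subjects}")
        for name in ("maf_snp1", "maf_snp2"):
            maf = getattr(self, name)
            if not (0.0 < maf <= 0.5):
                raise ParameterError(f"{name} must be in (0, 0.5], got {maf}")
        for name in ("age_sd", "bmi_sd", "tg_sd", "sigma_mediator", "sigma_outcome"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0, got {getattr(self, name)}")
        if not (0.0 <= self.prop_male <= 1.0):
            raise ParameterError(f"prop_male must be in [0, 1], got {self.prop_male}")
        if self.exposure_snp not in ("geno_snp1", "geno_snp2"):
            raise ParameterError(f"exposure_snp must be geno_snp1 or geno_snp2, got {self.exposure_snp!r}")
        if {self.mediator_column, self.outcome_column} != {"vitd", "ua"}:
            raise ParameterError("mediator_column and outcome_column must be 'vitd' and 'ua' in some order")
        missing = [k for k in MEDIATOR_COEF_KEYS if k not in self.mediator_coefs]
        if missing:
            raise ParameterError(f"mediator_coefs missing keys {missing}")
        missing = [k for k in OUTCOME_COEF_KEYS if k not in self.outcome_coefs]
        if missing:
            raise ParameterError(f"outcome_coefs missing keys {missing}")

    @property
    def implied_error_correlation(self) -> float:
        lm, ly = self.confounder_loading_m, self.confounder_loading_y
        return lm * ly / np.sqrt((1.0 + lm * lm) * (1.0 + ly * ly))


def _truncated_tg_mean(mean: float, sd: float) -> float:
    a = (0.0 - mean) / sd
    return float(stats.truncnorm.mean(a, np.inf, loc=mean, scale=sd))


def default_params(pathway: int = 1, **overrides) -> SimulationParams:
    """Default generative parameters for one of the two causal pathways.

    Pathway 1: SNP1 -> 25(OH)D -> uric acid, slope defaults from the
    vitamin-D-mediator orientation. Pathway 2: SNP2 -> uric acid -> 25(OH)D.
    Intercepts are calibrated so the population means of mediator and
    outcome match the target marginal means (25.1 ng/mL for 25(OH)D,
    5.6 mg/dL for uric acid) given the covariate distributions.
    """
    if pathway == 1:
        med_col, out_col, exposure = "vitd", "ua", "geno_snp1"
        med_target, out_target = 25.1, 5.6
        med = {"genotype": -2.4306, "age": 0.1226, "gender": -4.4174,
               "bmi": -0.1105, "tg": 0.0068}
        out = {"mediator": 0.0097, "genotype": 0.0765, "age": -0.0028,
               "gender": -1.6602, "bmi": 0.0843, "tg": 0.0024}
        sig_m, sig_y = 6.0, 1.2
    elif pathway == 2:
        med_col, out_col, exposure = "ua", "vitd", "geno_snp2"
        med_target, out_target = 5.6, 25.1
        med = {"genotype": 0.2726, "age": -0.0015, "gender": -1.6895,
               "bmi": 0.0824, "tg": 0.0025}
        out = {"mediator": 0.2956, "genotype": -0.2471, "age": 0.1177,
               "gender": -3.8216, "bmi": -0.1258, "tg": 0.0062}
        sig_m, sig_y = 1.2, 6.0
    else:
        raise ParameterError(f"pathway must be 1 or 2, got {pathway}")

    base = dict(sigma_mediator=sig_m, sigma_outcome=sig_y,
                exposure_snp=exposure, mediator_column=med_col, outcome_column=out_col)
    base.update({k: v for k, v in overrides.items()
                 if k not in ("mediator_coefs", "outcome_coefs")})
    probe = SimulationParams(mediator_coefs=dict(med, intercept=0.0),
                             outcome_coefs=dict(out, intercept=0.0), **base)

    maf = probe.maf_snp1 if exposure == "geno_snp1" else probe.maf_snp2
    means = {
        "genotype": 2.0 * maf,
        "age": probe.age_mean,
        "gender": 1.0 - probe.prop_male,  # 1 = female
        "bmi": probe.bmi_mean,
        "tg": _truncated_tg_mean(probe.tg_mean, probe.tg_sd),
    }
    med["intercept"] = med_target - sum(med[k] * means[k] for k in means)
    means["mediator"] = med_target
    out["intercept"] = out_target - sum(out[k] * means[k] for k in means)

    if "mediator_coefs" in overrides:
        med.update(overrides["mediator_coefs"])
    if "outcome_coefs" in overrides:
        out.update(overrides["outcome_coefs"])
    return SimulationParams(mediator_coefs=med, outcome_coefs=out, **base)


def simulate_genotypes(maf: float, n: int, seed=None) -> np.ndarray:
    """Draw additive genotype codes under Hardy-Weinberg proportions.

    Codes 0/1/2 are drawn with probabilities ``(1-maf)^2, 2*maf*(1-maf),
    maf^2``. ``seed`` may be an integer or a ``numpy.random.Generator``.
    """
    if not (0.0 < maf <= 0.5):
        raise ParameterError(f"maf must be in (0, 0.5], got {maf}")
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf ** 2])
    return rng.choice(3, size=n, p=p)


def simulate_cohort(params: SimulationParams) -> tuple[pd.DataFrame, dict]:
    """Generate one cohort table plus its generative truth record.

    The mediator is its linear predictor plus ``sigma_mediator * (eps +
    l_m * U)``; the outcome is its linear predictor (which includes the
    realised mediator) plus ``sigma_outcome * (eps' + l_y * U)``, with U a
    shared standard normal. Loadings (0, 0) give independent errors.
    """
    n = params.n_subjects
    rng = np.random.default_rng(params.seed)

    geno1 = simulate_genotypes(params.maf_snp1, n, rng)
    geno2 = simulate_genotypes(params.maf_snp2, n, rng)
    age = rng.normal(params.age_mean, params.age_sd, n)
    gender = (rng.random(n) >= params.prop_male).astype(np.int64)  # 1 = female
    bmi = rng.normal(params.bmi_mean, params.bmi_sd, n)
    a = (0.0 - params.tg_mean) / params.tg_sd
    tg = stats.truncnorm.rvs(a, np.inf, loc=params.tg_mean, scale=params.tg_sd,
                             size=n, random_state=rng)

    exposure = geno1 if params.exposure_snp == "geno_snp1" else geno2
    u = rng.standard_normal(n)
    eps_m = rng.standard_normal(n)
    eps_y = rng.standard_normal(n)

    mc, oc = params.mediator_coefs, params.outcome_coefs
    mediator = (
        mc["intercept"] + mc["genotype"] * exposure + mc["age"] * age
        + mc["gender"] * gender + mc["bmi"] * bmi + mc["tg"] * tg
        + params.sigma_mediator * (eps_m + params.confounder_loading_m * u)
    )
    outcome = (
        oc["intercept"] + oc["mediator"] * mediator + oc["genotype"] * exposure
        + oc["age"] * age + oc["gender"] * gender + oc["bmi"] * bmi + oc["tg"] * tg
        + params.sigma_outcome * (eps_y + params.confounder_loading_y * u)
    )

    width = max(4, len(str(n)))
    cohort = pd.DataFrame({
        "id": [f"S{i:0{width}d}" for i in range(1, n + 1)],
        "geno_snp1": geno1,
        "geno_snp2": geno2,
        "age": age,
        "gender": gender,
        "bmi": bmi,
        "tg": tg,
        params.mediator_column: mediator,
        params.outcome_column: outcome,
    })[COHORT_COLUMNS]

    a1 = mc["genotype"]
    b1 = oc["mediator"]
    truth = {
        "seed": params.seed,
        "n_subjects": n,
        "exposure_snp": params.exposure_snp,
        "mediator_column": params.mediator_column,
        "outcome_column": params.outcome_column,
        "gender_coding": "1=female",
        **{f"mediator_coef_{k}": v for k, v in mc.items()},
        **{f"outcome_coef_{k}": v for k, v in oc.items()},
        "sigma_mediator": params.sigma_mediator,
        "sigma_outcome": params.sigma_outcome,
        "confounder_loading_m": params.confounder_loading_m,
        "confounder_loading_y": params.confounder_loading_y,
        "implied_error_correlation": params.implied_error_correlation,
        "true_a1": a1,
        "true_b1": b1,
        "true_indirect": a1 * b1,
        "true_direct": oc["genotype"],
        "true_total": a1 * b1 + oc["genotype"],
    }
    return cohort, truth


def write_cohort(cohort: pd.DataFrame, truth: dict, out_dir, prefix: str = "cohort") -> dict:
    """Write the cohort CSV and its truth sidecar JSON; returns the paths.

    The CSV carries a ``# seed=<seed>`` comment line above the header so the
    seed travels with the table (readable with ``read_cohort`` or
    ``pandas.read_csv(..., comment='#')``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{prefix}.csv"
    truth_path = out_dir / f"{prefix}.truth.json"
    with open(csv_path, "w", newline="") as fh:
        fh.write(f"# seed={truth.get('seed')}\n")
        cohort.to_csv(fh, index=False)
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"cohort": str(csv_path), "truth": str(truth_path)}


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort` (or any CSV with the
    same header); ``#`` comment lines are ignored."""
    return pd.read_csv(path, comment="#")


def params_to_flat_dict(params: SimulationParams) -> dict:
    """Flatten parameters to scalar key-value pairs (for configs/reports)."""
    d = asdict(params)
    for group in ("mediator_coefs", "outcome_coefs"):
        coefs = d.pop(group)
        d.update({f"{group[:-1]}_{k}": v for k, v in coefs.items()})
    return d
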
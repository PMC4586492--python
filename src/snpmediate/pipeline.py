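"""End-to-end orchestration: configuration, cohort I/O, descriptives,
genotype QC, both mediation pathways, sensitivity, and report assembly.

The report layer only collects module outputs — every number in the bundle
is computed exactly once, in the module that owns it. Significance follows
the two-sided P < 0.05 convention with no multiple-testing correction
across the two pathways; the report says so explicitly. Numbers are stored
at full precision in the JSON report; the rendered tables round to 4
decimals.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genotype import encode_genotypes, snp_qc
from .mediation import PathwaySpec, run_bidirectional
from .simulate import (SimulationParams, default_params, read_cohort,
                       simulate_cohort, write_cohort)

CONTINUOUS_COLUMNS = ("age", "bmi", "tg", "vitd", "ua")
CATEGORICAL_COLUMNS = ("gender", "geno_snp1", "geno_snp2")

SIGNIFICANCE_NOTE = ("Two-sided P < 0.05 considered statistically significant; "
                     "no multiple-testing correction applied across pathways.")


class PipelineError(RuntimeError):
    """Stage-labelled orchestration failure."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """Configuration of one full run.

    Exactly one of ``cohort_path`` (an existing cohort CSV) or
    ``simulation`` (generator parameters) must be supplied.
    """

    cohort_path: str | None = None
    simulation: SimulationParams | None = None
    pathway1: PathwaySpec = dataclasses.field(
        default_factory=lambda: PathwaySpec("geno_snp1", "vitd", "ua"))
    pathway2: PathwaySpec = dataclasses.field(
        default_factory=lambda: PathwaySpec("geno_snp2", "ua", "vitd"))
    n_reps: int = 1000
    alpha: float = 0.05
    seed: int | None = None
    hwe_threshold: float = 0.05
    out_dir: str = "snpmediate_run"
    minor_allele_snp1: str | None = None
    minor_allele_snp2: str | None = None

    def __post_init__(self):
        if (self.cohort_path is None) == (self.simulation is None):
            raise ValueError("supply exactly one of cohort_path or simulation parameters")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        """Build a config from a flat key-value YAML file.

        Recognised keys: ``cohort`` (CSV path) or ``simulate`` (pathway 1 or
        2, triggers the generator; any ``SimulationParams`` field name may
        appear as a further key); ``pathway<k>_exposure/mediator/outcome``;
        ``covariates`` (comma-separated); ``n_reps``, ``alpha``, ``seed``,
        ``hwe_threshold``, ``out_dir``, ``minor_allele_snp1/2``.
        """
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        kwargs: dict = {}
        if "cohort" in raw:
            kwargs["cohort_path"] = str(raw.pop("cohort"))
        if "simulate" in raw:
            pathway = int(raw.pop("simulate"))
            # 'seed' belongs to the run config; run_all threads it into the generator
            sim_fields = {f.name for f in dataclasses.fields(SimulationParams)} - {"seed"}
            sim_kwargs = {k: raw.pop(k) for k in list(raw) if k in sim_fields}
            kwargs["simulation"] = default_params(pathway, **sim_kwargs)
        cov = tuple(str(raw.pop("covariates", "age,gender,bmi,tg")).split(","))
        for k in ("pathway1", "pathway2"):
            names = {f: raw.pop(f"{k}_{f}", None) for f in ("exposure", "mediator", "outcome")}
            if any(v is not None for v in names.values()):
                if any(v is None for v in names.values()):
                    raise ValueError(f"{k} needs exposure, mediator and outcome keys")
                kwargs[k] = PathwaySpec(covariates=cov, **names)
        for k in ("n_reps", "seed"):
            if k in raw:
                kwargs[k] = int(raw.pop(k))
        for k in ("alpha", "hwe_threshold"):
            if k in raw:
                kwargs[k] = float(raw.pop(k))
        for k in ("out_dir", "minor_allele_snp1", "minor_allele_snp2"):
            if k in raw:
                kwargs[k] = str(raw.pop(k))
        if raw:
            raise ValueError(f"unrecognised config keys: {sorted(raw)}")
        return cls(**kwargs)


def describe_cohort(cohort: pd.DataFrame) -> dict:
    """Mean/SD per continuous column and frequency/percent per categorical.

    SD is reported absent (None) for a single subject; a constant column
    with n > 1 reports SD = 0.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    n = len(cohort)
    cont = []
    for col in CONTINUOUS_COLUMNS:
        if col not in cohort.columns:
            continue
        vals = cohort[col].dropna()
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else None
        cont.append({"variable": col, "n": int(len(vals)),
                     "mean": float(vals.mean()), "sd": sd})
    cat = []
    for col in CATEGORICAL_COLUMNS:
        if col not in cohort.columns:
            continue
        counts = cohort[col].value_counts().sort_index()
        for level, count in counts.items():
            cat.append({"variable": col, "level": level, "count": int(count),
                        "percent": 100.0 * count / n})
    return {"n": n, "continuous": cont, "categorical": cat}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _estimate_block(est) -> dict:
    return {
        "a1": est.a1, "b1": est.b1, "c_prime": est.c_prime,
        "indirect": est.indirect, "direct": est.c_prime, "total": est.total,
        "percent_mediated_point": est.percent_mediated,
        "n_obs": est.n_obs, "n_dropped": est.n_dropped,
        "mediator_model": est.mediator_fit.to_frame().to_dict("records"),
        "outcome_model": est.outcome_fit.to_frame().to_dict("records"),
        "mediator_r_squared": est.mediator_fit.r_squared,
        "outcome_r_squared": est.outcome_fit.r_squared,
    }


def _bootstrap_block(boot) -> dict:
    return {
        "n_reps": boot.n_reps, "alpha": boot.alpha,
        "indirect": {"b": boot.point_indirect, "SE": boot.se_indirect,
                     "Z": boot.z_statistics["indirect"], "P": boot.p_values["indirect"],
                     "bias": boot.bias_indirect, "LL": boot.ci_indirect[0],
                     "UL": boot.ci_indirect[1],
                     "bootstrap_mean": float(np.mean(boot.replicate_indirect))},
        "direct": {"b": boot.point_direct, "SE": boot.se_direct,
                   "Z": boot.z_statistics["direct"], "P": boot.p_values["direct"],
                   "bias": boot.bias_direct, "LL": boot.ci_direct[0],
                   "UL": boot.ci_direct[1],
                   "bootstrap_mean": float(np.mean(boot.replicate_direct))},
        "n_redrawn": boot.n_redrawn,
    }


def _percent_block(pm) -> dict:
    return {"definition": pm.definition, "fraction": pm.value, "percent": pm.percent,
            "ci_lower": pm.ci_lower, "ci_upper": pm.ci_upper, "undefined": pm.undefined}


def _sensitivity_block(sens) -> dict:
    return {
        "rho_star": sens.rho_star,
        "r2_product_unexplained": sens.r2_product_unexplained,
        "r2_product_original": sens.r2_product_original,
        "residual_correlation": sens.rho_tilde,
        "acme_at_zero": sens.acme_at_zero,
        "note": "total-effect outcome model (without mediator) is auxiliary to this block",
    }


def _fmt_table(frame: pd.DataFrame, title: str) -> str:
    shown = frame.copy()
    for col in shown.columns:
        if pd.api.types.is_float_dtype(shown[col]):
            shown[col] = shown[col].map(lambda v: f"{v:.4f}")
    return f"== {title} ==\n{shown.to_string(index=False)}\n"


def render_tables(report: dict) -> str:
    """Human-readable tables in the b/SE/t/P/CI regression layout plus the
    effects decomposition in the b/SE/Z/P/Bias/CI layout."""
    parts = [f"snpmediate {report['version']}  n={report['n']}  seed={report['seed']}  "
             f"reps={report['n_reps']}", report["significance_note"], ""]
    desc = report["descriptives"]
    cont = pd.DataFrame(desc["continuous"])
    parts.append(_fmt_table(cont, "Descriptives (continuous)"))
    cat = pd.DataFrame(desc["categorical"])
    parts.append(_fmt_table(cat, "Descriptives (categorical)"))
    parts.append(_fmt_table(pd.DataFrame(report["qc"]), "Genotype QC"))
    for label, block in report["pathways"].items():
        s = block["spec"]
        head = f"{label}: {s['exposure']} -> {s['mediator']} -> {s['outcome']}"
        est = block["estimate"]
        parts.append(_fmt_table(pd.DataFrame(est["mediator_model"]),
                                f"{head} | mediator equation ({s['mediator']})"))
        parts.append(_fmt_table(pd.DataFrame(est["outcome_model"]),
                                f"{head} | outcome equation ({s['outcome']})"))
        boot = block["bootstrap"]
        eff = pd.DataFrame([
            {"Effects": "Indirect (a1b1)", **boot["indirect"]},
            {"Effects": "Direct (c')", **boot["direct"]},
        ]).drop(columns=["bootstrap_mean"])
        parts.append(_fmt_table(eff, f"{head} | mediation effects (BC bootstrap)"))
        pm = block["percent_mediated"]
        parts.append(
            f"percent mediated [indirect/total]: "
            f"{_pm_str(pm['ratio'])}; [|ind|/(|ind|+|dir|)]: {_pm_str(pm['absolute'])}\n")
        sens = block["sensitivity"]
        rs = sens["rho_star"]
        parts.append(
            f"sensitivity: rho* = {'absent' if rs is None else f'{rs:.4f}'}, "
            f"R2 product (unexplained) = {_opt(sens['r2_product_unexplained'])}, "
            f"R2 product (original) = {_opt(sens['r2_product_original'])}\n")
    return "\n".join(parts)


def _opt(v, fmt="{:.6f}"):
    return "absent" if v is None else fmt.format(v)


def _pm_str(pm: dict) -> str:
    if pm["undefined"]:
        return "undefined (total ~ 0)"
    s = f"{pm['percent']:.1f}%"
    if pm["ci_lower"] is not None:
        s += f" (95% CI {100 * pm['ci_lower']:.1f}%, {100 * pm['ci_upper']:.1f}%)"
    return s


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Stages: load/simulate -> validate -> describe -> genotype QC ->
    pathway 1 -> pathway 2 -> sensitivity -> report. Any stage error aborts
    with a stage-labelled message; with a fixed seed the bundle is
    byte-identical across reruns.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"snpmediate {__version__}", f"seed={config.seed}",
                            f"n_reps={config.n_reps}", f"alpha={config.alpha}"]

    stage = "load"
    try:
        if config.simulation is not None:
            sim = dataclasses.replace(config.simulation,
                                      seed=config.seed if config.simulation.seed is None
                                      else config.simulation.seed)
            cohort, truth = simulate_cohort(sim)
            paths = write_cohort(cohort, truth, out_dir)
            cohort_bytes = Path(paths["cohort"]).read_bytes()
            log_lines.append(f"simulated cohort n={len(cohort)} -> {paths['cohort']}")
        else:
            cohort_bytes = Path(config.cohort_path).read_bytes()
            cohort = read_cohort(config.cohort_path)
            log_lines.append(f"loaded cohort n={len(cohort)} from {config.cohort_path}")
        checksum = hashlib.sha256(cohort_bytes).hexdigest()
        log_lines.append(f"input_sha256={checksum}")

        stage = "validate"
        for snp, minor in (("geno_snp1", config.minor_allele_snp1),
                           ("geno_snp2", config.minor_allele_snp2)):
            if snp in cohort.columns:
                cohort[snp] = encode_genotypes(cohort[snp], minor_allele=minor)
        for label, spec in (("pathway1", config.pathway1), ("pathway2", config.pathway2)):
            missing = [c for c in spec.columns if c not in cohort.columns]
            if missing:
                raise ValueError(f"{label} references missing columns {missing}")

        stage = "describe"
        descriptives = describe_cohort(cohort)

        stage = "genotype_qc"
        qc = [snp_qc(cohort[snp].dropna(), label=snp, hwe_warn_threshold=config.hwe_threshold)
              for snp in ("geno_snp1", "geno_snp2") if snp in cohort.columns]
        for block in qc:
            log_lines.append(f"qc {block['snp']}: maf={block['maf']:.4f} "
                             f"hwe_p={block['hwe_p']:.4g} flag={block['hwe_flag']}")

        stage = "mediation"
        raw = run_bidirectional(cohort, config.pathway1, config.pathway2,
                                n_reps=config.n_reps, alpha=config.alpha, seed=config.seed)

        stage = "report"
        report = {
            "version": __version__, "seed": config.seed, "n_reps": config.n_reps,
            "alpha": config.alpha, "n": raw["n"], "input_sha256": checksum,
            "significance_note": SIGNIFICANCE_NOTE,
            "descriptives": descriptives, "qc": qc, "pathways": {},
        }
        for label, block in raw["pathways"].items():
            report["pathways"][label] = {
                "spec": block["spec"],
                "estimate": _estimate_block(block["estimate"]),
                "bootstrap": _bootstrap_block(block["bootstrap"]),
                "percent_mediated": {k: _percent_block(v)
                                     for k, v in block["percent_mediated"].items()},
                "sensitivity": _sensitivity_block(block["sensitivity"]),
            }
            block["sensitivity"].to_frame().to_csv(
                out_dir / f"sensitivity_{label}.csv", index=False)
        (out_dir / "report.json").write_text(
            json.dumps(_jsonable(report), indent=2, sort_keys=True) + "\n")
        (out_dir / "tables.txt").write_text(render_tables(report))
        log_lines.append("status=complete")
        (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
        return report
    except Exception as exc:
        if isinstance(exc, PipelineError):
            raise
        log_lines.append(f"status=failed stage={stage}: {exc}")
        (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
        raise PipelineError(stage, str(exc)) from exc
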
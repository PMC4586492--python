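"""Genotype handling: additive coding, allele frequencies, and the
Hardy-Weinberg exact test used for quality control.

Biallelic SNPs only. Genotypes enter the regressions as the count of minor
alleles (0 = major homozygote, 1 = heterozygote, 2 = minor homozygote), the
additive coding standard for quantitative-trait association models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp


class GenotypeDataError(ValueError):
    """Raised for malformed genotype labels or codes."""


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype class counts at one biallelic site."""

    n_major_hom: int
    n_het: int
    n_minor_hom: int

    def __post_init__(self):
        for name in ("n_major_hom", "n_het", "n_minor_hom"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise GenotypeDataError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.n_major_hom + self.n_het + self.n_minor_hom

    @property
    def minor_allele_count(self) -> int:
        return 2 * self.n_minor_hom + self.n_het

    @classmethod
    def from_codes(cls, codes) -> "GenotypeCounts":
        arr = np.asarray(codes)
        if not np.isin(arr, (0, 1, 2)).all():
            bad = sorted(set(arr[~np.isin(arr, (0, 1, 2))].tolist()))
            raise GenotypeDataError(f"genotype codes outside {{0,1,2}}: {bad}")
        return cls(int(np.sum(arr == 0)), int(np.sum(arr == 1)), int(np.sum(arr == 2)))


def additive_code(genotype_label: str, minor_allele: str, major_allele: str | None = None) -> int:
    """Count minor alleles in an allele-pair label such as ``"AC"``.

    Order-insensitive: ``"AC"`` and ``"CA"`` both code 1. If ``major_allele``
    is not given it is inferred as the single non-minor symbol in the label.

    Raises
    ------
    GenotypeDataError
        If the label does not contain exactly two allele symbols, or a
        symbol is neither the minor nor the major allele.
    """
    label = str(genotype_label).strip().upper()
    minor = str(minor_allele).strip().upper()
    if len(minor) != 1:
        raise GenotypeDataError(f"minor allele must be one symbol, got {minor_allele!r}")
    if len(label) != 2:
        raise GenotypeDataError(f"genotype label must have exactly two allele symbols, got {genotype_label!r}")
    allowed = {minor}
    if major_allele is not None:
        allowed.add(str(major_allele).strip().upper())
    else:
        others = {a for a in label if a != minor}
        if len(others) > 1:
            raise GenotypeDataError(f"label {genotype_label!r} carries two non-minor alleles {sorted(others)}")
        allowed |= others
    for a in label:
        if a not in allowed:
            raise GenotypeDataError(f"unknown allele symbol {a!r} in genotype {genotype_label!r}")
    return sum(a == minor for a in label)


def encode_genotypes(values, minor_allele: str | None = None,
                     major_allele: str | None = None) -> np.ndarray:
    """Vectorised additive coding of a genotype column.

    Accepts either pre-coded integers in {0,1,2} (validated and passed
    through) or allele-pair strings, which require ``minor_allele``.
    """
    ser = pd.Series(values)
    if pd.api.types.is_numeric_dtype(ser):
        arr = ser.to_numpy()
        if not np.isin(arr, (0, 1, 2)).all():
            bad = sorted(set(arr[~np.isin(arr, (0, 1, 2))].tolist()))
            raise GenotypeDataError(f"pre-coded genotypes outside {{0,1,2}}: {bad}")
        return arr.astype(np.int64)
    if minor_allele is None:
        raise GenotypeDataError("minor_allele is required to code allele-pair genotype strings")
    return np.array([additive_code(v, minor_allele, major_allele) for v in ser], dtype=np.int64)


def minor_allele_frequency(codes) -> float:
    """Sample frequency of the allele counted by the additive code."""
    counts = GenotypeCounts.from_codes(codes)
    if counts.total == 0:
        raise GenotypeDataError("no genotypes")
    return counts.minor_allele_count / (2 * counts.total)


def _log_het_probabilities(n: int, n_rare: int) -> tuple[np.ndarray, np.ndarray]:
    """Log conditional probabilities of each feasible heterozygote count.

    Conditions on the observed allele counts: with ``n`` diploids and
    ``n_rare`` copies of the rarer allele, the heterozygote count ranges over
    values of the same parity as ``n_rare``, and

        P(het = h) ∝ 2^h * n! / (n_AA! * h! * n_aa!)

    where the homozygote counts are determined by ``h``. Log-factorial
    accumulation keeps this stable at cohort scale (n ≈ 2300).
    """
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    n_rare_hom = (n_rare - hets) // 2
    n_common_hom = n - hets - n_rare_hom
    logp = (
        hets * np.log(2.0)
        - gammaln(n_rare_hom + 1)
        - gammaln(hets + 1)
        - gammaln(n_common_hom + 1)
    )
    logp -= logsumexp(logp)
    return hets, logp


def hwe_exact_test(counts: GenotypeCounts) -> float:
    """Two-sided exact test of Hardy-Weinberg proportions.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts whose probability does not exceed that of the
    observed count (ties included in the tail). Returns a p-value in (0, 1].

    A monomorphic site carries no information about HWE; the test returns
    1.0 and emits a ``UserWarning``.
    """
    n = counts.total
    if n < 1:
        raise GenotypeDataError("HWE test requires at least one genotype")
    n_minor = counts.minor_allele_count
    n_rare = min(n_minor, 2 * n - n_minor)
    if n_rare == 0:
        warnings.warn("monomorphic site: HWE exact test is degenerate, returning p = 1.0",
                      UserWarning, stacklevel=2)
        return 1.0
    hets, logp = _log_het_probabilities(n, n_rare)
    obs = logp[hets == counts.n_het]
    if obs.size != 1:  # parity mismatch means counts are inconsistent
        raise GenotypeDataError(
            f"heterozygote count {counts.n_het} is infeasible for allele count {n_minor} in {n} diploids")
    # relative tolerance admits float ties with mathematically equal probabilities
    in_tail = logp <= obs[0] + 1e-12
    p = float(np.exp(logsumexp(logp[in_tail])))
    return min(p, 1.0)


def snp_qc(codes, label: str = "snp", hwe_warn_threshold: float = 0.05) -> dict:
    """QC block for one SNP: genotype counts, MAF, and the HWE exact p-value.

    ``hwe_flag`` is set when the p-value falls below the warning threshold;
    no subjects are excluded — the test is reported, not enforced.
    """
    counts = GenotypeCounts.from_codes(codes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        p = hwe_exact_test(counts)
    monomorphic = counts.minor_allele_count in (0, 2 * counts.total)
    return {
        "snp": label,
        "n": counts.total,
        "n_major_hom": counts.n_major_hom,
        "n_het": counts.n_het,
        "n_minor_hom": counts.n_minor_hom,
        "maf": minor_allele_frequency(codes),
        "hwe_p": p,
        "monomorphic": monomorphic,
        "hwe_flag": bool((p < hwe_warn_threshold) and not monomorphic),
    }
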
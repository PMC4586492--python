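"""Independent reference implementations used only to check the package.

Each oracle is deliberately naive — exact rational enumeration, explicit
pseudo-inverse algebra, or literal replay of resample indices — and shares
no code with the implementation it checks.
"""

from fractions import Fraction
from math import comb

import numpy as np
from scipy import stats


def hwe_enumeration_p(n_major_hom: int, n_het: int, n_minor_hom: int) -> float:
    """Exact two-sided HWE p-value by full enumeration with rational arithmetic.

    Conditional on allele counts, the probability of ``h`` heterozygotes
    among ``n`` diploids with ``na`` copies of one allele is

        P(h) = C(n, h) * C(n - h, (na - h)/2) * 2^h / C(2n, na)  ... equivalently
        P(h) proportional to 2^h / (n1! h! n2!)

    computed here with exact Fractions and normalised explicitly.
    """
    n = n_major_hom + n_het + n_minor_hom
    na = 2 * n_minor_hom + n_het
    na = min(na, 2 * n - na)
    if na == 0:
        return 1.0
    weights = {}
    for h in range(na % 2, min(na, 2 * n - na) + 1, 2):
        n_rare_hom = (na - h) // 2
        n_common_hom = n - h - n_rare_hom
        # multinomial count of genotype assignments, times 2^h orderings
        weights[h] = Fraction(2 ** h * comb(n, h) * comb(n - h, n_rare_hom), 1)
    total = sum(weights.values())
    obs = weights[n_het]
    tail = sum(w for w in weights.values() if w <= obs)
    return float(Fraction(tail, total))


def pinv_ols(X: np.ndarray, y: np.ndarray) -> dict:
    """OLS through the Moore-Penrose pseudo-inverse and textbook formulas."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    beta = np.linalg.pinv(X) @ y
    resid = y - X @ beta
    sigma2 = resid @ resid / (n - p)
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    pvals = 2 * stats.t.sf(np.abs(t), n - p)
    return {"beta": beta, "se": se, "t": t, "p": pvals, "sigma2": sigma2}


def replay_bootstrap_ci(cohort, spec, n_reps, alpha, seed, chunk_size=256):
    """Literal re-implementation of the case-resampling BC bootstrap.

    Draws the identical index stream (same generator, same chunking), refits
    each replicate with ``numpy.linalg.lstsq``, and applies the BC formula
    through ``scipy.stats.norm``. Returns (ci_indirect, ci_direct,
    replicate_indirect, replicate_direct).
    """
    data = cohort[list(spec.columns)].dropna()
    x = data[spec.exposure].to_numpy(float)
    m = data[spec.mediator].to_numpy(float)
    y = data[spec.outcome].to_numpy(float)
    Z = data[list(spec.covariates)].to_numpy(float)
    n = len(data)
    ones = np.ones(n)
    Xm = np.column_stack([ones, x, Z])
    Xy = np.column_stack([ones, m, x, Z])

    def effects(rows):
        bm = np.linalg.lstsq(Xm[rows], m[rows], rcond=None)[0]
        by = np.linalg.lstsq(Xy[rows], y[rows], rcond=None)[0]
        return bm[1] * by[1], by[2]

    point_ind, point_dir = effects(np.arange(n))
    rng = np.random.default_rng(seed)
    rep_ind, rep_dir = [], []
    done = 0
    while done < n_reps:
        B = min(chunk_size, n_reps - done)
        idx = rng.integers(0, n, size=(B, n))
        for b in range(B):
            ind, dire = effects(idx[b])
            rep_ind.append(ind)
            rep_dir.append(dire)
        done += B
    rep_ind = np.array(rep_ind)
    rep_dir = np.array(rep_dir)

    def bc_ci(reps, point):
        B = reps.size
        prop = (np.sum(reps < point) + 0.5 * np.sum(reps == point)) / B
        zmax = stats.norm.ppf(1 - 1 / B)
        z0 = np.clip(stats.norm.ppf(prop), -zmax, zmax)
        za = stats.norm.ppf(1 - alpha / 2)
        return tuple(np.quantile(reps, stats.norm.cdf([2 * z0 - za, 2 * z0 + za])))

    return bc_ci(rep_ind, point_ind), bc_ci(rep_dir, point_dir), rep_ind, rep_dir
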
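"""Synthetic cohort generator: distributions, determinism, truth records."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

import snpmediate as sm


def _linear_predictor(cohort, truth, which):
    prefix = f"{which}_coef_"
    exposure = cohort[truth["exposure_snp"]]
    lp = (truth[prefix + "intercept"] + truth[prefix + "genotype"] * exposure
          + truth[prefix + "age"] * cohort["age"] + truth[prefix + "gender"] * cohort["gender"]
          + truth[prefix + "bmi"] * cohort["bmi"] + truth[prefix + "tg"] * cohort["tg"])
    if which == "outcome":
        lp = lp + truth[prefix + "mediator"] * cohort[truth["mediator_column"]]
    return lp


def _generative_errors(cohort, truth):
    m_err = cohort[truth["mediator_column"]] - _linear_predictor(cohort, truth, "mediator")
    y_err = cohort[truth["outcome_column"]] - _linear_predictor(cohort, truth, "outcome")
    return np.asarray(m_err), np.asarray(y_err)


@pytest.mark.parametrize("bad", [dict(maf=0.0), dict(maf=0.6), dict(maf=-0.1), dict(n=0)])
def test_genotype_parameter_validation(bad):
    kwargs = dict(maf=0.3, n=10)
    kwargs.update(bad)
    with pytest.raises(sm.ParameterError):
        sm.simulate_genotypes(kwargs["maf"], kwargs["n"], seed=1)


def test_genotype_mean_matches_binomial_expectation():
    n = 100_000
    g = sm.simulate_genotypes(0.5, n, seed=42)
    se = np.sqrt(2 * 0.5 * 0.5 / n)
    assert abs(g.mean() - 1.0) < 3 * se


def test_genotype_determinism_under_seed():
    a = sm.simulate_genotypes(0.3, 500, seed=7)
    b = sm.simulate_genotypes(0.3, 500, seed=7)
    np.testing.assert_array_equal(a, b)


def test_genotype_frequencies_follow_hwe_across_seeds():
    """Chi-square goodness of fit to HWE proportions is non-significant in
    nearly all seeds at n = 10^4 (nominal 95%, minus Monte-Carlo slack)."""
    maf, n, seeds = 0.3, 10_000, 200
    expected = n * np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf ** 2])
    ok = 0
    for s in range(seeds):
        g = sm.simulate_genotypes(maf, n, seed=s)
        obs = np.bincount(g, minlength=3)
        ok += stats.chisquare(obs, expected).pvalue > 0.05
    assert ok / seeds >= 0.95 - 3 * np.sqrt(0.05 * 0.95 / seeds)


def test_params_validation():
    with pytest.raises(sm.ParameterError):
        sm.default_params(1, n_subjects=0)
    with pytest.raises(sm.ParameterError):
        sm.default_params(1, prop_male=1.2)
    with pytest.raises(sm.ParameterError):
        sm.default_params(1, sigma_mediator=0.0)
    with pytest.raises(sm.ParameterError):
        sm.default_params(3)


def test_implied_error_correlation_closed_form():
    p = sm.default_params(1, confounder_loading_m=1.0, confounder_loading_y=1.0)
    assert p.implied_error_correlation == pytest.approx(0.5, abs=1e-15)
    p0 = sm.default_params(1)
    assert p0.implied_error_correlation == 0.0


@pytest.mark.parametrize("loadings, expected_rho", [((0.0, 0.0), 0.0), ((1.0, 1.0), 0.5)])
def test_generative_error_correlation(loadings, expected_rho):
    params = sm.default_params(1, n_subjects=10_000, seed=314,
                               confounder_loading_m=loadings[0],
                               confounder_loading_y=loadings[1])
    cohort, truth = sm.simulate_cohort(params)
    m_err, y_err = _generative_errors(cohort, truth)
    r = np.corrcoef(m_err, y_err)[0, 1]
    se = (1 - expected_rho ** 2) / np.sqrt(len(cohort))
    assert abs(r - expected_rho) < 3 * se
    assert truth["implied_error_correlation"] == pytest.approx(expected_rho, abs=1e-12)


def test_pure_noise_cohort_is_standard_normal():
    zeros_m = dict.fromkeys(sm.simulate.MEDIATOR_COEF_KEYS, 0.0)
    zeros_y = dict.fromkeys(sm.simulate.OUTCOME_COEF_KEYS, 0.0)
    params = sm.SimulationParams(n_subjects=10_000, mediator_coefs=zeros_m,
                                 outcome_coefs=zeros_y, sigma_mediator=1.0,
                                 sigma_outcome=1.0, seed=5)
    cohort, _ = sm.simulate_cohort(params)
    for col in ("vitd", "ua"):
        assert abs(cohort[col].mean()) < 3 / np.sqrt(10_000)
        assert cohort[col].std(ddof=1) == pytest.approx(1.0, abs=0.05)


def test_marginal_descriptives_match_targets():
    cohort, _ = sm.simulate_cohort(sm.default_params(1, n_subjects=10_000, seed=2))
    assert abs(cohort["age"].mean() - 39.9) < 3 * 6.6 / 100
    assert abs(cohort["vitd"].mean() - 25.1) < 3 * cohort["vitd"].std() / 100
    assert abs(cohort["ua"].mean() - 5.6) < 3 * cohort["ua"].std() / 100
    assert abs((cohort["gender"] == 0).mean() - 0.743) < 3 * np.sqrt(0.743 * 0.257 / 10_000)
    assert (cohort["tg"] > 0).all()


def test_truth_record_echoes_generative_coefficients():
    params = sm.default_params(2, n_subjects=50, seed=3)
    _, truth = sm.simulate_cohort(params)
    assert truth["mediator_coef_genotype"] == pytest.approx(0.2726)
    assert truth["outcome_coef_mediator"] == pytest.approx(0.2956)
    assert truth["true_indirect"] == pytest.approx(0.2726 * 0.2956, abs=1e-15)
    assert truth["true_total"] == pytest.approx(truth["true_indirect"] + truth["true_direct"])
    assert truth["seed"] == 3 and truth["n_subjects"] == 50
    assert truth["mediator_column"] == "ua" and truth["exposure_snp"] == "geno_snp2"


def test_cohort_csv_is_byte_deterministic(tmp_path):
    params = sm.default_params(1, n_subjects=200, seed=17)
    for d in ("a", "b"):
        cohort, truth = sm.simulate_cohort(params)
        sm.write_cohort(cohort, truth, tmp_path / d)
    assert (tmp_path / "a/cohort.csv").read_bytes() == (tmp_path / "b/cohort.csv").read_bytes()
    assert (tmp_path / "a/cohort.truth.json").read_bytes() == (
        tmp_path / "b/cohort.truth.json").read_bytes()


def test_cohort_roundtrip_and_header(tmp_path):
    params = sm.default_params(1, n_subjects=30, seed=8)
    cohort, truth = sm.simulate_cohort(params)
    paths = sm.write_cohort(cohort, truth, tmp_path)
    text = (tmp_path / "cohort.csv").read_text().splitlines()
    assert text[0] == "# seed=8"
    assert text[1] == "id,geno_snp1,geno_snp2,age,gender,bmi,tg,vitd,ua"
    back = sm.read_cohort(paths["cohort"])
    assert len(back) == 30
    assert set(back["geno_snp1"]).issubset({0, 1, 2})
    assert not back.isna().any().any()
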
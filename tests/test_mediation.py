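"""Mediation engine: decomposition, bootstrap inference, percent mediated."""

import numpy as np
import pytest

import snpmediate as sm

from _oracles import replay_bootstrap_ci


class TestIndirectEffect:
    @pytest.mark.parametrize("a1, b1, expected", [
        (-2.4306, 0.0097, -0.02357682),
        (0.2726, 0.2956, 0.08058056),
        (0.0, 5.0, 0.0),
    ])
    def test_product_of_coefficients(self, a1, b1, expected):
        assert sm.indirect_effect(a1, b1) == pytest.approx(expected, abs=1e-15)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            sm.indirect_effect(np.nan, 1.0)


class TestFitPathway:
    def test_decomposition_identities(self, fitted_small):
        est = fitted_small
        assert est.indirect == sm.indirect_effect(est.a1, est.b1)
        assert est.total == est.indirect + est.c_prime
        assert est.a1 == est.mediator_fit.coef("geno_snp1")
        assert est.b1 == est.outcome_fit.coef("vitd")

    def test_total_effect_regression_equals_indirect_plus_direct(self, cohort_small, spec1):
        """Nested-OLS identity: the exposure slope of outcome ~ exposure +
        covariates equals a1*b1 + c' from the two path models exactly."""
        cohort, _ = cohort_small
        est = sm.fit_pathway(cohort, spec1)
        X, _, names = sm.ols.build_design(cohort, ["geno_snp1", "age", "gender", "bmi", "tg"])
        total_fit = sm.fit_ols(X, cohort["ua"].to_numpy(), names)
        assert total_fit.coef("geno_snp1") == pytest.approx(est.total, abs=1e-10)

    def test_null_mediator_path_gives_near_zero_indirect(self):
        params = sm.default_params(1, n_subjects=4000, seed=66,
                                   outcome_coefs={"mediator": 0.0})
        cohort, _ = sm.simulate_cohort(params)
        est = sm.fit_pathway(cohort, sm.PathwaySpec("geno_snp1", "vitd", "ua"))
        se_delta = np.sqrt(est.b1 ** 2 * est.mediator_fit.se("geno_snp1") ** 2
                           + est.a1 ** 2 * est.outcome_fit.se("vitd") ** 2)
        assert abs(est.indirect) < 3 * se_delta

    def test_constant_exposure_rejected(self, cohort_small, spec1):
        cohort, _ = cohort_small
        frozen = cohort.copy()
        frozen["geno_snp1"] = 1
        with pytest.raises(sm.ModelError, match="constant"):
            sm.fit_pathway(frozen, spec1)

    def test_missing_rows_dropped_and_counted(self, cohort_small, spec1):
        cohort, _ = cohort_small
        holey = cohort.copy()
        holey.loc[holey.index[:7], "vitd"] = np.nan
        est = sm.fit_pathway(holey, spec1)
        assert est.n_dropped == 7
        assert est.n_obs == len(cohort) - 7


class TestBCBootstrap:
    def test_validation(self, cohort_small, spec1):
        cohort, _ = cohort_small
        with pytest.raises(ValueError):
            sm.bc_bootstrap(cohort, spec1, n_reps=50)
        with pytest.raises(ValueError):
            sm.bc_bootstrap(cohort, spec1, n_reps=200, alpha=1.5)

    def test_seeded_bootstrap_is_reproducible(self, cohort_small, spec1):
        cohort, _ = cohort_small
        b1 = sm.bc_bootstrap(cohort, spec1, n_reps=200, seed=5)
        b2 = sm.bc_bootstrap(cohort, spec1, n_reps=200, seed=5)
        np.testing.assert_array_equal(b1.replicate_indirect, b2.replicate_indirect)
        assert b1.ci_indirect == b2.ci_indirect

    def test_bias_is_bootstrap_mean_minus_point(self, cohort_small, spec1):
        cohort, _ = cohort_small
        boot = sm.bc_bootstrap(cohort, spec1, n_reps=200, seed=5)
        assert boot.bias_indirect == pytest.approx(
            boot.replicate_indirect.mean() - boot.point_indirect, abs=1e-15)
        assert boot.ci_indirect[0] < boot.ci_indirect[1]
        assert boot.ci_direct[0] < boot.ci_direct[1]

    def test_matches_index_replay_oracle(self, spec1):
        """Same resample indices, independently refit and summarised."""
        cohort, _ = sm.simulate_cohort(sm.default_params(1, n_subjects=150, seed=12))
        boot = sm.bc_bootstrap(cohort, spec1, n_reps=200, seed=31)
        ci_ind, ci_dir, rep_ind, rep_dir = replay_bootstrap_ci(
            cohort, spec1, n_reps=200, alpha=0.05, seed=31)
        np.testing.assert_allclose(boot.replicate_indirect, rep_ind, atol=1e-9)
        np.testing.assert_allclose(boot.ci_indirect, ci_ind, atol=1e-9)
        np.testing.assert_allclose(boot.ci_direct, ci_dir, atol=1e-9)

    def test_symmetric_distribution_reduces_to_percentile(self):
        reps = np.linspace(-1, 1, 1001)
        lo, hi = sm.bias_corrected_interval(reps, point=0.0, alpha=0.05)
        plo, phi = np.quantile(reps, [0.025, 0.975])
        assert lo == pytest.approx(plo, abs=1e-12)
        assert hi == pytest.approx(phi, abs=1e-12)

    def test_ci_stable_in_replicate_count(self, cohort_small, spec1):
        cohort, _ = cohort_small
        b1k = sm.bc_bootstrap(cohort, spec1, n_reps=1000, seed=9)
        b2k = sm.bc_bootstrap(cohort, spec1, n_reps=2000, seed=9)
        width = b1k.ci_indirect[1] - b1k.ci_indirect[0]
        assert abs(b2k.ci_indirect[0] - b1k.ci_indirect[0]) < 0.1 * width
        assert abs(b2k.ci_indirect[1] - b1k.ci_indirect[1]) < 0.1 * width


def test_null_indirect_test_is_not_anticonservative():
    """With the exposure -> mediator path silenced, the 'BC CI excludes 0'
    decision rejects at most at the nominal rate (plus binomial slack).
    The product statistic is conservative under this null when the
    mediator -> outcome signal is weak, so only the upper bound is sharp."""
    res = sm.type_one_error_simulation(n_repeats=300, n_subjects=500,
                                       n_boot=300, seed=777)
    assert res["rejection_rate"] <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 300)


class TestPercentMediated:
    def test_definition_arithmetic_for_opposed_effects(self):
        """With opposed direct and indirect effects the two definitions
        diverge sharply — the share is definition-dependent."""
        est = _fake_estimate(indirect=-0.0235, c_prime=0.0765)
        ratio = sm.percent_mediated(est, definition="ratio")
        absolute = sm.percent_mediated(est, definition="absolute")
        assert absolute.percent == pytest.approx(23.5, abs=1e-10)
        assert ratio.percent == pytest.approx(100 * -0.0235 / 0.0530, abs=1e-8)
        assert ratio.definition == "ratio" and absolute.definition == "absolute"

    def test_boundary_cases(self):
        assert sm.percent_mediated(_fake_estimate(0.0, 0.5)).percent == 0.0
        assert sm.percent_mediated(_fake_estimate(0.3, 0.0)).percent == pytest.approx(100.0)
        und = sm.percent_mediated(_fake_estimate(0.3, -0.3))
        assert und.undefined and und.value is None

    def test_bootstrap_ci_attached(self, cohort_small, spec1):
        cohort, _ = cohort_small
        est = sm.fit_pathway(cohort, spec1)
        boot = sm.bc_bootstrap(cohort, spec1, n_reps=300, seed=4)
        pm = sm.percent_mediated(est, boot, definition="absolute")
        assert pm.ci_lower is not None and pm.ci_lower < pm.value < pm.ci_upper


def _fake_estimate(indirect, c_prime):
    a1, b1 = 1.0, indirect
    return sm.MediationEstimate(
        spec=sm.PathwaySpec("geno_snp1", "vitd", "ua"), a1=a1, b1=b1,
        c_prime=c_prime, indirect=indirect, total=indirect + c_prime,
        mediator_fit=None, outcome_fit=None, n_obs=0, n_dropped=0)


class TestRunBidirectional:
    def test_report_provenance_and_cross_module_consistency(self, cohort_small):
        cohort, _ = cohort_small
        report = sm.run_bidirectional(
            cohort, sm.PathwaySpec("geno_snp1", "vitd", "ua"),
            sm.PathwaySpec("geno_snp2", "ua", "vitd"), n_reps=150, seed=21)
        assert report["n"] == len(cohort)
        assert report["seed"] == 21 and report["n_reps"] == 150
        for label in ("pathway1", "pathway2"):
            block = report["pathways"][label]
            est, boot = block["estimate"], block["bootstrap"]
            assert boot.point_indirect == est.indirect
            sens = block["sensitivity"]
            assert sens.acme_at_zero == pytest.approx(est.indirect, abs=1e-8)

    def test_rejects_non_swapping_specs(self, cohort_small):
        cohort, _ = cohort_small
        with pytest.raises(ValueError, match="swap"):
            sm.run_bidirectional(cohort, sm.PathwaySpec("geno_snp1", "vitd", "ua"),
                                 sm.PathwaySpec("geno_snp2", "vitd", "ua"), n_reps=100)
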
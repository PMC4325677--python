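"""Summarized-data estimators: likelihood (ML/Bayes/LD) and regression-based."""

import numpy as np
import pytest
from scipy import stats

from mvmr import (
    LikelihoodParameters,
    SummaryAssociations,
    TraitCorrelationModel,
    VariantLDMatrix,
    build_variant_covariance,
    fit_likelihood_bayes,
    fit_likelihood_ld,
    fit_likelihood_ml,
    fit_regression_based,
    ivw_solution,
    loglik,
    or_per_fraction_change,
)
from mvmr.exceptions import ValidationError

from conftest import simulate_summary_data


def _make_assoc(J=6, K=2, seed=0, outcome_scale="linear"):
    rng = np.random.default_rng(seed)
    return SummaryAssociations(
        variant_ids=[f"v{j}" for j in range(J)],
        beta_exposures=rng.normal(0, 0.2, (J, K)),
        se_exposures=rng.uniform(0.02, 0.1, (J, K)),
        beta_outcome=rng.normal(0, 0.2, J),
        se_outcome=rng.uniform(0.02, 0.1, J),
        outcome_scale=outcome_scale,
    )


def _random_trait_corr(K1, seed):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(K1, K1 + 2))
    S = A @ A.T
    d = np.sqrt(np.diag(S))
    return TraitCorrelationModel(S / np.outer(d, d))


class TestVariantCovariance:
    def test_identity_corr_gives_diagonal(self):
        assoc = _make_assoc()
        cov = build_variant_covariance(assoc, 0, TraitCorrelationModel.identity(2))
        sig = np.append(assoc.se_exposures[0], assoc.se_outcome[0])
        np.testing.assert_allclose(cov, np.diag(sig**2), atol=1e-15)

    def test_direct_formula(self):
        assoc = SummaryAssociations(
            variant_ids=["v"],
            beta_exposures=[[0.0, 0.0]],
            se_exposures=[[0.1, 0.2]],
            beta_outcome=[0.0],
            se_outcome=[0.3],
        )
        corr = np.eye(3)
        corr[0, 1] = corr[1, 0] = 0.5
        cov = build_variant_covariance(assoc, 0, TraitCorrelationModel(corr))
        np.testing.assert_allclose(cov[0, 1], 0.5 * 0.1 * 0.2)
        np.testing.assert_allclose(np.diag(cov), [0.01, 0.04, 0.09])

    def test_elementwise_oracle(self):
        assoc = _make_assoc(J=4, K=3, seed=2)
        tc = _random_trait_corr(4, seed=3)
        for j in range(4):
            cov = build_variant_covariance(assoc, j, tc)
            sig = np.append(assoc.se_exposures[j], assoc.se_outcome[j])
            oracle = np.empty((4, 4))
            for a in range(4):
                for b in range(4):
                    oracle[a, b] = tc.corr[a, b] * sig[a] * sig[b]
            np.testing.assert_allclose(cov, oracle, atol=1e-15)


class TestLoglik:
    def test_zero_quadratic_form_closed_form(self):
        """Observed betas at the model mean: density is the normalizing constant."""
        xi = np.array([[0.2]])
        beta = np.array([0.5])
        assoc = SummaryAssociations(
            variant_ids=["v"], beta_exposures=xi.copy(), se_exposures=[[0.1]],
            beta_outcome=[0.2 * 0.5], se_outcome=[0.3],
        )
        tc = TraitCorrelationModel.identity(1)
        ll = loglik(LikelihoodParameters(xi, beta), assoc, tc)
        expected = -0.5 * (2 * np.log(2 * np.pi) + np.log(0.1**2 * 0.3**2))
        np.testing.assert_allclose(ll, expected, rtol=1e-12)

    def test_matches_dense_matrix_oracle(self):
        assoc = _make_assoc(J=5, K=2, seed=4)
        tc = _random_trait_corr(3, seed=5)
        rng = np.random.default_rng(6)
        params = LikelihoodParameters(rng.normal(size=(5, 2)), rng.normal(size=2))
        ll = loglik(params, assoc, tc)
        oracle = 0.0
        for j in range(5):
            sig = np.append(assoc.se_exposures[j], assoc.se_outcome[j])
            cov = tc.corr * np.outer(sig, sig)
            mean = np.append(params.xi[j], params.xi[j] @ params.beta)
            obs = np.append(assoc.beta_exposures[j], assoc.beta_outcome[j])
            r = obs - mean
            oracle += -0.5 * (
                3 * np.log(2 * np.pi)
                + np.linalg.slogdet(cov)[1]
                + r @ np.linalg.inv(cov) @ r
            )
        np.testing.assert_allclose(ll, oracle, rtol=1e-10)

    def test_doubling_ses_scaling_identity(self):
        """At a perfect fit with rho=0, doubling SEs costs (K+1)*J*ln 2."""
        J, K = 4, 2
        rng = np.random.default_rng(7)
        xi = rng.normal(size=(J, K))
        beta = rng.normal(size=K)
        tc = TraitCorrelationModel.identity(K)
        kw = dict(
            variant_ids=[f"v{j}" for j in range(J)],
            beta_exposures=xi.copy(), beta_outcome=xi @ beta,
        )
        a1 = SummaryAssociations(se_exposures=np.full((J, K), 0.1),
                                 se_outcome=np.full(J, 0.2), **kw)
        a2 = SummaryAssociations(se_exposures=np.full((J, K), 0.2),
                                 se_outcome=np.full(J, 0.4), **kw)
        p = LikelihoodParameters(xi, beta)
        np.testing.assert_allclose(
            loglik(p, a1, tc) - loglik(p, a2, tc), (K + 1) * J * np.log(2), rtol=1e-10
        )

    def test_invariant_under_variant_permutation(self):
        assoc = _make_assoc(J=6, K=2, seed=8)
        tc = _random_trait_corr(3, seed=9)
        rng = np.random.default_rng(10)
        xi = rng.normal(size=(6, 2))
        beta = rng.normal(size=2)
        perm = rng.permutation(6)
        permuted = SummaryAssociations(
            variant_ids=[assoc.variant_ids[j] for j in perm],
            beta_exposures=assoc.beta_exposures[perm],
            se_exposures=assoc.se_exposures[perm],
            beta_outcome=assoc.beta_outcome[perm],
            se_outcome=assoc.se_outcome[perm],
        )
        ll1 = loglik(LikelihoodParameters(xi, beta), assoc, tc)
        ll2 = loglik(LikelihoodParameters(xi[perm], beta), permuted, tc)
        np.testing.assert_allclose(ll1, ll2, rtol=1e-12)


class TestLikelihoodML:
    def test_vanishing_exposure_se_limit_is_ivw(self):
        """Exact exposure betas + identity correlations -> multivariable IVW."""
        assoc = _make_assoc(J=10, K=3, seed=11)
        tight = SummaryAssociations(
            variant_ids=assoc.variant_ids,
            beta_exposures=assoc.beta_exposures,
            se_exposures=np.full_like(assoc.se_exposures, 1e-6),
            beta_outcome=assoc.beta_outcome,
            se_outcome=assoc.se_outcome,
        )
        est = fit_likelihood_ml(tight, TraitCorrelationModel.identity(3))
        # weighted-normal-equations oracle: WLS of by on bx, weights 1/sy^2
        X, w, y = tight.beta_exposures, 1 / tight.se_outcome**2, tight.beta_outcome
        oracle = np.linalg.solve(X.T @ (X * w[:, None]), X.T @ (w * y))
        np.testing.assert_allclose(est.beta, oracle, atol=1e-6)

    def test_parameter_recovery(self, recovery_summary):
        assoc, xi, beta, tc = recovery_summary
        est = fit_likelihood_ml(assoc, tc)
        np.testing.assert_array_less(np.abs(est.beta - beta), 3 * est.se)
        assert est.diagnostics["converged"]
        assert est.diagnostics["n_parameters"] == 3 * (28 + 1)

    def test_coverage_nominal(self):
        """95% Wald intervals cover the truth at the nominal rate."""
        beta = np.array([0.3, 0.0, -0.1])
        tc = TraitCorrelationModel.identity(3)
        rng = np.random.default_rng(12)
        xi = rng.normal(0, 0.2, size=(28, 3))
        reps, covered = 200, np.zeros(3)
        for r in range(reps):
            assoc = simulate_summary_data(xi, beta, 0.02, 0.02, tc, seed=1000 + r)
            est = fit_likelihood_ml(assoc, tc)
            covered += (est.ci_lower <= beta) & (beta <= est.ci_upper)
        rate = covered / reps
        # binomial sampling error around 0.95 at 200 replicates
        tol = 3 * np.sqrt(0.95 * 0.05 / reps)
        assert np.all(np.abs(rate - 0.95) <= tol), rate

    def test_outcome_scale_propagates(self):
        assoc = _make_assoc(J=8, K=2, seed=13, outcome_scale="log_odds")
        est = fit_likelihood_ml(assoc, TraitCorrelationModel.identity(2))
        assert est.scale == "log_odds"


class TestLikelihoodLD:
    def test_identity_ld_reduces_to_independent_fit(self):
        assoc = _make_assoc(J=8, K=2, seed=14)
        tc = _random_trait_corr(3, seed=15)
        ml = fit_likelihood_ml(assoc, tc)
        ld = fit_likelihood_ld(assoc, tc, VariantLDMatrix(np.eye(8)))
        np.testing.assert_allclose(ld.beta, ml.beta, atol=1e-8)
        np.testing.assert_allclose(ld.se, ml.se, rtol=1e-4)

    def test_duplicated_variant_detected_as_singular(self):
        assoc = _make_assoc(J=2, K=1, seed=16)
        dup = SummaryAssociations(
            variant_ids=["a", "b"],
            beta_exposures=np.tile(assoc.beta_exposures[:1], (2, 1)),
            se_exposures=np.tile(assoc.se_exposures[:1], (2, 1)),
            beta_outcome=np.repeat(assoc.beta_outcome[:1], 2),
            se_outcome=np.repeat(assoc.se_outcome[:1], 2),
        )
        ld = VariantLDMatrix(np.array([[1.0, 1.0], [1.0, 1.0]]))
        with pytest.raises(ValidationError, match="clip_psd"):
            fit_likelihood_ld(dup, TraitCorrelationModel.identity(1), ld)

    def test_ld_calibrated_naive_miscalibrated(self):
        """Correlated variants: the LD-aware intervals attain nominal coverage
        while the independent-variant fit misstates its own sampling variability
        (its reported SEs no longer track the empirical SD, so its intervals
        are unreliable)."""
        rng = np.random.default_rng(17)
        J, K, rho = 8, 2, 0.4
        ldm = rho * np.ones((J, J)) + (1 - rho) * np.eye(J)
        xi = rng.normal(0, 0.3, (J, K))
        beta = np.array([0.4, -0.2])
        se_x = np.full((J, K), 0.05)
        se_y = np.full(J, 0.05)
        tc = TraitCorrelationModel.identity(K)
        # stacked-model draws with the separable covariance
        sig = np.column_stack([se_x, se_y])
        big = (ldm[:, None, :, None] * tc.corr[None, :, None, :]
               * sig[:, :, None, None] * sig[None, None, :, :]).reshape(J * 3, J * 3)
        mean = np.column_stack([xi, xi @ beta]).ravel()
        chol = np.linalg.cholesky(big)
        reps = 200
        covered = np.zeros(K)
        naive_est = np.empty((reps, K))
        naive_se = np.empty((reps, K))
        for r in range(reps):
            draw = (mean + chol @ rng.standard_normal(J * 3)).reshape(J, 3)
            assoc = SummaryAssociations(
                variant_ids=[f"v{j}" for j in range(J)],
                beta_exposures=draw[:, :K], se_exposures=se_x,
                beta_outcome=draw[:, K], se_outcome=se_y,
            )
            est = fit_likelihood_ld(assoc, tc, VariantLDMatrix(ldm))
            naive = fit_likelihood_ml(assoc, tc)
            covered += (est.ci_lower <= beta) & (beta <= est.ci_upper)
            naive_est[r] = naive.beta
            naive_se[r] = naive.se
        rate = covered / reps
        tol = 3 * np.sqrt(0.95 * 0.05 / reps)
        assert np.all(np.abs(rate - 0.95) <= tol), rate
        # the independent-variant fit understates its sampling SD for at
        # least one coefficient (anticonservative intervals under LD)
        ratio = naive_se.mean(axis=0) / naive_est.std(axis=0, ddof=1)
        assert ratio.min() < 0.85, ratio


class TestBayes:
    def test_posterior_mean_close_to_ml(self):
        """In the well-identified regime the posterior concentrates and its
        mean agrees with the maximum-likelihood estimate."""
        rng = np.random.default_rng(11)
        xi = rng.normal(0, 0.3, size=(28, 3))
        tc = TraitCorrelationModel.identity(3)
        assoc = simulate_summary_data(xi, [0.3, 0.0, -0.1], 0.01, 0.01, tc, seed=5)
        ml = fit_likelihood_ml(assoc, tc)
        est, summary = fit_likelihood_bayes(
            assoc, tc, chains=4, draws=1500, tune=500, seed=21
        )
        assert summary.converged, summary.rhat
        np.testing.assert_array_less(np.abs(est.beta - ml.beta), 0.1 * summary.sd)

    def test_prior_scale_insensitive_when_likelihood_dominates(self, recovery_summary):
        assoc, _, _, tc = recovery_summary
        e10, s10 = fit_likelihood_bayes(assoc, tc, prior_scale=10, chains=2,
                                        draws=1500, tune=500, seed=22)
        e100, _ = fit_likelihood_bayes(assoc, tc, prior_scale=100, chains=2,
                                       draws=1500, tune=500, seed=23)
        np.testing.assert_array_less(np.abs(e10.beta - e100.beta), 0.05 * s10.sd + 1e-12)

    def test_single_variant_ratio_limit(self):
        assoc = SummaryAssociations(
            variant_ids=["v"], beta_exposures=[[0.5]], se_exposures=[[1e-4]],
            beta_outcome=[0.2], se_outcome=[1e-4],
        )
        est, _ = fit_likelihood_bayes(assoc, TraitCorrelationModel.identity(1),
                                      chains=2, draws=1000, tune=500, seed=24)
        np.testing.assert_allclose(est.beta[0], 0.2 / 0.5, atol=5e-3)

    def test_reproducible_under_seed(self):
        assoc = _make_assoc(J=6, K=2, seed=25)
        tc = TraitCorrelationModel.identity(2)
        e1, _ = fit_likelihood_bayes(assoc, tc, chains=2, draws=200, tune=100, seed=9)
        e2, _ = fit_likelihood_bayes(assoc, tc, chains=2, draws=200, tune=100, seed=9)
        np.testing.assert_array_equal(e1.beta, e2.beta)


class TestRegressionBased:
    def test_orthogonal_design_exact(self):
        """by proportional to bx1, bx2 orthogonal to both: slope recovered exactly."""
        bx1 = np.array([1.0, -1.0, 2.0, -2.0, 0.5, -0.5])
        bx2 = np.array([1.0, 1.0, -1.0, -1.0, 0.0, 0.0])  # centered, bx2 @ bx1 = 0
        assert bx1 @ bx2 == 0 and bx1.sum() == 0 and bx2.sum() == 0
        by = 0.3 * bx1
        assoc = SummaryAssociations(
            variant_ids=[f"v{j}" for j in range(6)],
            beta_exposures=np.column_stack([bx1, bx2]),
            se_exposures=np.full((6, 2), 0.1),
            beta_outcome=by, se_outcome=np.full(6, 0.1),
        )
        est = fit_regression_based(assoc, target=0)
        np.testing.assert_allclose(est.beta[0], 0.3, atol=1e-12)
        assert np.isnan(est.beta[1])

    def test_two_stage_normal_equations_oracle(self):
        assoc = _make_assoc(J=12, K=3, seed=26)
        est = fit_regression_based(assoc)
        J = 12
        for k in range(3):
            comp = np.delete(assoc.beta_exposures, k, axis=1)
            X1 = np.column_stack([np.ones(J), comp])
            b1 = np.linalg.solve(X1.T @ X1, X1.T @ assoc.beta_outcome)
            resid = assoc.beta_outcome - X1 @ b1
            X2 = np.column_stack([np.ones(J), assoc.beta_exposures[:, k]])
            b2 = np.linalg.solve(X2.T @ X2, X2.T @ resid)
            np.testing.assert_allclose(est.beta[k], b2[1], rtol=1e-12)
        assert "comparator" in est.diagnostics

    def test_target_by_name(self):
        assoc = _make_assoc(J=10, K=2, seed=27)
        by_idx = fit_regression_based(assoc, target=1)
        by_name = fit_regression_based(assoc, target=assoc.exposure_names[1])
        np.testing.assert_array_equal(
            by_idx.beta[~np.isnan(by_idx.beta)], by_name.beta[~np.isnan(by_name.beta)]
        )


class TestOddsRatioTransform:
    def test_closed_forms(self):
        est = _log_odds_estimates(beta=[0.0, 1.0, -1.0])
        ors = or_per_fraction_change(est, 0.30)
        np.testing.assert_allclose(ors.odds_ratio, [1.0, 0.7, 1 / 0.7], rtol=1e-12)
        assert np.all(ors.ci_lower <= ors.odds_ratio)
        assert np.all(ors.odds_ratio <= ors.ci_upper)

    def test_monotone_decreasing_in_beta(self):
        grid = np.linspace(-2, 2, 9)
        ors = or_per_fraction_change(_log_odds_estimates(beta=grid), 0.30)
        assert np.all(np.diff(ors.odds_ratio) < 0)

    def test_requires_log_scale_and_valid_fraction(self):
        with pytest.raises(ValidationError):
            or_per_fraction_change(_log_odds_estimates([0.0], scale="linear"), 0.3)
        with pytest.raises(ValidationError):
            or_per_fraction_change(_log_odds_estimates([0.0]), 1.5)


def _log_odds_estimates(beta, scale="log_odds"):
    from mvmr import CausalEstimates

    beta = np.asarray(beta, float)
    se = np.full_like(beta, 0.1)
    z = stats.norm.ppf(0.975)
    return CausalEstimates(
        method="likelihood_ml", beta=beta, se=se,
        ci_lower=beta - z * se, ci_upper=beta + z * se, scale=scale,
        n_variants=5,
    )
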
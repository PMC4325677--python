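"""Causal-effect estimation from summarized association data.

The central model treats the observed per-variant beta coefficients for the
K risk factors and the outcome as a (K+1)-variate normal around latent true
genetic associations xi:

    (bx_1j, ..., bx_Kj, by_j) ~ N( (xi_1j, ..., xi_Kj, sum_k beta_k xi_kj),
                                   Sigma_j )

where Sigma_j has the reported squared standard errors on its diagonal and
off-diagonal terms rho_ab * sigma_aj * sigma_bj driven by the trait
correlations (zero when exposure and outcome associations come from
non-overlapping samples).  The model has K(J+1) free parameters: the J*K
latent associations xi and the K causal effects beta.

Fitting routes:

* :func:`fit_likelihood_ml` — maximum likelihood via the profile trick: for
  fixed beta the optimal xi for each variant is a closed-form GLS solve, so
  the numerical optimisation runs over the K causal effects only.
* :func:`fit_likelihood_bayes` — a blocked Gibbs sampler; both full
  conditionals (xi | beta and beta | xi) are Gaussian under independent
  normal priors, so no tuning is needed and chains mix rapidly.
* :func:`fit_likelihood_ld` — variants in linkage disequilibrium: a single
  stacked J(K+1)-variate normal whose cross-variant covariance is the
  separable product rho_LD(j, j') * rho_ab * sigma_aj * sigma_bj'.
* :func:`fit_regression_based` — the two-step residual-regression comparator
  (outcome betas regressed on competing risk-factor betas, residuals then
  regressed on the target risk factor's betas).  It ignores the uncertainty
  in the beta coefficients and is reproduced faithfully as an ad hoc
  comparator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import optimize, stats

from .exceptions import EstimationError, IdentificationError, ValidationError
from .estimators_individual import CausalEstimates, wald_interval
from .summary_data import SummaryAssociations, TraitCorrelationModel, VariantLDMatrix

__all__ = [
    "LikelihoodParameters",
    "PosteriorSummary",
    "OddsRatioEstimates",
    "build_variant_covariance",
    "loglik",
    "fit_likelihood_ml",
    "fit_likelihood_bayes",
    "fit_likelihood_ld",
    "fit_regression_based",
    "ivw_solution",
    "or_per_fraction_change",
]

logger = logging.getLogger(__name__)

_LOG_2PI = np.log(2 * np.pi)


@dataclass
class LikelihoodParameters:
    """Parameter vector of the summarized-data model.

    ``xi`` is the J x K matrix of latent true genetic associations with the
    risk factors; ``beta`` the K causal effects.  Total parameter count is
    K*(J+1).
    """

    xi: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        self.xi = np.asarray(self.xi, dtype=float)
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if self.xi.ndim != 2 or self.xi.shape[1] != self.beta.shape[0]:
            raise ValidationError(
                f"xi shape {self.xi.shape} inconsistent with beta length "
                f"{self.beta.shape[0]}"
            )

    @property
    def n_parameters(self) -> int:
        J, K = self.xi.shape
        return K * (J + 1)


@dataclass
class PosteriorSummary:
    """Posterior draws summary for the causal-effect parameters."""

    n_draws: int
    mean: np.ndarray
    sd: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    level: float
    rhat: np.ndarray
    converged: bool

    def __post_init__(self) -> None:
        if np.any(self.ci_lower > self.ci_upper):
            raise ValidationError("credible interval endpoints out of order")
        if self.rhat.shape != self.mean.shape:
            raise ValidationError("one scale-reduction statistic required per effect")


@dataclass
class OddsRatioEstimates:
    """Causal odds (or risk) ratios per fractional reduction in exposure."""

    odds_ratio: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    fraction: float
    level: float
    exposure_names: list[str] = field(default_factory=list)
    method: str = ""


def build_variant_covariance(
    assoc: SummaryAssociations, j: int, trait_corr: TraitCorrelationModel
) -> np.ndarray:
    """(K+1)x(K+1) covariance of variant j's beta coefficients.

    Entry (a, b) = rho_ab * sigma_aj * sigma_bj, with trait order
    (exposures..., outcome); the diagonal is the squared reported SEs.
    """
    sig = np.append(assoc.se_exposures[j], assoc.se_outcome[j])
    K1 = sig.shape[0]
    if trait_corr.corr.shape != (K1, K1):
        raise ValidationError(
            f"trait correlation matrix is {trait_corr.corr.shape}, expected {(K1, K1)}"
        )
    cov = trait_corr.corr * np.outer(sig, sig)
    if np.linalg.eigvalsh(cov).min() < -1e-10 * sig.max() ** 2:
        raise ValidationError(
            f"covariance for variant {assoc.variant_ids[j]!r} is not positive "
            "semi-definite; repair trait_corr to a valid (PSD) correlation matrix"
        )
    return cov


class _VariantwiseLikelihood:
    """Precomputed per-variant Gaussian machinery (independent variants).

    Stores the observed beta matrix B (J x (K+1)), the per-variant covariance
    inverses and log-determinants, and exposes the profile trick: for fixed
    beta the per-variant GLS solve for xi is closed-form.
    """

    def __init__(self, assoc: SummaryAssociations, trait_corr: TraitCorrelationModel):
        J, K = assoc.beta_exposures.shape
        self.J, self.K = J, K
        self.B = np.column_stack([assoc.beta_exposures, assoc.beta_outcome])
        sig = np.column_stack([assoc.se_exposures, assoc.se_outcome])
        cov = trait_corr.corr[None, :, :] * sig[:, :, None] * sig[:, None, :]
        self.cov = cov
        self.variant_ids = assoc.variant_ids
        self.Sinv = np.empty_like(cov)
        self.logdet = np.empty(J)
        for j in range(J):
            sign, ld = np.linalg.slogdet(cov[j])
            if sign <= 0 or not np.isfinite(ld):
                raise EstimationError(
                    f"singular beta-coefficient covariance for variant "
                    f"{assoc.variant_ids[j]!r}"
                )
            self.Sinv[j] = np.linalg.inv(cov[j])
            self.logdet[j] = ld

    def _design(self, beta: np.ndarray) -> np.ndarray:
        # A maps xi_j to the mean vector: identity block plus outcome row beta'
        return np.vstack([np.eye(self.K), beta])

    def loglik(self, xi: np.ndarray, beta: np.ndarray) -> float:
        mean = np.column_stack([xi, xi @ beta])
        r = self.B - mean
        quad = np.einsum("ja,jab,jb->", r, self.Sinv, r)
        return float(-0.5 * (quad + self.logdet.sum() + self.J * (self.K + 1) * _LOG_2PI))

    def profile_xi(self, beta: np.ndarray) -> np.ndarray:
        """GLS solve for the optimal latent associations at fixed beta."""
        A = self._design(beta)
        AtSinv = np.einsum("ak,jab->jkb", A, self.Sinv)
        lhs = AtSinv @ A              # (J, K, K)
        rhs = np.einsum("jkb,jb->jk", AtSinv, self.B)
        return np.linalg.solve(lhs, rhs[:, :, None])[:, :, 0]

    def profile_negloglik(self, beta: np.ndarray) -> float:
        return -self.loglik(self.profile_xi(beta), beta)


def loglik(
    params: LikelihoodParameters,
    assoc: SummaryAssociations,
    trait_corr: TraitCorrelationModel,
) -> float:
    """Log-likelihood of the summarized-data model at ``params``.

    Sum over variants of the (K+1)-variate normal log-density of the observed
    beta vector at mean (xi_1j, ..., xi_Kj, sum_k beta_k xi_kj) and the
    covariance from :func:`build_variant_covariance`.
    """
    J, K = assoc.beta_exposures.shape
    if params.xi.shape != (J, K):
        raise ValidationError(f"xi must be {J}x{K}, got {params.xi.shape}")
    model = _VariantwiseLikelihood(assoc, trait_corr)
    return model.loglik(params.xi, params.beta)


def ivw_solution(assoc: SummaryAssociations) -> tuple[np.ndarray, np.ndarray]:
    """Multivariable inverse-variance weighted estimate and covariance.

    Weighted least squares of the outcome betas on the K exposure-beta
    columns with weights 1/se_outcome^2 and no intercept — the limit of the
    likelihood model when the exposure betas are treated as exact and traits
    are uncorrelated.  Used as the optimiser starting point and as the
    analytic limit oracle.
    """
    X = assoc.beta_exposures
    w = 1.0 / assoc.se_outcome**2
    xtwx = X.T @ (X * w[:, None])
    beta = np.linalg.solve(xtwx, X.T @ (w * assoc.beta_outcome))
    return beta, np.linalg.inv(xtwx)


def _numerical_hessian(fun, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian; steps scaled to parameter magnitude."""
    n = x.shape[0]
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.empty((n, n))
    for i in range(n):
        for k in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ek = np.zeros(n); ek[k] = h[k]
            fpp = fun(x + ei + ek)
            fpm = fun(x + ei - ek)
            fmp = fun(x - ei + ek)
            fmm = fun(x - ei - ek)
            H[i, k] = H[k, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[k])
    return H


def _finalize_ml(
    model, beta0: np.ndarray, assoc: SummaryAssociations, level: float,
    method_label: str, extra_diag: dict[str, Any],
) -> CausalEstimates:
    """Shared ML driver: optimise the profile likelihood, SEs from its Hessian."""
    res = optimize.minimize(model.profile_negloglik, beta0, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
    res2 = optimize.minimize(model.profile_negloglik, res.x, method="BFGS",
                             options={"gtol": 1e-9})
    best = res2 if res2.fun <= res.fun else res
    if not (res.success or res2.success):
        raise EstimationError(
            f"likelihood maximization did not converge: {res.message} / {res2.message}"
        )
    beta_hat = np.asarray(best.x, dtype=float)
    # Profile-likelihood curvature in beta equals the beta block of the
    # inverse full observed information, so these are the correct Wald SEs
    # accounting for the estimated latent associations.
    H = _numerical_hessian(model.profile_negloglik, beta_hat)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:
        raise EstimationError("observed information matrix is singular") from exc
    diag_cov = np.diag(cov)
    if np.any(diag_cov <= 0):
        raise EstimationError("observed information is not positive definite at optimum")
    se = np.sqrt(diag_cov)
    lo, hi = wald_interval(beta_hat, se, level)
    scale = assoc.outcome_scale
    diagnostics = {
        "converged": bool(res.success or res2.success),
        "loglik": -float(best.fun),
        "n_parameters": assoc.n_exposures * (assoc.n_variants + 1),
        "optimizer": "profile likelihood over beta; per-variant GLS solve for xi",
        **extra_diag,
    }
    return CausalEstimates(
        method=method_label, beta=beta_hat, se=se, ci_lower=lo, ci_upper=hi,
        level=level, scale=scale, n_variants=assoc.n_variants,
        exposure_names=list(assoc.exposure_names), diagnostics=diagnostics,
    )


def _default_corr(assoc: SummaryAssociations,
                  trait_corr: TraitCorrelationModel | None) -> TraitCorrelationModel:
    if trait_corr is not None:
        return trait_corr
    logger.warning(
        "no trait correlation matrix supplied; assuming uncorrelated beta "
        "coefficients (valid for non-overlapping samples). With overlapping "
        "samples the correlations should be set approximately equal to the "
        "observational trait correlations — consider a sensitivity analysis "
        "over plausible values (reporting.correlation_sensitivity)."
    )
    return TraitCorrelationModel.identity(assoc.n_exposures)


def fit_likelihood_ml(
    assoc: SummaryAssociations,
    trait_corr: TraitCorrelationModel | None = None,
    level: float = 0.95,
) -> CausalEstimates:
    """Maximum-likelihood fit of the summarized-data model.

    Valid only for variants that are mutually uncorrelated (no linkage
    disequilibrium); use :func:`fit_likelihood_ld` otherwise.  Standard
    errors come from the observed information at the optimum; intervals are
    Wald.  Binary-outcome inputs (log odds ratios / log relative risks)
    yield causal effects on the same scale.
    """
    if assoc.n_variants < assoc.n_exposures:
        raise IdentificationError(
            f"J={assoc.n_variants} variants cannot identify K={assoc.n_exposures} effects"
        )
    trait_corr = _default_corr(assoc, trait_corr)
    model = _VariantwiseLikelihood(assoc, trait_corr)
    beta0, _ = ivw_solution(assoc)
    return _finalize_ml(model, beta0, assoc, level, "likelihood_ml", {})


class _StackedLikelihood:
    """J(K+1)-variate normal over all variants jointly (variants in LD).

    Stacking is variant-major: component (j, a) is trait a of variant j.
    Cov[(j,a), (j',b)] = rho_LD[j,j'] * rho_ab * sigma_aj * sigma_bj'.
    The within-variant blocks (j = j') coincide with the independent model;
    the cross-variant, within-trait blocks carry the LD correlation, and the
    cross-variant, cross-trait blocks use the separable product — the
    natural completion of the within-trait rule, documented as an assumption.
    """

    def __init__(self, assoc: SummaryAssociations, trait_corr: TraitCorrelationModel,
                 ld: VariantLDMatrix, clip_psd: bool = False):
        J, K = assoc.beta_exposures.shape
        self.J, self.K = J, K
        if ld.corr.shape != (J, J):
            raise ValidationError(f"LD matrix is {ld.corr.shape}, expected {(J, J)}")
        sig = np.column_stack([assoc.se_exposures, assoc.se_outcome])  # (J, K+1)
        big = (ld.corr[:, None, :, None] * trait_corr.corr[None, :, None, :]
               * sig[:, :, None, None] * sig[None, None, :, :])
        self.Sigma = big.reshape(J * (K + 1), J * (K + 1))
        eig = np.linalg.eigvalsh(self.Sigma)
        if eig.min() <= 1e-12 * eig.max():
            if not clip_psd:
                raise ValidationError(
                    "stacked LD covariance is singular or not positive definite "
                    "(e.g. perfectly collinear variants); pass clip_psd=True to "
                    "clip small eigenvalues explicitly, or drop duplicate variants"
                )
            w, V = np.linalg.eigh(self.Sigma)
            floor = 1e-10 * eig.max()
            w = np.maximum(w, floor)
            self.Sigma = (V * w) @ V.T
            logger.warning("stacked covariance eigenvalues clipped at %.3g", floor)
        self.chol = np.linalg.cholesky(self.Sigma)
        self.logdet = 2 * np.sum(np.log(np.diag(self.chol)))
        self.b = np.column_stack([assoc.beta_exposures, assoc.beta_outcome]).ravel()

    def _solve(self, M: np.ndarray) -> np.ndarray:
        y = np.linalg.solve(self.chol, M)
        return np.linalg.solve(self.chol.T, y)

    def loglik(self, xi: np.ndarray, beta: np.ndarray) -> float:
        mean = np.column_stack([xi, xi @ beta]).ravel()
        r = self.b - mean
        quad = r @ self._solve(r)
        return float(-0.5 * (quad + self.logdet + self.b.shape[0] * _LOG_2PI))

    def profile_xi(self, beta: np.ndarray) -> np.ndarray:
        A = np.vstack([np.eye(self.K), beta])         # (K+1, K)
        Abig = np.kron(np.eye(self.J), A)             # (J(K+1), JK)
        SinvA = self._solve(Abig)
        lhs = Abig.T @ SinvA
        rhs = SinvA.T @ self.b
        return np.linalg.solve(lhs, rhs).reshape(self.J, self.K)

    def profile_negloglik(self, beta: np.ndarray) -> float:
        return -self.loglik(self.profile_xi(beta), beta)


def fit_likelihood_ld(
    assoc: SummaryAssociations,
    trait_corr: TraitCorrelationModel | None = None,
    ld: VariantLDMatrix | None = None,
    level: float = 0.95,
    clip_psd: bool = False,
) -> CausalEstimates:
    """LD-aware maximum-likelihood fit using the stacked multivariate normal.

    With ``ld`` equal to the identity this reduces exactly to
    :func:`fit_likelihood_ml`.  Correlated variants widen the standard
    errors relative to the (anti-conservative) independent-variant fit.
    """
    if assoc.n_variants < assoc.n_exposures:
        raise IdentificationError(
            f"J={assoc.n_variants} variants cannot identify K={assoc.n_exposures} effects"
        )
    trait_corr = _default_corr(assoc, trait_corr)
    if ld is None:
        ld = VariantLDMatrix(np.eye(assoc.n_variants), list(assoc.variant_ids))
    model = _StackedLikelihood(assoc, trait_corr, ld, clip_psd=clip_psd)
    beta0, _ = ivw_solution(assoc)
    return _finalize_ml(model, beta0, assoc, level, "likelihood_ld",
                        {"ld_aware": True})


def _split_rhat(chains: np.ndarray) -> np.ndarray:
    """Split-chain potential scale reduction, per parameter.

    ``chains`` has shape (n_chains, n_draws, K); each chain is split in half
    before the between/within variance comparison.
    """
    c, d, K = chains.shape
    half = d // 2
    segs = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)
    m, n = segs.shape[0], segs.shape[1]
    means = segs.mean(axis=1)
    W = segs.var(axis=1, ddof=1).mean(axis=0)
    B = n * means.var(axis=0, ddof=1)
    var_plus = (n - 1) / n * W + B / n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_plus / W)
    return np.where(W > 0, rhat, 1.0)


def fit_likelihood_bayes(
    assoc: SummaryAssociations,
    trait_corr: TraitCorrelationModel | None = None,
    prior_scale: float = 10.0,
    chains: int = 4,
    draws: int = 2000,
    tune: int = 500,
    seed: int | None = None,
    level: float = 0.95,
) -> tuple[CausalEstimates, PosteriorSummary]:
    """Bayesian fit by blocked Gibbs sampling.

    Priors are independent N(0, prior_scale^2) on every latent association
    and every causal effect.  Both full conditionals are Gaussian: given
    beta, the xi for each variant is a K-variate GLS posterior; given xi,
    beta is a K-variate Gaussian because the mean is linear in beta.  The
    sampler therefore requires no tuning and is exactly reproducible under a
    fixed seed.  ``draws`` is per chain, after ``tune`` discarded warm-up
    iterations (minimum 100 retained draws per chain).
    """
    if draws < 100:
        raise ValidationError("at least 100 retained draws per chain are required")
    if assoc.n_variants < assoc.n_exposures:
        raise IdentificationError(
            f"J={assoc.n_variants} variants cannot identify K={assoc.n_exposures} effects"
        )
    trait_corr = _default_corr(assoc, trait_corr)
    model = _VariantwiseLikelihood(assoc, trait_corr)
    J, K = model.J, model.K
    Sinv = model.Sinv
    B = model.B
    prior_prec = 1.0 / prior_scale**2
    root = np.random.SeedSequence(seed)
    chain_seeds = root.spawn(chains)

    beta0, _ = ivw_solution(assoc)
    all_beta = np.empty((chains, draws, K))
    for c in range(chains):
        rng = np.random.default_rng(chain_seeds[c])
        beta = beta0 + rng.normal(scale=0.1 + np.abs(beta0) * 0.1, size=K)
        xi = assoc.beta_exposures.copy()
        for it in range(tune + draws):
            # xi_j | beta  (independent K-variate Gaussians, batched over j)
            A = np.vstack([np.eye(K), beta])
            AtSinv = np.einsum("ak,jab->jkb", A, Sinv)
            prec = AtSinv @ A + prior_prec * np.eye(K)[None]
            rhs = np.einsum("jkb,jb->jk", AtSinv, B)
            chol = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, rhs[:, :, None])[:, :, 0]
            z = rng.standard_normal((J, K))
            # sample: mean + chol^{-T} z
            xi = mean + np.linalg.solve(np.transpose(chol, (0, 2, 1)), z[:, :, None])[:, :, 0]
            # beta | xi : residual is linear in beta through the outcome row
            c_resid = B.copy()
            c_resid[:, :K] -= xi
            s_yy = Sinv[:, K, K]                       # scalar per variant
            lin = np.einsum("jk,j->k", xi, np.einsum("jb,jb->j", Sinv[:, K, :], c_resid))
            prec_b = np.einsum("j,jk,jl->kl", s_yy, xi, xi) + prior_prec * np.eye(K)
            cholb = np.linalg.cholesky(prec_b)
            mean_b = np.linalg.solve(prec_b, lin)
            beta = mean_b + np.linalg.solve(cholb.T, rng.standard_normal(K))
            if it >= tune:
                all_beta[c, it - tune] = beta

    flat = all_beta.reshape(-1, K)
    post_mean = flat.mean(axis=0)
    post_sd = flat.std(axis=0, ddof=1)
    alpha = (1 - level) / 2
    lo = np.quantile(flat, alpha, axis=0)
    hi = np.quantile(flat, 1 - alpha, axis=0)
    rhat = _split_rhat(all_beta)
    converged = bool(np.all(rhat < 1.05))
    if not converged:
        logger.warning("Gibbs chains not converged: max split-Rhat = %.3f", rhat.max())
    summary = PosteriorSummary(
        n_draws=chains * draws, mean=post_mean, sd=post_sd,
        ci_lower=lo, ci_upper=hi, level=level, rhat=rhat, converged=converged,
    )
    est = CausalEstimates(
        method="likelihood_bayes", beta=post_mean, se=post_sd,
        ci_lower=np.minimum(lo, post_mean), ci_upper=np.maximum(hi, post_mean),
        level=level, scale=assoc.outcome_scale, n_variants=J,
        exposure_names=list(assoc.exposure_names),
        diagnostics={
            "sampler": "blocked Gibbs (conjugate Gaussian conditionals)",
            "prior_scale": prior_scale, "chains": chains, "draws": draws,
            "tune": tune, "rhat": rhat, "converged": converged,
            "interval": "central posterior quantiles",
        },
    )
    return est, summary


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Plain OLS: coefficients, residuals, coefficient SEs (naive)."""
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise IdentificationError("regressor matrix is rank deficient (collinear columns)")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = n - p
    if dof <= 0:
        raise ValidationError("not enough rows for OLS degrees of freedom")
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return coef, resid, np.sqrt(np.diag(cov))


def fit_regression_based(
    assoc: SummaryAssociations,
    target: int | str | None = None,
    level: float = 0.95,
    include_intercept: bool = True,
) -> CausalEstimates:
    """Two-step residual-regression estimate from summarized data.

    Stage 1 regresses the outcome betas on the beta columns of the competing
    risk factors; stage 2 regresses the stage-1 residuals on the target risk
    factor's betas, and the stage-2 slope is the estimate, with its naive
    OLS standard error.  The method ignores the uncertainty in the beta
    coefficients; it is reproduced faithfully as an ad hoc comparator and
    flagged as such in the diagnostics.

    ``target`` selects one risk factor (index or name); ``None`` loops over
    all K and returns the full vector.
    """
    J, K = assoc.beta_exposures.shape
    if J <= K:
        raise IdentificationError(f"regression-based method needs J > K (J={J}, K={K})")
    if target is None:
        targets = list(range(K))
    else:
        if isinstance(target, str):
            target = assoc.exposure_names.index(target)
        targets = [int(target)]

    beta = np.full(K, np.nan)
    se = np.full(K, np.nan)
    for k in targets:
        competing = np.delete(assoc.beta_exposures, k, axis=1)
        if include_intercept:
            X1 = np.column_stack([np.ones(J), competing])
        else:
            X1 = competing if competing.size else np.zeros((J, 0))
        if X1.shape[1] > 0:
            _, resid, _ = _ols(assoc.beta_outcome, X1)
        else:
            resid = assoc.beta_outcome.copy()
        x_t = assoc.beta_exposures[:, k]
        X2 = np.column_stack([np.ones(J), x_t]) if include_intercept else x_t[:, None]
        coef2, _, se2 = _ols(resid, X2)
        beta[k] = coef2[-1]
        se[k] = se2[-1]

    lo = np.where(np.isnan(beta), np.nan, beta)
    hi = lo.copy()
    ok = ~np.isnan(beta)
    lo_ok, hi_ok = wald_interval(beta[ok], se[ok], level)
    lo[ok], hi[ok] = lo_ok, hi_ok
    return CausalEstimates(
        method="regression_based", beta=beta, se=se, ci_lower=lo, ci_upper=hi,
        level=level, scale=assoc.outcome_scale, n_variants=J,
        exposure_names=list(assoc.exposure_names),
        diagnostics={
            "comparator": "ad hoc two-step residual regression; ignores "
                          "uncertainty in the beta coefficients",
            "include_intercept": include_intercept,
        },
    )


def or_per_fraction_change(estimates: CausalEstimates, fraction: float = 0.30) -> OddsRatioEstimates:
    """Causal odds/risk ratio per (100*fraction)% reduction in each exposure.

    Requires log-scale outcome associations and risk factors measured on a
    natural-log concentration scale: a (100*f)% reduction then corresponds
    to an exposure shift of ln(1 - f), so OR = exp(beta * ln(1 - f)).
    Interval endpoints are transformed monotonically (the map is decreasing
    in beta, so the endpoints swap).
    """
    if not (0 < fraction < 1):
        raise ValidationError(f"fraction must lie in (0, 1), got {fraction}")
    if estimates.scale not in ("log_odds", "log_relative_risk"):
        raise ValidationError(
            "odds-ratio transformation requires a log_odds or log_relative_risk "
            f"outcome scale, got {estimates.scale!r}"
        )
    factor = np.log1p(-fraction)  # negative
    or_hat = np.exp(estimates.beta * factor)
    e1 = np.exp(estimates.ci_lower * factor)
    e2 = np.exp(estimates.ci_upper * factor)
    return OddsRatioEstimates(
        odds_ratio=or_hat,
        ci_lower=np.minimum(e1, e2),
        ci_upper=np.maximum(e1, e2),
        fraction=fraction,
        level=estimates.level,
        exposure_names=list(estimates.exposure_names),
        method=estimates.method,
    )
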
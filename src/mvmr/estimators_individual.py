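"""Causal-effect estimation from individual-level data.

The workhorse is multivariable two-stage least squares (2SLS): regress the K
risk factors jointly on the J genetic instruments (first stage), then regress
the outcome on the K fitted risk-factor columns (second stage).  The point
estimates equal the sequential-regression solution, but the standard errors
are the IV-corrected ones — the residual variance is computed from the
ORIGINAL risk factors, not the fitted values, which is what dedicated IV
software does and what a naive second-stage OLS gets wrong.

``fit_sequential_adjustment`` implements a known-biased comparator in which
each risk factor is instrumented in turn while the others are adjusted for
as if they were confounders; it is provided only so its bias can be
demonstrated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import stats

from .exceptions import IdentificationError, ValidationError
from .summary_data import IndividualDataset

__all__ = ["CausalEstimates", "fit_2sls", "fit_sequential_adjustment"]

METHODS = (
    "twostage",
    "likelihood_ml",
    "likelihood_bayes",
    "likelihood_ld",
    "regression_based",
    "sequential_adjustment",
)


@dataclass
class CausalEstimates:
    """Direct causal effect estimates for K risk factors.

    ``beta[k]`` is the estimated effect of risk factor k on the outcome
    holding the other modelled risk factors fixed (the controlled direct
    effect); on a binary outcome analysed via log odds ratios the estimates
    are log odds ratios.  ``diagnostics`` carries method-specific extras
    (first-stage strength, convergence flags, comparator warnings).
    """

    method: str
    beta: np.ndarray
    se: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    level: float = 0.95
    scale: str = "linear"
    n_variants: int = 0
    exposure_names: list[str] = field(default_factory=list)
    diagnostics: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(f"unknown method {self.method!r}")
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.se = np.atleast_1d(np.asarray(self.se, dtype=float))
        self.ci_lower = np.atleast_1d(np.asarray(self.ci_lower, dtype=float))
        self.ci_upper = np.atleast_1d(np.asarray(self.ci_upper, dtype=float))
        K = self.beta.shape[0]
        for name, arr in (("se", self.se), ("ci_lower", self.ci_lower),
                          ("ci_upper", self.ci_upper)):
            if arr.shape != (K,):
                raise ValidationError(f"{name} must have length K={K}")
        if np.any(self.se[np.isfinite(self.se)] < 0):
            raise ValidationError("standard errors must be non-negative")
        if not self.exposure_names:
            self.exposure_names = [f"x{k + 1}" for k in range(K)]
        ok = np.isfinite(self.beta)
        if np.any(self.ci_lower[ok] - 1e-12 > self.beta[ok]) or np.any(
            self.beta[ok] > self.ci_upper[ok] + 1e-12
        ):
            raise ValidationError("interval endpoints must bracket the estimates")

    @property
    def n_exposures(self) -> int:
        return self.beta.shape[0]

    def to_dict(self) -> dict[str, Any]:
        """JSON-ready representation with schema version and provenance."""
        diag = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.diagnostics.items()}
        return {
            "schema_version": 1,
            "method": self.method,
            "exposures": list(self.exposure_names),
            "beta": self.beta.tolist(),
            "se": self.se.tolist(),
            "ci_lower": self.ci_lower.tolist(),
            "ci_upper": self.ci_upper.tolist(),
            "level": self.level,
            "scale": self.scale,
            "n_variants": self.n_variants,
            "diagnostics": diag,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "CausalEstimates":
        return cls(
            method=d["method"],
            beta=np.asarray(d["beta"], float),
            se=np.asarray(d["se"], float),
            ci_lower=np.asarray(d["ci_lower"], float),
            ci_upper=np.asarray(d["ci_upper"], float),
            level=d.get("level", 0.95),
            scale=d.get("scale", "linear"),
            n_variants=d.get("n_variants", 0),
            exposure_names=d.get("exposures", []),
            diagnostics=d.get("diagnostics", {}),
        )


def wald_interval(beta: np.ndarray, se: np.ndarray, level: float) -> tuple[np.ndarray, np.ndarray]:
    z = stats.norm.ppf(0.5 + level / 2)
    return beta - z * se, beta + z * se


def _with_intercept(mat: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(mat.shape[0]), mat])


def first_stage_strength(data: IndividualDataset) -> tuple[np.ndarray, np.ndarray, bool]:
    """Per-exposure (R^2, F) from regressing each risk factor on all variants.

    F = ((n - J - 1) / J) * R^2 / (1 - R^2).  A perfect fit reports +inf.
    Returns (r2, f, rank_deficient_flag); a rank-deficient genotype design is
    handled by the least-squares pseudo-inverse and flagged.
    """
    n, J = data.genotypes.shape
    if n <= J + 1:
        raise ValidationError("need n > J+1 subjects for first-stage F statistics")
    Z = _with_intercept(data.genotypes)
    rank_deficient = np.linalg.matrix_rank(Z) < Z.shape[1]
    coef, *_ = np.linalg.lstsq(Z, data.exposures, rcond=None)
    fitted = Z @ coef
    resid = data.exposures - fitted
    tss = ((data.exposures - data.exposures.mean(axis=0)) ** 2).sum(axis=0)
    rss = (resid**2).sum(axis=0)
    r2 = np.where(tss > 0, 1 - rss / tss, 0.0)
    with np.errstate(divide="ignore"):
        f = ((n - J - 1) / J) * r2 / (1 - r2)
    f = np.where(np.isclose(r2, 1.0, atol=1e-12), np.inf, f)
    return r2, f, bool(rank_deficient)


def _tsls(y: np.ndarray, regressors: np.ndarray, instruments: np.ndarray,
          robust: bool = False) -> tuple[np.ndarray, np.ndarray, float]:
    """Generic 2SLS solve.

    ``regressors`` and ``instruments`` both include their intercept columns.
    Returns (coef, cov, sigma2) where cov uses the IV-corrected residuals
    y - regressors @ coef (original regressors, not projections).
    """
    n = y.shape[0]
    p = regressors.shape[1]
    proj_coef, *_ = np.linalg.lstsq(instruments, regressors, rcond=None)
    fitted = instruments @ proj_coef
    if np.linalg.matrix_rank(fitted) < p:
        raise IdentificationError(
            "first-stage fitted-value matrix is rank deficient; the causal "
            "effects are not separately identified (check J >= K and "
            "instrument collinearity)"
        )
    wtw = fitted.T @ fitted
    coef = np.linalg.solve(wtw, fitted.T @ y)
    resid = y - regressors @ coef
    dof = n - p
    if dof <= 0:
        raise ValidationError("sample too small for 2SLS degrees of freedom")
    sigma2 = float(resid @ resid) / dof
    bread = np.linalg.inv(wtw)
    if robust:
        meat = fitted.T @ (fitted * (resid**2)[:, None])
        cov = bread @ meat @ bread
    else:
        cov = sigma2 * bread
    return coef, cov, sigma2


def fit_2sls(data: IndividualDataset, level: float = 0.95,
             robust: bool = False) -> CausalEstimates:
    """Multivariable 2SLS estimate of the K direct causal effects.

    Valid whether or not the instruments are in linkage disequilibrium.
    Requires at least as many instruments as risk factors (J >= K);
    J == K is the just-identified case and is allowed.
    """
    n, J = data.genotypes.shape
    K = data.n_exposures
    if J < K:
        raise IdentificationError(
            f"J={J} instruments cannot identify K={K} causal effects"
        )
    if n <= J + K + 1:
        raise ValidationError(f"n={n} too small for J={J} instruments and K={K} exposures")
    regressors = _with_intercept(data.exposures)
    instruments = _with_intercept(data.genotypes)
    coef, cov, sigma2 = _tsls(data.outcome, regressors, instruments, robust=robust)
    # IV residual dof convention: n - K - 1 for the structural equation
    beta = coef[1:]
    se = np.sqrt(np.diag(cov)[1:])
    lo, hi = wald_interval(beta, se, level)
    r2, f, rank_flag = first_stage_strength(data)
    return CausalEstimates(
        method="twostage",
        beta=beta, se=se, ci_lower=lo, ci_upper=hi, level=level,
        scale="linear", n_variants=J, exposure_names=list(data.exposure_names),
        diagnostics={
            "first_stage_r2": r2,
            "first_stage_f": f,
            "rank_deficient_instruments": rank_flag,
            "residual_variance": sigma2,
            "robust_se": robust,
        },
    )


def fit_sequential_adjustment(data: IndividualDataset, level: float = 0.95) -> CausalEstimates:
    """Single-exposure IV fits with the other risk factors as covariates.

    For each risk factor k in turn, the outcome is regressed on risk factor k
    (instrumented by all J variants) with the remaining K-1 risk factors
    entered as exogenous covariates in both stages — treating them as if they
    were confounders.  This "sequential adjustment" is a known-biased
    comparator: when the adjusted-for risk factors are themselves caused by
    the confounders, conditioning on them opens non-causal paths and the
    estimates are biased even under the null, in a direction set by the
    unknown confounders.
    """
    n, J = data.genotypes.shape
    K = data.n_exposures
    if J < 1:
        raise IdentificationError("at least one instrument required")
    if n <= J + K + 1:
        raise ValidationError(f"n={n} too small for J={J} instruments and K={K} exposures")
    beta = np.empty(K)
    se = np.empty(K)
    for k in range(K):
        others = np.delete(data.exposures, k, axis=1)
        regressors = _with_intercept(np.column_stack([data.exposures[:, k], others]))
        instruments = _with_intercept(np.column_stack([data.genotypes, others]))
        coef, cov, _ = _tsls(data.outcome, regressors, instruments)
        beta[k] = coef[1]
        se[k] = np.sqrt(cov[1, 1])
    lo, hi = wald_interval(beta, se, level)
    return CausalEstimates(
        method="sequential_adjustment",
        beta=beta, se=se, ci_lower=lo, ci_upper=hi, level=level,
        scale="linear", n_variants=J, exposure_names=list(data.exposure_names),
        diagnostics={
            "comparator": "sequential adjustment treats co-risk-factors as "
                          "confounders; biased under confounding, provided "
                          "for comparison only"
        },
    )
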
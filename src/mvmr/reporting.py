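"""Diagnostics and result reporting.

Two diagnostics accompany the estimators:

* :func:`risk_score` — an unmeasured-pleiotropy check.  Each variant's
  predicted outcome association is the sum over risk factors of its genetic
  association times the estimated causal effect.  If the causal model holds
  for every variant, the observed outcome betas scatter around these scores
  with slope one; a variant whose standardized residual is large is a
  candidate for an unmodelled direct pathway.
* :func:`correlation_sensitivity` — the trait-correlation parameters of the
  summarized-data likelihood are usually not estimable from the summary
  statistics themselves, so the estimator is refit over a grid of plausible
  settings and the spread of the estimates is reported.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .estimators_individual import CausalEstimates
from .estimators_summary import fit_likelihood_ml, fit_regression_based
from .summary_data import SummaryAssociations, TraitCorrelationModel

__all__ = [
    "RiskScoreTable",
    "SensitivityGrid",
    "risk_score",
    "correlation_sensitivity",
    "estimates_to_json",
    "estimates_from_json",
]

logger = logging.getLogger(__name__)


@dataclass
class RiskScoreTable:
    """Per-variant predicted scores, observed outcome betas and residuals.

    ``slope`` is from the inverse-variance weighted regression of the
    observed outcome betas on the scores through the origin; a value near 1
    indicates the estimated causal effects are consistent across variants.
    """

    table: pd.DataFrame
    slope: float
    slope_se: float
    outliers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        resid = self.table["beta_outcome"] - self.table["score"]
        if not np.allclose(resid, self.table["residual"]):
            raise ValidationError("residual must equal observed minus score exactly")


def risk_score(assoc: SummaryAssociations, estimates: CausalEstimates) -> RiskScoreTable:
    """Predicted-vs-observed outcome association diagnostic.

    score_j = sum_k beta_exposures[j, k] * beta_hat_k (units of the outcome
    scale).  Variants with |residual / se_outcome| > 3 are flagged as
    outliers, the pattern expected of a variant with an unmeasured direct
    effect on the outcome.
    """
    if estimates.n_exposures != assoc.n_exposures:
        raise ValidationError(
            f"estimates cover {estimates.n_exposures} risk factors, "
            f"summary data have {assoc.n_exposures}"
        )
    score = assoc.beta_exposures @ estimates.beta
    residual = assoc.beta_outcome - score
    std_resid = residual / assoc.se_outcome
    w = 1.0 / assoc.se_outcome**2
    denom = float(np.sum(w * score**2))
    if denom > 0:
        slope = float(np.sum(w * score * assoc.beta_outcome) / denom)
        slope_se = float(np.sqrt(1.0 / denom))
    else:
        slope, slope_se = np.nan, np.nan
    table = pd.DataFrame({
        "variant": assoc.variant_ids,
        "score": score,
        "beta_outcome": assoc.beta_outcome,
        "se_outcome": assoc.se_outcome,
        "residual": residual,
        "standardized_residual": std_resid,
        "outlier": np.abs(std_resid) > 3,
    })
    outliers = table.loc[table["outlier"], "variant"].tolist()
    return RiskScoreTable(table=table, slope=slope, slope_se=slope_se, outliers=outliers)


@dataclass
class SensitivityGrid:
    """Estimates refit across a grid of trait-correlation settings."""

    settings: list[TraitCorrelationModel]
    estimates: list[CausalEstimates]
    max_abs_deviation: np.ndarray
    skipped: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.settings) != len(self.estimates):
            raise ValidationError("one estimate set required per grid point")


def correlation_sensitivity(
    assoc: SummaryAssociations,
    grid: Iterable[TraitCorrelationModel | np.ndarray],
    method: str = "likelihood",
    estimator: Callable[..., CausalEstimates] | None = None,
    **options: Any,
) -> SensitivityGrid:
    """Refit the chosen summarized-data estimator at each correlation setting.

    Invalid grid points (non-PSD matrices, estimator failures) are skipped
    with a logged reason; ``max_abs_deviation`` is the per-coefficient
    spread (max minus min) of the estimates across the valid points.
    """
    if estimator is None:
        if method == "likelihood":
            estimator = fit_likelihood_ml
        elif method == "regression":
            # trait correlations do not enter the regression-based method;
            # accepted for interface symmetry
            estimator = lambda a, tc, **kw: fit_regression_based(a, **kw)  # noqa: E731
        else:
            raise ValidationError(f"unknown sensitivity method {method!r}")
    settings: list[TraitCorrelationModel] = []
    estimates: list[CausalEstimates] = []
    skipped: list[tuple[int, str]] = []
    for i, point in enumerate(grid):
        try:
            tc = point if isinstance(point, TraitCorrelationModel) else TraitCorrelationModel(
                np.asarray(point, dtype=float)
            )
            est = estimator(assoc, tc, **options)
        except Exception as exc:  # noqa: BLE001 - skip-and-log contract
            logger.warning("sensitivity grid point %d skipped: %s", i, exc)
            skipped.append((i, str(exc)))
            continue
        settings.append(tc)
        estimates.append(est)
    if not estimates:
        raise ValidationError("no valid grid points in sensitivity analysis")
    betas = np.vstack([e.beta for e in estimates])
    deviation = betas.max(axis=0) - betas.min(axis=0)
    return SensitivityGrid(settings=settings, estimates=estimates,
                           max_abs_deviation=deviation, skipped=skipped)


def estimates_to_json(estimates: CausalEstimates, path) -> None:
    with open(path, "w") as fh:
        json.dump(estimates.to_dict(), fh, indent=2)


def estimates_from_json(path) -> CausalEstimates:
    with open(path) as fh:
        return CausalEstimates.from_dict(json.load(fh))
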
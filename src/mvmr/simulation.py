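"""Monte-Carlo machinery for validating the multivariable MR estimators.

The data-generating model mirrors a lipid-fractions setting: J independent
biallelic variants (binomial allele counts), K risk factors each built from
an additive genetic component, shared standard-normal confounders, optional
causal effects between risk factors, and a linear outcome.  With K = 3 the
confounder wiring is the leave-one-out pattern: risk factor k receives every
confounder except its own (u_k loads on the other risk factors and on the
outcome), which induces correlation between the risk factors and the outcome
without giving any variant a direct path to the outcome.

Scenario execution produces tidy Monte-Carlo summaries (mean estimate, mean
SE, empirical SD, power at a nominal significance level) for any subset of
the estimators, together with Monte-Carlo standard errors, and helpers build
the standard scenario grids: the 8 confounder-sign scenarios and the 9-point
grid of causal effects between risk factors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, ValidationError
from .estimators_individual import (
    CausalEstimates,
    first_stage_strength,
    fit_2sls,
    fit_sequential_adjustment,
)
from .estimators_summary import fit_likelihood_ml, fit_regression_based
from .summary_data import (
    IndividualDataset,
    TraitCorrelationModel,
    estimate_trait_correlations,
    summarize,
)

__all__ = [
    "SimulationScenario",
    "ScenarioResult",
    "default_genetic_effects",
    "r2_for_f",
    "leave_one_out_confounding",
    "simulate_dataset",
    "run_scenario",
    "scenario_grid",
    "confounder_sign_grid",
    "exposure_dependence_grid",
    "instrument_strength",
    "total_effect",
]

logger = logging.getLogger(__name__)

#: Internal seed fixing the shipped synthetic genetic-effect pattern.
_FIXTURE_SEED = 715


def r2_for_f(f: float, n: int, J: int) -> float:
    """First-stage R^2 implied by a target F statistic at sample size n.

    Inverts F = ((n - J - 1)/J) * R^2 / (1 - R^2).
    """
    x = f * J / (n - J - 1)
    return x / (1 + x)


def leave_one_out_confounding(effects: Sequence[float]) -> np.ndarray:
    """K x K confounder-loading matrix from the K per-confounder effects.

    Entry (k, l) is the effect of confounder l on risk factor k; the
    diagonal is structurally zero (confounder k skips risk factor k).
    """
    v = np.asarray(effects, dtype=float)
    K = v.shape[0]
    mat = np.tile(v, (K, 1))
    np.fill_diagonal(mat, 0.0)
    return mat


def default_genetic_effects(
    J: int = 28,
    K: int = 3,
    maf: float = 0.3,
    target_r2: Sequence[float] = (0.006, 0.005, 0.032),
    nongenetic_variance: float = 1.18,
    sample_size_for_r2: int | None = 30_000,
    seed: int = _FIXTURE_SEED,
) -> np.ndarray:
    """Synthetic J x K matrix of per-allele genetic effects.

    The pattern is a fixed, seeded draw of pleiotropic effects (every
    variant may load on several risk factors), with each column rescaled so
    the aggregate first-stage R^2 for its risk factor matches ``target_r2``
    given ``nongenetic_variance`` of confounder-plus-noise variance.  When
    ``sample_size_for_r2`` is given, the targets are interpreted as the
    expected SAMPLE R^2 from a J-regressor fit at that sample size (the
    quantity instrument-strength tables report), which exceeds the
    population R^2 by roughly (1 - R^2) * J/(n-1); the population value is
    back-corrected accordingly.  The defaults reproduce instrument
    strengths typical of lipid genetics: aggregate R^2 of 0.6%, 0.5% and
    3.2% across the three risk factors (weak, weak, strong), i.e. mean
    first-stage F near 6.6, 5.2 and 35.4 at n = 30,000.  This is a
    synthetic stand-in pattern; real per-variant effect sizes can be
    supplied directly on the scenario.
    """
    if len(target_r2) != K:
        raise ValidationError(f"target_r2 needs {K} entries, got {len(target_r2)}")
    if sample_size_for_r2 is not None:
        infl = J / (sample_size_for_r2 - 1)
        target_r2 = [(r - infl) / (1 - infl) for r in target_r2]
    rng = np.random.default_rng(seed)
    raw = rng.normal(size=(J, K))
    # sparsify mildly so some variants are trait-specific, most pleiotropic
    mask = rng.random((J, K)) < 0.85
    raw = np.where(mask, raw, 0.0)
    for k in range(K):
        if not np.any(raw[:, k]):
            raw[0, k] = 1.0
    var_per_unit = 2 * maf * (1 - maf)
    alpha = np.empty_like(raw)
    for k, r2 in enumerate(target_r2):
        if not (0 < r2 < 1):
            raise ValidationError(f"target_r2 entries must lie in (0,1), got {r2}")
        genetic_var = nongenetic_variance * r2 / (1 - r2)
        scale = np.sqrt(genetic_var / (var_per_unit * np.sum(raw[:, k] ** 2)))
        alpha[:, k] = raw[:, k] * scale
    return alpha


@dataclass
class SimulationScenario:
    """Full parameterisation of one simulated multivariable MR study.

    Defaults are the base study conditions: n = 30,000 subjects, J = 28
    variants with minor allele frequency 0.3, K = 3 risk factors with
    direct causal effects beta = (0.3, 0, -0.1), confounder effects of 0.3
    on the risk factors (leave-one-out pattern) and on the outcome, unit
    noise SDs, and no causal effects between risk factors.
    """

    n: int = 30_000
    J: int = 28
    K: int = 3
    maf: float = 0.3
    alpha_G: np.ndarray | None = None
    alpha_U: np.ndarray | None = None
    beta_U: np.ndarray | None = None
    beta: np.ndarray | None = None
    alpha_X: np.ndarray | None = None
    noise_sd: np.ndarray | None = None
    interaction_scale: float = 0.0
    reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.maf < 1):
            raise ValidationError(f"maf must lie in (0, 1), got {self.maf}")
        if self.alpha_G is None:
            self.alpha_G = default_genetic_effects(self.J, self.K, self.maf)
        self.alpha_G = np.asarray(self.alpha_G, dtype=float)
        if self.alpha_G.shape != (self.J, self.K):
            raise ValidationError(
                f"alpha_G must be {self.J}x{self.K}, got {self.alpha_G.shape}"
            )
        if self.alpha_U is None:
            self.alpha_U = leave_one_out_confounding([0.3] * self.K)
        self.alpha_U = np.asarray(self.alpha_U, dtype=float)
        if self.alpha_U.shape != (self.K, self.K):
            raise ValidationError(f"alpha_U must be {self.K}x{self.K}")
        if np.any(np.diag(self.alpha_U) != 0):
            raise ValidationError("alpha_U must have structural zeros on the diagonal")
        self.beta_U = np.asarray(
            [0.3] * self.K if self.beta_U is None else self.beta_U, dtype=float
        )
        default_beta = [0.3, 0.0, -0.1][: self.K] + [0.0] * max(0, self.K - 3)
        self.beta = np.asarray(default_beta if self.beta is None else self.beta,
                               dtype=float)
        if self.alpha_X is None:
            self.alpha_X = np.zeros((self.K, self.K))
        self.alpha_X = np.asarray(self.alpha_X, dtype=float)
        if self.alpha_X.shape != (self.K, self.K):
            raise ValidationError(f"alpha_X must be {self.K}x{self.K}")
        _topological_order(self.alpha_X)  # raises on cycles
        self.noise_sd = np.asarray(
            [1.0] * (self.K + 1) if self.noise_sd is None else self.noise_sd,
            dtype=float,
        )
        if self.beta_U.shape != (self.K,) or self.beta.shape != (self.K,):
            raise ValidationError("beta_U and beta must have length K")
        if self.noise_sd.shape != (self.K + 1,) or np.any(self.noise_sd <= 0):
            raise ValidationError("noise_sd must be K+1 positive values")
        if self.reps < 1:
            raise ValidationError("reps must be at least 1")


def _topological_order(alpha_X: np.ndarray) -> list[int]:
    """Kahn's algorithm over the risk-factor dependence graph.

    Edge l -> k exists when alpha_X[k, l] != 0 (risk factor l feeds into k).
    Raises on cycles.
    """
    K = alpha_X.shape[0]
    indeg = [int(np.count_nonzero(alpha_X[k])) for k in range(K)]
    children = {l: [k for k in range(K) if alpha_X[k, l] != 0] for l in range(K)}
    queue = [k for k in range(K) if indeg[k] == 0]
    order: list[int] = []
    while queue:
        l = queue.pop()
        order.append(l)
        for k in children[l]:
            indeg[k] -= 1
            if indeg[k] == 0:
                queue.append(k)
    if len(order) != K:
        raise ValidationError("alpha_X encodes a cyclic dependence between risk factors")
    return order


def simulate_dataset(
    scenario: SimulationScenario,
    replicate_seed: int | np.random.SeedSequence | None = None,
) -> IndividualDataset:
    """Draw one individual-level dataset from the generating model.

    Genotypes are i.i.d. Binomial(2, maf); confounders and noise are
    standard normal.  Risk factors are evaluated in dependency order so
    downstream factors receive the causal contributions of upstream ones;
    the outcome is linear in confounders and risk factors.  Fully
    reproducible given a seed.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed if replicate_seed is None else replicate_seed)
    n, J, K = sc.n, sc.J, sc.K
    g = rng.binomial(2, sc.maf, size=(n, J)).astype(float)
    u = rng.standard_normal((n, K))
    eps_x = rng.standard_normal((n, K))
    eps_y = rng.standard_normal(n)

    genetic = g @ sc.alpha_G  # (n, K)
    if sc.interaction_scale != 0.0:
        # misspecification probe: pairwise genotype products entering the
        # risk factors, violating the additive-in-variants analysis model
        n_pairs = min(3, J // 2)
        inter = np.zeros(n)
        for t in range(n_pairs):
            prod = g[:, 2 * t] * g[:, 2 * t + 1]
            inter += prod - (2 * sc.maf) ** 2
        genetic = genetic + sc.interaction_scale * inter[:, None]

    x = np.zeros((n, K))
    for k in _topological_order(sc.alpha_X):
        x[:, k] = (
            genetic[:, k]
            + u @ sc.alpha_U[k]
            + x @ sc.alpha_X[k]
            + sc.noise_sd[k] * eps_x[:, k]
        )
    y = u @ sc.beta_U + x @ sc.beta + sc.noise_sd[K] * eps_y
    return IndividualDataset(genotypes=g, exposures=x, outcome=y)


@dataclass
class ScenarioResult:
    """Tidy Monte-Carlo summary of one scenario.

    ``table`` has one row per method x coefficient with columns
    mean_estimate, mean_se, sd_estimates, power_pct, mcse_mean,
    mcse_power_pct; power is 100 x the share of replicates whose Wald
    statistic exceeds the nominal critical value, and its Monte-Carlo SE is
    the binomial sqrt(p(1-p)/reps).
    """

    table: pd.DataFrame
    reps_completed: int
    failures: dict[str, int]
    seed: int
    scenario: SimulationScenario | None = None

    def __post_init__(self) -> None:
        p = self.table["power_pct"].to_numpy()
        if np.any((p < 0) | (p > 100)):
            raise ValidationError("power must lie in [0, 100] percent")


_INDIVIDUAL_METHODS = {"twostage", "sequential"}
_SUMMARY_METHODS = {"likelihood", "regression"}


def _two_sample_corr(corr_one: TraitCorrelationModel) -> TraitCorrelationModel:
    """Zero the exposure-outcome correlations (separate outcome sample)."""
    m = corr_one.corr.copy()
    m[-1, :-1] = 0.0
    m[:-1, -1] = 0.0
    return TraitCorrelationModel(m, trait_names=list(corr_one.trait_names))


def run_scenario(
    scenario: SimulationScenario,
    methods: Iterable[str] = ("twostage",),
    level: float = 0.95,
    two_sample: bool = False,
    estimator_options: dict[str, dict[str, Any]] | None = None,
) -> ScenarioResult:
    """Monte-Carlo evaluation of the requested estimators on one scenario.

    Methods: ``twostage``, ``sequential`` (individual-level), ``likelihood``,
    ``regression`` (applied to the per-replicate summarized data, with trait
    correlations re-estimated inside each replicate).  In two-sample mode
    the outcome associations are taken from an independent second dataset of
    the same scenario and the exposure-outcome beta correlations are set to
    zero.  Replicates where an estimator fails are logged and excluded from
    that estimator's averages, with the exclusion count reported.
    """
    methods = list(dict.fromkeys(methods))
    if not methods:
        raise ConfigurationError("at least one method is required")
    unknown = set(methods) - _INDIVIDUAL_METHODS - _SUMMARY_METHODS
    if unknown:
        raise ConfigurationError(f"unknown methods: {sorted(unknown)}")
    if scenario.reps < 2:
        raise ValidationError("Monte-Carlo summaries require reps >= 2")
    opts = estimator_options or {}
    K = scenario.K
    z_crit = stats.norm.ppf(0.975)

    estimates: dict[str, list[np.ndarray]] = {m: [] for m in methods}
    ses: dict[str, list[np.ndarray]] = {m: [] for m in methods}
    failures = {m: 0 for m in methods}

    for r in range(scenario.reps):
        data = simulate_dataset(scenario, np.random.SeedSequence(
            entropy=scenario.seed, spawn_key=(r, 0)))
        assoc = corr = None
        if any(m in _SUMMARY_METHODS for m in methods):
            assoc = summarize(data)
            corr = estimate_trait_correlations(data)
            if two_sample:
                data2 = simulate_dataset(scenario, np.random.SeedSequence(
                    entropy=scenario.seed, spawn_key=(r, 1)))
                assoc2 = summarize(data2)
                assoc = replace_outcome(assoc, assoc2)
                corr = _two_sample_corr(corr)
        for m in methods:
            try:
                if m == "twostage":
                    est = fit_2sls(data, level=level, **opts.get(m, {}))
                elif m == "sequential":
                    est = fit_sequential_adjustment(data, level=level, **opts.get(m, {}))
                elif m == "likelihood":
                    est = fit_likelihood_ml(assoc, corr, level=level, **opts.get(m, {}))
                else:
                    est = fit_regression_based(assoc, level=level, **opts.get(m, {}))
            except Exception as exc:  # noqa: BLE001 - failures counted, never averaged
                failures[m] += 1
                logger.warning("replicate %d: %s failed: %s", r, m, exc)
                continue
            estimates[m].append(est.beta)
            ses[m].append(est.se)

    rows = []
    for m in methods:
        est_mat = np.asarray(estimates[m])
        se_mat = np.asarray(ses[m])
        reps_m = est_mat.shape[0]
        if reps_m < 2:
            raise ValidationError(f"method {m!r} succeeded in fewer than 2 replicates")
        rej = (np.abs(est_mat / se_mat) > z_crit).mean(axis=0)
        for k in range(K):
            p = rej[k]
            rows.append({
                "method": m,
                "coefficient": f"beta_{k + 1}",
                "true_value": scenario.beta[k],
                "mean_estimate": est_mat[:, k].mean(),
                "mean_se": se_mat[:, k].mean(),
                "sd_estimates": est_mat[:, k].std(ddof=1),
                "power_pct": 100 * p,
                "mcse_mean": est_mat[:, k].std(ddof=1) / np.sqrt(reps_m),
                "mcse_power_pct": 100 * np.sqrt(p * (1 - p) / reps_m),
                "reps_used": reps_m,
                "failures": failures[m],
            })
    return ScenarioResult(
        table=pd.DataFrame(rows),
        reps_completed=scenario.reps,
        failures=failures,
        seed=scenario.seed,
        scenario=scenario,
    )


def replace_outcome(assoc_exposures, assoc_outcome):
    """Exposure associations from one sample, outcome from another."""
    from dataclasses import replace as _dc_replace

    return _dc_replace(
        assoc_exposures,
        beta_outcome=assoc_outcome.beta_outcome.copy(),
        se_outcome=assoc_outcome.se_outcome.copy(),
    )


# ---------------------------------------------------------------------------
# scenario grids
# ---------------------------------------------------------------------------

_VIRTUAL_AXES = ("alpha_u", "alpha_x_on_first")


def scenario_grid(
    base: SimulationScenario, axis: str, values: Iterable[Any]
) -> list[SimulationScenario]:
    """Vary one scenario parameter over ``values``.

    ``axis`` is either a scenario field name, or one of the virtual axes:
    ``alpha_u`` (a K-vector of per-confounder effects expanded to the
    leave-one-out matrix) and ``alpha_x_on_first`` (a pair of effects of the
    second and third risk factors on the first).
    """
    field_names = {f.name for f in SimulationScenario.__dataclass_fields__.values()}  # type: ignore[attr-defined]
    if axis not in field_names and axis not in _VIRTUAL_AXES:
        raise ConfigurationError(
            f"unknown scenario axis {axis!r}; valid: {sorted(field_names) + list(_VIRTUAL_AXES)}"
        )
    out = []
    for v in values:
        if axis == "alpha_u":
            out.append(replace(base, alpha_U=leave_one_out_confounding(v)))
        elif axis == "alpha_x_on_first":
            a2, a3 = v
            ax = np.zeros((base.K, base.K))
            ax[0, 1], ax[0, 2] = a2, a3
            out.append(replace(base, alpha_X=ax))
        else:
            out.append(replace(base, **{axis: v}))
    return out


def confounder_sign_grid(
    base: SimulationScenario, magnitude: float = 0.3
) -> list[SimulationScenario]:
    """The 8 scenarios with each confounder effect at +/- ``magnitude``."""
    signs = [(s1, s2, s3) for s1 in (1, -1) for s2 in (1, -1) for s3 in (1, -1)]
    values = [tuple(magnitude * s for s in combo) for combo in signs]
    return scenario_grid(base, "alpha_u", values)


def exposure_dependence_grid(
    base: SimulationScenario, magnitude: float = 0.5
) -> list[SimulationScenario]:
    """The 9 settings of the effects of risk factors 2 and 3 on risk factor 1.

    Rows: (0,0), (m,0), (-m,0), (0,m), (0,-m), (m,m), (-m,m), (m,-m), (-m,-m).
    """
    m = magnitude
    values = [(0, 0), (m, 0), (-m, 0), (0, m), (0, -m),
              (m, m), (-m, m), (m, -m), (-m, -m)]
    return scenario_grid(base, "alpha_x_on_first", values)


def instrument_strength(data: IndividualDataset) -> pd.DataFrame:
    """Per-risk-factor instrument strength: R^2 and F over all J variants.

    R^2 is from the multiple regression of the risk factor on all variants
    with intercept; F = ((n - J - 1)/J) * R^2/(1 - R^2).  A rank-deficient
    genotype design is handled by pseudo-inverse and flagged in the
    ``rank_deficient`` column.
    """
    r2, f, rank_flag = first_stage_strength(data)
    return pd.DataFrame({
        "exposure": list(data.exposure_names),
        "r_squared": r2,
        "f_statistic": f,
        "rank_deficient": rank_flag,
    })


def total_effect(beta_direct: Sequence[float], alpha_X: np.ndarray) -> np.ndarray:
    """Total causal effect of each risk factor on the outcome.

    Sums the direct effect and every directed path through the other risk
    factors: with A[k, l] the effect of risk factor l on risk factor k, the
    total-effect vector t solves t = beta + A' t, i.e. t = (I - A')^{-1} beta,
    a finite path expansion because the dependence graph is acyclic.
    """
    beta = np.asarray(beta_direct, dtype=float)
    A = np.asarray(alpha_X, dtype=float)
    K = beta.shape[0]
    if A.shape != (K, K):
        raise ValidationError(f"alpha_X must be {K}x{K}, got {A.shape}")
    _topological_order(A)  # raises on cycles
    return np.linalg.solve(np.eye(K) - A.T, beta)
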
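import numpy as np
import pytest

from mvmr import (
    SimulationScenario,
    SummaryAssociations,
    TraitCorrelationModel,
    default_genetic_effects,
    r2_for_f,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """Seeded individual-level dataset: n=200, J=3 variants, K=2 exposures."""
    rng = np.random.default_rng(42)
    n = 200
    g = rng.binomial(2, 0.3, size=(n, 3)).astype(float)
    x = 0.5 * g[:, :2] + rng.standard_normal((n, 2))
    y = 0.7 * x[:, 0] - 0.2 * x[:, 1] + rng.standard_normal(n)
    from mvmr import IndividualDataset

    return IndividualDataset(genotypes=g, exposures=x, outcome=y)


def strong_scenario(n=5000, reps=2, seed=0, f=50.0, **kw):
    """Base-study scenario rescaled so every first-stage F is around ``f``."""
    r2 = [r2_for_f(f, n, 28)] * 3
    alpha_G = default_genetic_effects(28, 3, 0.3, target_r2=r2, sample_size_for_r2=n)
    return SimulationScenario(n=n, reps=reps, seed=seed, alpha_G=alpha_G, **kw)


@pytest.fixture(scope="session")
def strong_replicate():
    """One strong-instrument replicate of the generating model."""
    sc = strong_scenario(n=5000, seed=7)
    return simulate_dataset(sc, 7)


def simulate_summary_data(xi, beta, se_x, se_y, trait_corr, seed):
    """Draw observed betas directly from the summarized-data model.

    Per variant j the (K+1)-vector of observed betas is multivariate normal
    around (xi_j, beta . xi_j) with the stated covariance — the model the
    likelihood estimators assume, used for parameter-recovery checks.
    """
    rng = np.random.default_rng(seed)
    xi = np.asarray(xi, float)
    beta = np.asarray(beta, float)
    J, K = xi.shape
    se_x = np.broadcast_to(np.asarray(se_x, float), (J, K))
    se_y = np.broadcast_to(np.asarray(se_y, float), (J,))
    bx = np.empty((J, K))
    by = np.empty(J)
    for j in range(J):
        sig = np.append(se_x[j], se_y[j])
        cov = trait_corr.corr * np.outer(sig, sig)
        mean = np.append(xi[j], xi[j] @ beta)
        draw = rng.multivariate_normal(mean, cov)
        bx[j], by[j] = draw[:K], draw[K]
    return SummaryAssociations(
        variant_ids=[f"v{j}" for j in range(J)],
        beta_exposures=bx, se_exposures=se_x.copy(),
        beta_outcome=by, se_outcome=se_y.copy(),
    )


@pytest.fixture(scope="session")
def recovery_summary():
    """J=28, K=3 summary dataset with known causal effects (0.3, 0, -0.1)."""
    rng = np.random.default_rng(11)
    xi = rng.normal(0.0, 0.2, size=(28, 3))
    beta = np.array([0.3, 0.0, -0.1])
    tc = TraitCorrelationModel.identity(3)
    assoc = simulate_summary_data(xi, beta, se_x=0.02, se_y=0.02, trait_corr=tc, seed=5)
    return assoc, xi, beta, tc
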
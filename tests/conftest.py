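import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import bandfec as bf

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# counts printed for dark-eyed juncos: bandings and same-season recaptures
JUNCO = dict(M_j=248_939, f2_j=45, M_a=107_998, f2_a=15)


@pytest.fixture(scope="session")
def junco_recaptures() -> bf.RecaptureSummary:
    return bf.RecaptureSummary.from_counts(
        JUNCO["M_j"], JUNCO["f2_j"], JUNCO["M_a"], JUNCO["f2_a"]
    )


@pytest.fixture(scope="session")
def junco_fit(junco_recaptures):
    """Time-constant fit of the recapture/age-composition components to the
    junco counts (shared across tests; seeded)."""
    model = bf.TagRecoveryModel(bf.BandingDataset(recaptures=junco_recaptures))
    return model.fit(bf.MCMCSettings(n_chains=3, n_iter=25_000, n_burn=5_000,
                                     thin=10, n_adapt=2_000, seed=1))


@pytest.fixture(scope="session")
def chao_study():
    """Scaled-down 24-year replicate study with the closed-form estimator."""
    from bandfec.simulate import SimConfig, run_study

    return run_study(SimConfig(n_replicates=150, seed=0), estimator="chao")


@pytest.fixture
def toy_marray() -> bf.MArray:
    # 2 cohorts, 3 occasions
    return bf.MArray(
        "adult",
        cohort_years=np.array([1, 2, 3]),
        releases=np.array([10, 8, 0]),
        recoveries=np.array([[1, 2, 0], [0, 3, 1], [0, 0, 0]]),
    )


def mcse(draws: np.ndarray) -> float:
    """Monte Carlo standard error of a posterior mean via arviz ESS."""
    import arviz as az

    ess = float(az.ess(az.convert_to_dataset(draws[None] if draws.ndim == 1 else draws))["x"])
    return float(draws.std(ddof=1) / np.sqrt(max(ess, 1.0)))
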
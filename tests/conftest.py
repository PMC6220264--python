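import numpy as np
import pytest

import edutwin as et
from edutwin.synthetic import achievement_cpm_params, achievement_simplex_params
from edutwin.twin_models import GroupCovariances, implied_covariance


@pytest.fixture(scope="session")
def ace_cohort():
    """Large single-occasion cohort at the a2=0.6, c2=0.2, e2=0.2 regime."""
    return et.simulate_ace(5000, 5000, et.ACEParams(0.6, 0.2, 0.2), seed=1)


@pytest.fixture(scope="session")
def simplex_params():
    return achievement_simplex_params()


@pytest.fixture(scope="session")
def cpm_params():
    return achievement_cpm_params()


@pytest.fixture(scope="session")
def simplex_cohort(simplex_params):
    return et.simulate_simplex(10000, 10000, simplex_params, seed=11)


@pytest.fixture(scope="session")
def genotype_panel():
    return et.simulate_genotypes(500, 2000, 0.05, 0.5, seed=7)


def exact_group_covariances(model, params, n=5000, labels=None):
    """GroupCovariances whose matrices equal the model-implied covariance
    exactly (the noiseless-inversion oracle input)."""
    covs = {g: implied_covariance(model, params, g) for g in ("MZ", "DZ")}
    p = next(iter(covs.values())).shape[0] // 2
    if labels is None:
        labels = [f"v{t + 1}" for t in range(p)]
    return GroupCovariances(covs=covs, ns={"MZ": n, "DZ": n}, labels=labels)


def wishart_group_covariances(model, params, n, seed, labels=None):
    """Sample covariances drawn from the Wishart distribution implied by the
    model: statistically equivalent to simulating n complete pairs per group
    without materializing individual rows."""
    from scipy import stats

    rng = np.random.default_rng(seed)
    covs = {}
    for g in ("MZ", "DZ"):
        sigma = implied_covariance(model, params, g)
        covs[g] = stats.wishart.rvs(df=n - 1, scale=sigma / (n - 1), random_state=rng)
    p = next(iter(covs.values())).shape[0] // 2
    if labels is None:
        labels = [f"v{t + 1}" for t in range(p)]
    return GroupCovariances(covs=covs, ns={"MZ": n, "DZ": n}, labels=labels)
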
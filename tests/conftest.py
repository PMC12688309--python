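import numpy as np
import pandas as pd
import pytest

from climmed import synthetic as syn


@pytest.fixture(scope="session")
def default_cohort():
    """Mid-sized cohort at the documented default coefficients."""
    cfg = syn.default_config(n_individuals=5000, seed=2024)
    provinces, cohort = syn.simulate_cohort(cfg)
    return cfg, provinces, cohort


@pytest.fixture(scope="session")
def large_cohort():
    """Large cohort for recovery checks."""
    cfg = syn.default_config(n_individuals=100_000, seed=7)
    provinces, cohort = syn.simulate_cohort(cfg)
    return cfg, provinces, cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_logistic_data(n, beta, seed, n_clusters=None, sigma2=0.0):
    """Simple logistic testbed: x ~ N(0,1), optional cluster intercepts."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    eta = beta[0] + beta[1] * x
    if n_clusters:
        g = rng.integers(0, n_clusters, n)
        u = rng.normal(0, np.sqrt(sigma2), n_clusters)
        eta = eta + u[g]
    else:
        g = np.zeros(n, dtype=int)
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    return pd.DataFrame({"x": x, "y": y, "cluster": g})
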
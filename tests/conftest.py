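import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from gceprofiler import generate_cohort, preset_spec


def simulate_clustered(n_clusters, n_per, sigma2, beta0=-1.0, slope=0.5,
                       seed=0, slope_sd=0.0):
    """Random-intercept logistic data with one standardized covariate.

    Returns (X DataFrame, y, groups, truth dict).  Optionally adds a
    cluster-level random slope on the covariate (slope_sd > 0).
    """
    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, np.sqrt(sigma2), n_clusters)
    b = rng.normal(0.0, slope_sd, n_clusters) if slope_sd > 0 else np.zeros(n_clusters)
    g = np.repeat(np.arange(n_clusters), n_per)
    x = rng.standard_normal(n_clusters * n_per)
    lp = beta0 + (slope + b[g]) * x + u[g]
    y = (rng.random(len(g)) < expit(lp)).astype(int)
    X = pd.DataFrame({"x": x})
    return X, y, g, {"u": u, "beta0": beta0, "slope": slope}


@pytest.fixture(scope="session")
def danish_cohort():
    return generate_cohort(preset_spec("danish_like"), seed=11)


@pytest.fixture(scope="session")
def swedish_cohort():
    return generate_cohort(preset_spec("swedish_like"), seed=11)


@pytest.fixture(scope="session")
def small_glmm():
    """A small clustered dataset (15 clusters) reused by the integration oracles."""
    return simulate_clustered(15, 25, 0.115, seed=42)
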
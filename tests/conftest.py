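import numpy as np
import pandas as pd
import pytest

from triarchy import cfa


@pytest.fixture(scope="session")
def cs_truth():
    """True parameters of a 'C+S' bifactor population model."""
    spec = cfa.model_library()["C+S"]
    L = np.zeros((9, 2))
    L[:, 0] = [0.5, 0.45, 0.4, 0.6, 0.65, 0.55, 0.5, 0.55, 0.6]
    L[6:, 1] = [0.5, 0.55, 0.45]
    theta = 1.0 - (L**2).sum(axis=1)
    return spec, L, theta


def simulate_cs_scores(L, theta, n, rng, missing_rate=0.0):
    f = rng.standard_normal((n, 2))
    X = f @ L.T + rng.standard_normal((n, 9)) * np.sqrt(theta)
    if missing_rate:
        X = np.where(rng.random(X.shape) < missing_rate, np.nan, X)
    return pd.DataFrame(X, columns=cfa.INDICATORS), f


@pytest.fixture(scope="session")
def cs_sample(cs_truth):
    spec, L, theta = cs_truth
    rng = np.random.default_rng(42)
    scores, f = simulate_cs_scores(L, theta, 2000, rng)
    return spec, L, theta, scores, f


@pytest.fixture(scope="session")
def small_genotypes():
    """A small linkage-equilibrium genotype panel with standardized dosages."""
    rng = np.random.default_rng(11)
    n, m = 500, 800
    p = rng.uniform(0.05, 0.5, m)
    dosages = rng.binomial(2, p, (n, m)).astype(float)
    W = (dosages - 2 * p) / np.sqrt(2 * p * (1 - p))
    return dosages, W, p
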
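import numpy as np
import pytest

from stratpca import (
    AlleleFreqModel,
    CovParams,
    PopulationLayout,
    freq_to_cov,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_freq_model(rng, K):
    """Random valid allele-frequency model (psi PSD, variance bound met)."""
    mu = rng.uniform(0.2, 0.8, K)
    B = rng.normal(size=(K, K))
    psi0 = B @ B.T + 1e-12 * np.eye(K)
    u = rng.uniform(0.05, 0.95, K)
    t = np.sqrt(u * mu * (1 - mu) / np.diag(psi0))
    return AlleleFreqModel(mu=mu, psi=psi0 * np.outer(t, t))


def random_params(rng, K):
    """Random raw covariance parameters, guaranteed PSD via the model route."""
    return freq_to_cov(random_freq_model(rng, K))


def random_layout(rng, K, max_per_pop=60):
    sizes = tuple(int(s) for s in rng.integers(1, max_per_pop + 1, K))
    return PopulationLayout(tuple(f"P{i + 1}" for i in range(K)), sizes)


@pytest.fixture
def table1():
    """Three populations with identical parameters, unbalanced sizes."""
    layout = PopulationLayout(("P1", "P2", "P3"), (5, 10, 100))
    params = CovParams(
        sigma2=[1.0, 1.0, 1.0], c=[0.8, 0.8, 0.8], d=np.full((3, 3), 0.1)
    )
    return layout, params


@pytest.fixture
def table2():
    """Five populations: P1-P3 closely related, P4 and P5 distant."""
    layout = PopulationLayout(("P1", "P2", "P3", "P4", "P5"),
                              (100, 110, 120, 130, 140))
    d = np.array(
        [
            [0.80, 0.70, 0.70, 0.10, 0.11],
            [0.70, 0.73, 0.70, 0.13, 0.14],
            [0.70, 0.70, 0.75, 0.14, 0.09],
            [0.10, 0.13, 0.14, 0.90, 0.17],
            [0.11, 0.14, 0.09, 0.17, 0.91],
        ]
    )
    params = CovParams(sigma2=np.ones(5), c=np.diag(d).copy(), d=d)
    return layout, params
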
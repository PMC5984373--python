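import numpy as np
import pytest

from nbid import CountMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240001)


@pytest.fixture
def small_matrix(rng):
    """50 genes x 20 cells NB matrix with heterogeneous means."""
    mus = rng.uniform(0.5, 10, 50)
    phis = rng.uniform(0.1, 1.0, 50)
    counts = rng.poisson(rng.gamma((1 / phis)[:, None], (mus * phis)[:, None], (50, 20)))
    return CountMatrix(
        counts,
        gene_ids=[f"g{i}" for i in range(50)],
        cell_ids=[f"c{j}" for j in range(20)],
    )


def nb_counts(rng, mu, phi, n):
    """Gamma-Poisson draw of n NB(mu, phi) counts."""
    if phi == 0:
        return rng.poisson(mu, n)
    return rng.poisson(rng.gamma(1.0 / phi, mu * phi, n))
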
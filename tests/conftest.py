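import numpy as np
import pytest

from adelle.covariance import LowRankCorrelation


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def equicorr50():
    """Equicorrelated 50-trait correlation (rho = 0.4) in factored form."""
    rho, d = 0.4, 50
    return LowRankCorrelation(np.full(d, 1 - rho),
                              np.full((d, 1), np.sqrt(rho)))


@pytest.fixture
def random_lowrank300():
    """A seeded random 300-trait diag+low-rank correlation."""
    r = np.random.default_rng(11)
    u = r.standard_normal((300, 12))
    u *= (np.sqrt(r.uniform(0.2, 0.7, 300)) / np.linalg.norm(u, axis=1))[:, None]
    return LowRankCorrelation(1 - np.einsum("ij,ij->i", u, u), u)
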
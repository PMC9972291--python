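import numpy as np
import pytest

from ipolng import CountMatrix, FactorConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def poisson_k1_fixture():
    """50 cells x 20 features drawn from a rank-1 Poisson model."""
    rng = np.random.default_rng(42)
    I, J = 50, 20
    theta = rng.dirichlet(np.ones(J) * 2)
    s = rng.integers(100, 400, I).astype(float)
    W = rng.poisson(s[:, None] * theta[None, :]).astype(float)
    return CountMatrix(W), theta, s


@pytest.fixture
def quick_cfg():
    return FactorConfig(K=3, epochs=200, seed=0)
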
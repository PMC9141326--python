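import numpy as np
import pytest

from metatempo import inference


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_state_model():
    """Uniform prior over two external states; informative binary likelihood."""
    return inference.DiscreteGenerativeModel(
        external_states=("e1", "e2"),
        blanket_states=("m1", "m2"),
        prior=np.array([0.5, 0.5]),
        likelihood=np.array([[0.9, 0.1], [0.2, 0.8]]),
    )


def random_model(rng: np.random.Generator, n_e: int = 3, n_m: int = 4) -> inference.DiscreteGenerativeModel:
    prior = rng.dirichlet(np.ones(n_e))
    likelihood = rng.dirichlet(np.ones(n_m), size=n_e)
    return inference.DiscreteGenerativeModel(
        external_states=tuple(range(n_e)),
        blanket_states=tuple(range(n_m)),
        prior=prior,
        likelihood=likelihood,
    )
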
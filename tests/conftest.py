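import numpy as np
import pytest

from fmblaw.io import generate_population


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def two_state_pop():
    """The hand-evaluable two-state population: q=(1/2,1/2), θ=(0,1), q'=(1/4,3/4)."""
    from fmblaw.price import Population

    return Population([0.5, 0.5], [[0.0], [1.0]], updated_weights=[0.25, 0.75])


def random_population(seed, m=30, n=3, delta_model="w_correlated"):
    """Seeded random population with nontrivial selection and transmission."""
    gen = np.random.default_rng(seed)
    return generate_population(m, n, gen, fitness_model="linear", noise=0.3,
                               delta_model=delta_model)
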
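import numpy as np
import pytest

from coext import synthetic
from coext.network_io import BipartiteNetwork


@pytest.fixture
def perfect_matching4():
    return synthetic.perfect_matching(4)


@pytest.fixture
def star5():
    return synthetic.star(5)


@pytest.fixture
def two_component():
    return synthetic.two_component()


@pytest.fixture
def nested_triangle():
    return synthetic.nested_triangle()


@pytest.fixture(scope="session")
def ac_like():
    return synthetic.ac_like()


@pytest.fixture
def small_random():
    """P=5, A=7 uniform fixture used for enumeration-scale checks."""
    return synthetic.generate(
        synthetic.GeneratorSpec(n_plants=5, n_animals=7, n_edges=16, seed=3)
    )


@pytest.fixture
def weighted_toy():
    """3 animals x 2 plants with distinctive integer weights."""
    M = np.array([[9.0, 1.0], [2.0, 2.0], [0.0, 5.0]])
    return BipartiteNetwork(["a1", "a2", "a3"], ["p1", "p2"], M, weighted=True)


def random_network(rng, max_side=6, weighted=False):
    """Small random valid network for property-style loops."""
    A = int(rng.integers(1, max_side + 1))
    P = int(rng.integers(1, max_side + 1))
    E = int(rng.integers(max(A, P), A * P + 1))
    spec = synthetic.GeneratorSpec(
        n_plants=P,
        n_animals=A,
        n_edges=E,
        weight_model=synthetic.GEOMETRIC if weighted else synthetic.UNIT,
        seed=int(rng.integers(0, 2**31)),
    )
    return synthetic.generate(spec)
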
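import numpy as np
import pytest

from markovselect import Alphabet, TrajectorySet, count_transitions, free_throw_example


@pytest.fixture(scope="session")
def worked():
    """The two-game free-throw example: J=2, lengths 7 and 11."""
    return free_throw_example()


@pytest.fixture(scope="session")
def worked_h1(worked):
    return count_transitions(worked, 1)


@pytest.fixture(scope="session")
def worked_h0(worked):
    return count_transitions(worked, 0)


def random_fixture(rng: np.random.Generator):
    """A random small trajectory set plus an order and a prior choice.

    Sizes J<=5, L<=12, M<=3, h<=2, alpha in {1, 1/2}: small enough that
    the urn oracles in tests/_oracles.py are instant.
    """
    M = int(rng.integers(2, 4))
    symbols = tuple("abc"[:M])
    J = int(rng.integers(1, 6))
    trajs = []
    for _ in range(J):
        L = int(rng.integers(1, 13))
        trajs.append(tuple(symbols[i] for i in rng.integers(0, M, L)))
    h = int(rng.integers(0, 3))
    alpha = 1.0 if rng.random() < 0.5 else 0.5
    return TrajectorySet(Alphabet(symbols), trajs), h, np.full(M, alpha)
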
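import numpy as np
import pytest

from coopctl import EvolutionParams, InterferenceScheme, PDGame


@pytest.fixture
def game():
    """The (R, T, S, P) = (1, 2, -1, 0) Prisoner's Dilemma used throughout."""
    return PDGame.standard()


@pytest.fixture
def params100(game):
    return EvolutionParams(N=100, beta=0.1)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def random_scheme(rng, N, scale=5.0):
    """A random non-negative general interference scheme of the right length."""
    return InterferenceScheme.general(rng.uniform(0.0, scale, N - 1))
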
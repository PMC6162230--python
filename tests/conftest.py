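import numpy as np
import pytest

from pdpa import AlphaGrid, GameParams, build_lattice, init_population, make_fixture


@pytest.fixture
def params():
    """The standard dilemma point used throughout: T=1.4, L=0.4, R=1, P=S=0."""
    return GameParams(T=1.4, L=0.4)


@pytest.fixture
def grid():
    return AlphaGrid(kappa=4)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def single_c_3x3():
    return make_fixture("single_c_3x3")


@pytest.fixture
def all_loners_5x5():
    return make_fixture("all_loners_5x5")


@pytest.fixture
def checkerboard_4x4():
    return make_fixture("checkerboard_4x4")


def random_world(side, rng, mode="pdpa"):
    w = build_lattice(side)
    init_population(w, mode, rng)
    return w
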
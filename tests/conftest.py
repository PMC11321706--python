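import numpy as np
import pytest

from cdstore.alphabet import (
    CompositeAlphabet,
    CompositeLetter,
    enumerate_full_alphabet,
    select_low_error_subset,
)
from cdstore.channel import ChannelParams
from cdstore.experiments import build_code_alphabet
from cdstore.rscode import RSSpec
from cdstore.translib import build_library_exact, get_library


@pytest.fixture(scope="session")
def phi1():
    return enumerate_full_alphabet(1)


@pytest.fixture(scope="session")
def phi2():
    return enumerate_full_alphabet(2)


@pytest.fixture(scope="session")
def sigma6():
    """The six-letter in vitro alphabet {A, C, G, T, M, K} at resolution 2."""
    ratios = [
        (2, 0, 0, 0),
        (0, 2, 0, 0),
        (0, 0, 2, 0),
        (0, 0, 0, 2),
        (1, 1, 0, 0),
        (0, 0, 1, 1),
    ]
    return CompositeAlphabet(2, tuple(CompositeLetter(r, 2) for r in ratios))


@pytest.fixture(scope="session")
def phi2_lib10(phi2):
    """Exact transition library for the full resolution-2 alphabet, N=10."""
    return build_library_exact(phi2, ChannelParams(p_error=0.01, depth_N=10))


@pytest.fixture(scope="session")
def toy_code(phi2):
    """Small soft-decoding testbed: 8-letter alphabet, RS(7,3)/GF(8), N=30."""
    params = ChannelParams(p_error=0.01, depth_N=30, seed=0)
    full_lib = build_library_exact(phi2, params)
    alphabet = select_low_error_subset(phi2, 8, full_lib)
    library = build_library_exact(alphabet, params)
    return alphabet, library, RSSpec(8, 7, 3), params


@pytest.fixture(scope="session")
def s64_setup():
    """Selected 64-letter resolution-6 alphabet with its depth-190 library."""
    alphabet = build_code_alphabet(6, 64, 190, p_error=0.01, seed=1)
    params = ChannelParams(p_error=0.01, depth_N=190, seed=2)
    library = get_library(alphabet, params, method="monte_carlo", n_draws=20_000)
    return alphabet, library, params


@pytest.fixture(scope="session")
def s256_setup():
    """Selected 256-letter resolution-10 alphabet with its depth-490 library."""
    alphabet = build_code_alphabet(10, 256, 490, p_error=0.01, seed=5)
    params = ChannelParams(p_error=0.01, depth_N=490, seed=6)
    library = get_library(alphabet, params, method="monte_carlo", n_draws=20_000)
    return alphabet, library, params


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
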
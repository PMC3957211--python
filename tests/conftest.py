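import numpy as np
import pytest

from polychron import (
    CodeSpec,
    NetworkConfig,
    Pattern,
    PatternSpec,
    build_codebook,
    generate_patterns,
)


@pytest.fixture(scope="session")
def neuron_book():
    return build_codebook(CodeSpec(8, 3))


@pytest.fixture(scope="session")
def axon_book():
    return build_codebook(CodeSpec(9, 4))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_disjoint_patterns():
    """Five cross-talk-free 20-spike patterns on 126 neurons."""
    return generate_patterns(
        PatternSpec(n_patterns=5, n_spikes=20, n_neurons=126, disjoint=True, seed=42)
    )


@pytest.fixture
def small_config():
    return NetworkConfig(n_neurons=126, n_axon_modules=100, seed=42)


@pytest.fixture
def chain_pattern():
    """A short hand-written pattern with known timing."""
    return Pattern(
        neurons=np.array([7, 3, 11, 5, 9, 1, 13]),
        times=np.array([0.0, 6.0, 13.5, 21.0, 27.5, 35.0, 44.0]),
    )
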
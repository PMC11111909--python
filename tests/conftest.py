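import numpy as np
import pytest

from olfex import DogModel, make_block_design, randomize_session


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def block1():
    return make_block_design(1, 1e-2, order="8-4-8-4")


@pytest.fixture
def plan(block1):
    return randomize_session(block1, intensity=8, seed=7)


@pytest.fixture
def default_dog():
    return DogModel()


@pytest.fixture
def quiet_dog():
    """Deterministic near-perfect detector: no lapses, no false alerts."""
    return DogModel(
        mu0=-8.0,
        lapse=0.0,
        fa_rate_low=0.0,
        fa_rate_mod=0.0,
        decay_rate=0.0,
        latency_noise_sd=0.0,
        latency_conc_slope=0.0,
        latency_intensity_offset_s=0.0,
    )
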
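import numpy as np
import pytest

from circmix.simulate import simulate_mixtur


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_table():
    """A small mixed-set-size simulated dataset shared across IO/summary tests."""
    return simulate_mixtur(
        model="3_component",
        kappa=8.0,
        p_u=0.1,
        p_n=0.15,
        n_trials=240,
        set_size=[2, 4],
        seed=99,
    )
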
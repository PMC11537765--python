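import numpy as np
import pytest

from microlag import (
    InitialCondition,
    PopulationParams,
    StochasticRunConfig,
    TransferParams,
    get_preset,
)


@pytest.fixture(scope="session")
def preset_a():
    return get_preset("A")


@pytest.fixture(scope="session")
def preset_b():
    return get_preset("B")


@pytest.fixture(scope="session")
def preset_c():
    return get_preset("C")


@pytest.fixture
def single_species_pop():
    """One-species logistic: no competition, invader compartments decoupled."""
    return PopulationParams(
        rn=1.0, Kn=100.0, alpha_in=0.0, alpha_mn=0.0, alpha_ni=0.0, alpha_nm=0.0
    )


@pytest.fixture
def no_transfer():
    return TransferParams(lambda_n=0.0, lambda_m=0.0)


def short_cfg(t_end=50.0, seed=0, **kw):
    return StochasticRunConfig(dt_jump=0.05, t_end=t_end, seed=seed, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
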
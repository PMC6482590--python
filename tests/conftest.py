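import pytest

from tlrct.simulate import SimulationConfig, generate_trial


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A scaled-down trial for fast structural tests."""
    return SimulationConfig(
        seed=7,
        n_participants=60,
        catalog_size=60,
        n_fruit_veg=5,
        n_other=10,
        n_withdrawals=2,
    )


@pytest.fixture(scope="session")
def small_trial(small_config):
    return generate_trial(small_config)


@pytest.fixture(scope="session")
def default_trial():
    """One trial at the study conditions (null effect)."""
    return generate_trial(SimulationConfig(seed=11))
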
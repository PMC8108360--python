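import pytest

from senesce_enh.simulate import SimConfig, generate

DATASET_SEED = 11


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(seed=DATASET_SEED)


@pytest.fixture(scope="session")
def dataset(sim_config):
    """One shared synthetic dataset under the default study conditions."""
    return generate(sim_config)
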
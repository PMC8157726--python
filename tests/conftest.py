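import pytest
from hypothesis import settings

from evoland import SyntheticConfig, simulate_all

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study():
    """Small simulated study with sampling noise on."""
    return simulate_all(SyntheticConfig(seed=11, n_genes=12))


@pytest.fixture(scope="session")
def noise_free_study():
    """Simulated study in the deterministic regime: every planted variant is
    fully fixed and expression carries no noise."""
    return simulate_all(SyntheticConfig(seed=7, n_genes=12).noise_free())
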
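import numpy as np
import pytest

from moevo import RunConfig, build_scenario, simulate_case


@pytest.fixture(scope="session")
def cfg():
    return RunConfig()


@pytest.fixture(scope="session")
def default_bundles():
    """One simulated case per mode at default scenario settings."""
    return {moe: simulate_case(build_scenario(moe, {}, seed=3)) for moe in "SPNE"}


@pytest.fixture(scope="session")
def noiseless_bundles():
    """One case per mode at effectively noise-free observation settings."""
    overrides = {"purity_polyp": 1.0, "purity_cancer": 1.0, "depth": 1e6}
    return {moe: simulate_case(build_scenario(moe, overrides, seed=1)) for moe in "SPNE"}


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
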
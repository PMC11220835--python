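import numpy as np
import pytest

from superlet_toolkit import SignalConfig, run_benchmark


@pytest.fixture(scope="session")
def default_config() -> SignalConfig:
    return SignalConfig()


@pytest.fixture(scope="session")
def full_report():
    """The complete default benchmark, computed once per session."""
    return run_benchmark(SignalConfig())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240703)
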
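import pytest

from sparsenergy import NetworkConfig, default_budget


@pytest.fixture
def budget_3hz():
    """Measured ATP budget at the 3 Hz end of the physiological rate range."""
    return default_budget(3.0)


@pytest.fixture
def budget_4hz():
    return default_budget(4.0)


@pytest.fixture
def benchmark_net():
    """The (N=100, A=50) benchmark network all capacities are normalized to."""
    return NetworkConfig(N=100, A=50)
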
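import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from rnmkit import (  # noqa: E402
    make_benchmark_network,
    make_paired_fixture,
    make_toggle_network,
)


@pytest.fixture(scope="session")
def benchmark():
    """Benchmark network with default planted flip (0.2585)."""
    return make_benchmark_network()


@pytest.fixture(scope="session")
def toggle():
    return make_toggle_network()


@pytest.fixture(scope="session")
def paired_zero():
    """Paired network/secretome fixture with zero planted deviation."""
    return make_paired_fixture(seed=11)
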
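import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from lncmem.synthetic import SimConfig, simulate  # noqa: E402


@pytest.fixture(scope="session")
def small_sim():
    """Compact labelled fixture shared across tests (deterministic)."""
    return simulate(SimConfig(seed=5, n_genes=40, n_lncs=60, n_chroms=4))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
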
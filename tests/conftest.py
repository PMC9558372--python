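import pytest
from hypothesis import HealthCheck, settings

from cphkit.fixtures import asp_like_reference_grid
from cphkit.ti_fit import build_grid

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_grid():
    return build_grid(-0.1, 1.1, 0.05)


@pytest.fixture(scope="session")
def asp7_grid():
    """Noiseless reference grid from the degree-7 carboxylate-like truth."""
    return asp_like_reference_grid(7)
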
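import numpy as np
import pytest

from comodnet.simulate import DEFAULT_EFFECTS, default_spec, simulate_expression


@pytest.fixture(scope="session")
def small_spec():
    """Three planted modules plus background at the full sample design."""
    return default_spec(
        seed=7,
        module_sizes=(60, 50, 40),
        effects=DEFAULT_EFFECTS[:3],
        n_background=40,
    )


@pytest.fixture(scope="session")
def small_bundle(small_spec):
    return simulate_expression(small_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
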
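import numpy as np
import pytest

from mskpain.synthetic import SyntheticConfig, generate_parameter_set


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic study conditions, seed 1."""
    return generate_parameter_set(SyntheticConfig(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
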
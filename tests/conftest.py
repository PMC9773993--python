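import numpy as np
import pytest

from spinefield.synthetic_anatomy import AnatomyParams, build_anatomy


@pytest.fixture(scope="session")
def default_params() -> AnatomyParams:
    return AnatomyParams()


@pytest.fixture(scope="session")
def anatomy(default_params):
    """Default synthetic anatomy (2 mm grid), shared across tests."""
    return build_anatomy(default_params)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
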
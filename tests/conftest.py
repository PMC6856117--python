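import numpy as np
import pytest

from cabalsim import TraitResponse


@pytest.fixture(scope="session")
def tr_087() -> TraitResponse:
    """t = 0.87 k, c_trait = 0.9 k^1.5 (the threshold-and-purge experiments)."""
    return TraitResponse.power(0.87, 1.0, 0.9, 1.5)


@pytest.fixture(scope="session")
def tr_linear() -> TraitResponse:
    """t = k, c_trait = k/2 (the dynamics and ABM experiments)."""
    return TraitResponse.power(1.0, 1.0, 0.5, 1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240913)
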
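import numpy as np
import pytest

from fanfold import (
    FanParams,
    build_folded_geometry,
    build_wing_model,
    unfold_pattern,
)


@pytest.fixture(scope="session")
def standard_params() -> FanParams:
    """The upscaled standard geometry: 25/25 cm segments, r=5, theta=15, n=1."""
    return FanParams(l_proximal=25.0, l_distal=25.0, r=5.0, theta=15.0, n=1)


@pytest.fixture(scope="session")
def folded(standard_params):
    return build_folded_geometry(standard_params)


@pytest.fixture(scope="session")
def pattern(folded, standard_params):
    return unfold_pattern(folded, standard_params)


@pytest.fixture(scope="session")
def standard_model(pattern):
    return build_wing_model(pattern, k=10.0, l_r=0.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)
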
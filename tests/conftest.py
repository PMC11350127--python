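import numpy as np
import pytest

from cslmap import EffectModel, MarkerMap, enumerate_panel


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def panel5():
    return enumerate_panel(5)


@pytest.fixture(scope="session")
def default_map():
    return MarkerMap.default()


@pytest.fixture
def additive_model():
    """Main-effects-only truth used by null-calibration simulations."""
    return EffectModel(
        mu=100.0, a=np.array([2.0, -1.0, 0.5, 1.5, -2.5]), b={}, c={},
        sigma_e=2.0,
    )
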
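import numpy as np
import pytest

from taskbold.config import ConditionParams, NoiseSpec, ProtocolConfig
from taskbold.synth import generate_session, make_voxel_meta


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def protocol():
    return ProtocolConfig()


@pytest.fixture
def small_protocol():
    return ProtocolConfig(runs_per_condition=2)


@pytest.fixture
def quiet_conditions():
    """Conditions with no noise at all and equal amplitude."""
    spec = NoiseSpec()
    return {
        "high": ConditionParams(amplitude=1.0, noise=spec),
        "low": ConditionParams(amplitude=1.0, noise=spec),
    }


@pytest.fixture
def default_session(small_protocol, rng):
    meta = make_voxel_meta(24, rng)
    return generate_session(small_protocol, None, meta, rng,
                            include_physio=True)


@pytest.fixture(autouse=True)
def _quiet_warnings():
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
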
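import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def n15_observers():
    """Observer settings of the 15N Q-band HYSCORE protocol."""
    from flavospin.synthetic import PROTOCOLS

    p = PROTOCOLS["hyscore_qband_15n"]
    return [(b, p["mw_freq_GHz"], p["bandwidth_MHz"]) for b in p["observers_mT"]]


@pytest.fixture(scope="session")
def n14_observers():
    from flavospin.synthetic import PROTOCOLS

    p = PROTOCOLS["hyscore_qband_14n"]
    return [(b, p["mw_freq_GHz"], p["bandwidth_MHz"]) for b in p["observers_mT"]]
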
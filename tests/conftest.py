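import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from multiorgan.spectra import builtin_library

settings.register_profile(
    "suite", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def library():
    return builtin_library()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
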
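import numpy as np
import pytest

from quantal.datatypes import StimProtocol
from quantal.synth import ReleaseModelParams


@pytest.fixture
def control_params():
    """Control-like tonic terminal: 300 AZs, q = 0.58 nA, 2.7 Hz minis."""
    return ReleaseModelParams(seed=123)


@pytest.fixture
def single_az_params():
    """One AZ, deterministic release, clean rendering."""
    return ReleaseModelParams(n_az=1, slots_per_az=1, p_v=1.0, theta=0.0,
                              rho=1.0, q_cv=0.0, noise_sigma=0.0,
                              mini_rate=0.0, f_async=0.0, sync_sigma=0.0,
                              seed=7)


@pytest.fixture
def short_protocol():
    return StimProtocol.periodic(5, 1.0, start=0.2)


def poisson_3se(rate, duration):
    return 3.0 * np.sqrt(rate / duration)
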
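import numpy as np
import pytest

from mpsize.events_io import ContrastMeasurement
from mpsize.simulate import SimConfig


@pytest.fixture
def cfg():
    """Default simulator configuration, seeded."""
    return SimConfig(seed=1)


@pytest.fixture
def noiseless_cfg():
    return SimConfig(seed=1).noiseless()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def two_peak_measurement(rng):
    """Two well-separated Gaussian populations (released-genome scale)."""
    ev = np.concatenate(
        [
            rng.normal(-0.041, 0.002, size=300),
            rng.normal(-0.146, 0.004, size=300),
        ]
    )
    return ContrastMeasurement(measurement_id="two_peak", events=ev)
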
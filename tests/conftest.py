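import numpy as np
import pytest

from strainpheno import GrowthSimSpec, synth


@pytest.fixture
def short_grid():
    """13-min sampling over 12 h: long enough for a full sigmoid."""
    return synth.default_time_grid(12.0)


@pytest.fixture
def canonical_spec(short_grid):
    """The reference noiseless curve used across fitting tests."""
    return GrowthSimSpec(
        y0=0.05, A=1.0, mu_max=0.3, lag=2.0, noise_sd=0.0,
        t_grid=synth.default_time_grid(48.0), seed=1,
    )


@pytest.fixture
def calibration():
    return synth.DEFAULT_CALIBRATION
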
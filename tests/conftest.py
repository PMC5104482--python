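import numpy as np
import pytest

from sspstes import RunConfig, TimeSeriesMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cfg():
    """Lightweight configuration for fast pipeline tests."""
    return RunConfig(sm=19, tm=5, seed=7)


@pytest.fixture
def tiny_ts(rng):
    """Three short independent series."""
    return TimeSeriesMatrix(
        values=rng.standard_normal((120, 3)), names=("a", "b", "c")
    )
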
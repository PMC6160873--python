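import numpy as np
import pytest

from eegstates.data import TrialTensor


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_tensor(rng):
    """4 channels x 120 samples x 12 trials, two conditions."""
    data = rng.standard_normal((4, 120, 12))
    return TrialTensor(
        data=data, fs=240.0,
        condition=np.array(["a"] * 6 + ["b"] * 6),
    )
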
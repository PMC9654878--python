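import numpy as np
import pytest

from ecgstego import synth_ecg


@pytest.fixture(scope="session")
def ecg4096():
    """Default 4096-sample synthetic trace shared across read-only tests."""
    return synth_ecg(4096, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
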
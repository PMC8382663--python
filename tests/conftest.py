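import numpy as np
import pytest

from hkb import HKBParams


@pytest.fixture
def avitabile_mp() -> HKBParams:
    """alpha = beta = 1, a = -0.5, b = 0.5, c = 0, omega = 2 (gamma = 1)."""
    return HKBParams(gamma=1.0, alpha=1.0, beta=1.0, a=-0.5, b=0.5, c=0.0,
                     omega=2.0)


@pytest.fixture
def avitabile_pp() -> HKBParams:
    return HKBParams(gamma=1.0, alpha=1.0, beta=1.0, a=0.5, b=0.5, c=0.0,
                     omega=2.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
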
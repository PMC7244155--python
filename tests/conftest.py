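import numpy as np
import pytest
from hypothesis import settings

from ebinfer import EBIConfig, EBIState, TaskConfig

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_task():
    return TaskConfig(segment_length=100, total_steps=500, seed=7)


@pytest.fixture
def two_hypothesis_state():
    cfg = EBIConfig(alpha=0.1, m=0.0, K=2)
    return EBIState.initialize(cfg, mu0=[1.0, 4.0], sigma20=[0.05, 0.08])
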
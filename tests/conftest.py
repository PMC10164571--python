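import numpy as np
import pytest

from irscan import ScanConfig, build_dataset


@pytest.fixture
def default_config():
    return ScanConfig()


@pytest.fixture(scope="session")
def small_dataset():
    """20 regions, 12 with exactly one planted passing pair, deterministic."""
    plan = [[(94, 1500)] if i < 12 else [] for i in range(20)]
    return build_dataset(plan, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
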
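import numpy as np
import pytest

from vegstab import SimConfig, simulate_stack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_stack():
    """40-year 8x8 stack with mild persistence, shared across read-only tests."""
    return simulate_stack(SimConfig(n_years=40, n_rows=8, n_cols=8, phi=0.4, sigma_rel=0.1, seed=42))
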
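import numpy as np
import pytest

from ouroboros.simulate import SimConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Two pseudo-patients x 40 spots at 64 px; shared across read-only tests."""
    cfg = SimConfig(n_patients=2, spots_per_patient=40, seed=42)
    dataset, cells = simulate_cohort(cfg)
    return cfg, dataset, cells
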
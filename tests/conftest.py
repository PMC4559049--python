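import numpy as np
import pytest
from hypothesis import settings

from snpdispersal.markers import build_panel
from snpdispersal.simulate import SimulationConfig, simulate_dataset

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def small_panel():
    """Tiny panel: 12 autosomal + 3 X + 2 Y + 4 mtDNA loci."""
    return build_panel(np.full(12, 0.63))


@pytest.fixture(scope="session")
def ideal_dataset():
    """Small error-free, fully sampled simulated study (shared across
    tests that only read from it)."""
    cfg = SimulationConfig(
        n_founders_f=6, n_founders_m=6, n_generations=3,
        epsilon=0.0, dropout_rate=0.0, missing_rate=0.0, invalid_rate=0.0,
        prop_sampled=1.0, seed=7,
    )
    return simulate_dataset(cfg)
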
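import numpy as np
import pytest

from ramanstage.spectral_core import WavenumberAxis
from ramanstage.synthetic_data import SyntheticConfig


@pytest.fixture(scope="session")
def axis() -> WavenumberAxis:
    return WavenumberAxis.default()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def clean_config() -> SyntheticConfig:
    """Noise-free, baseline-free, jitter-free study conditions."""
    return SyntheticConfig(
        seed=1,
        noise_sd=0.0,
        spike_rate=0.0,
        baseline_scale=0.0,
        weight_jitter=0.0,
        cell_heterogeneity=0.0,
    )


@pytest.fixture
def small_cube_config() -> SyntheticConfig:
    """A small map for fast cube tests (the geometry, not the default size)."""
    return SyntheticConfig(seed=3, rows=20, cols=20, n_cells=2, cell_radius_um=(6.0, 10.0))
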
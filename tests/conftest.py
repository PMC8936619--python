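import numpy as np
import pytest

from gastricnet import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A fast cohort: reduced grid, short participant count."""
    return SimulationConfig(n_participants=3, grid_shape=(12, 12, 6), n_coupled_voxels=40, seed=11)


@pytest.fixture
def clean_config():
    """No nuisance structure: coupled voxels carry only the locked cosine."""
    return SimulationConfig(
        n_participants=3,
        grid_shape=(8, 8, 4),
        n_coupled_voxels=20,
        drift_amp=0.0,
        csf_amp=0.0,
        cardiac_amp=0.0,
        noise_sd=0.0,
        seed=21,
    )
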
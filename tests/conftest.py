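import numpy as np
import pytest

from drivemeg import simulate


@pytest.fixture(scope="session")
def model32():
    """Small forward model shared across tests: 32 sensors, 162 sources."""
    return simulate.build_source_model(n_sensors=32, grid=2, seed=0)


@pytest.fixture(scope="session")
def planted_study():
    """Small cohort with the default planted effects (5 subjects, 32
    sensors, 60 s blocks) used by the end-to-end pipeline tests."""
    cfg = simulate.StudyConfig.with_planted_effects(
        n_subjects=5, n_sensors=32, sfreq=100.0,
        block_duration_s=60.0, baseline_duration_s=20.0,
        empty_room_duration_s=60.0)
    return simulate.generate_experiment(cfg, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
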
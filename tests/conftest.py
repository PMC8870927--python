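import numpy as np
import pytest

from enoseml import StudyDesign, simulate_dataset
from enoseml.synth import default_sensor_bank


@pytest.fixture(scope="session")
def small_design():
    """Tiny 2-day single-session design (14 samples) for fast tests."""
    return StudyDesign(n_days=2, sessions=("A",), proportions=(0.0, 0.3, 0.6),
                       samples_per_proportion_per_day_per_session=2, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_design):
    return simulate_dataset(small_design)


@pytest.fixture(scope="session")
def design_a():
    """Measurement-A style design: 10 days, one session, 210 samples."""
    return StudyDesign(n_days=10, sessions=("A",), seed=5)


@pytest.fixture(scope="session")
def dataset_a(design_a):
    return simulate_dataset(design_a)


@pytest.fixture(scope="session")
def noise_free_bank():
    bank = default_sensor_bank()
    for s in bank:
        s.noise_sd = 0.0
    return bank


@pytest.fixture(scope="session")
def quiet_design():
    """All nuisance terms switched off: deterministic mean curves."""
    return StudyDesign(n_days=1, sessions=("A",),
                       samples_per_proportion_per_day_per_session=1,
                       seed=0, day_effect_sd=0.0, sensor_drift_sd=0.0,
                       sample_jitter_sd=0.0, sample_gain_sd=0.0,
                       flow_noise_sd=0.0)
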
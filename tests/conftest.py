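import logging

import numpy as np
import pytest

from eegprognosis.config import (
    AnnotationSchedule,
    EntropyParams,
    SimulationConfig,
)
from eegprognosis.containers import CHANNELS_1020, Epoch
from eegprognosis.synthetic import simulate_cohort_table, simulate_recording

logging.getLogger("eegprognosis").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def entropy_params():
    return EntropyParams()


@pytest.fixture(scope="session")
def short_sim_config():
    """Montage-only schedule: three 10-s epochs per 110-s recording."""
    return SimulationConfig(
        n_patients=4,
        prevalence_recurrence=0.5,
        duration_s=110.0,
        schedule=AnnotationSchedule(
            montage_interval_s=30.0,
            hv_start_s=None,
            photic_freqs_hz=None,
            eye_interval_s=None,
        ),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_recording(short_sim_config):
    table = simulate_cohort_table(short_sim_config)
    return simulate_recording(table.iloc[0], short_sim_config)


@pytest.fixture
def noise_epoch(rng):
    return Epoch(
        eeg_id="E0001",
        epoch_index=0,
        onset_s=0.0,
        condition="montage_change",
        data=10.0 * rng.standard_normal((19, 2000)),
        sampling_rate=200.0,
    )


@pytest.fixture
def channels():
    return CHANNELS_1020
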
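import numpy as np
import pytest

import apnealab as al


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def short_schedule():
    """Four 3-min blocks (OFF first) for fast end-to-end runs."""
    return al.StimulationSchedule.standard("off_first", block_hours=0.05)


@pytest.fixture
def quiet_params():
    """Noise-free, small simulation parameters for exact-recovery checks."""
    return al.SimParams(
        duration_h=0.2,
        sample_rate=50.0,
        spo2_rate=5.0,
        hr_rate=5.0,
        apnea_rate_off=40.0,
        resp_noise_sd=0.0,
        spo2_noise_sd=0.0,
        hr_noise_sd=0.0,
        ecg_noise_sd=0.0,
        seed=7,
    )


@pytest.fixture
def tiny_cohort():
    """Deterministic 3-subject cohort table for arithmetic-level checks."""
    return al.generate_cohort(3, seed=99)
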
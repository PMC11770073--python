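import numpy as np
import pytest

from icpflow.simulate import (
    PatientSimConfig,
    PulseMorphParams,
    simulate_recording,
)


@pytest.fixture(scope="session")
def clean_recording():
    """Two minutes of artifact-free signal at a fixed 60 bpm heart rate."""
    cfg = PatientSimConfig(
        patient_id="clean",
        hr_mean_bpm=60.0,
        hr_sd_bpm=0.0,
        artifact_rate_per_min=0.0,
        drift_sd=0.0,
        noise_sd=0.01,
        duration_s=120.0,
        morph_drift_sd=0.0,
    )
    return simulate_recording(cfg, PulseMorphParams(), seed=42)


@pytest.fixture(scope="session")
def default_morph():
    return PulseMorphParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
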
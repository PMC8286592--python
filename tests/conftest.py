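import numpy as np
import pytest
from hypothesis import settings

from resppat.synth import SubjectProfile, make_healthy_protocol, sample_profile

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def noiseless_profile():
    """Deterministic limit: no jitter, no noise, no drift, no wander."""
    return SubjectProfile(
        subject_id="NL",
        rest_rate=20.0,
        rest_amplitude=1.0,
        exercise_rate_multiplier=1.5,
        exercise_amplitude_multiplier=1.3,
        strategy="rate_dominant",
        breath_length_cv=0.0,
        amplitude_cv=0.0,
        noise_sd=0.0,
        baseline_drift_amplitude=0.0,
        rate_wander_sd=0.0,
        amplitude_wander_sd=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def noiseless_recording(noiseless_profile):
    return make_healthy_protocol(noiseless_profile)


@pytest.fixture(scope="session")
def rate_dominant_recording():
    rng = np.random.default_rng(11)
    prof = sample_profile("RD", "rate_dominant", 11, rng)
    return make_healthy_protocol(prof)


@pytest.fixture(scope="session")
def amplitude_dominant_recording():
    rng = np.random.default_rng(12)
    prof = sample_profile("AD", "amplitude_dominant", 12, rng)
    return make_healthy_protocol(prof)
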
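import numpy as np
import pandas as pd
import pytest

from rtee.formulas import ParticipantProfile
from rtee.synth import ActivityProtocol, NoiseParams, SessionRecord, generate_session


@pytest.fixture
def male_profile():
    return ParticipantProfile(weight=70.0, height=175.0, age=30.0, gender_flag=1)


@pytest.fixture
def female_profile():
    return ParticipantProfile(weight=60.0, height=165.0, age=25.0, gender_flag=0)


@pytest.fixture
def default_protocol():
    return ActivityProtocol.default(
        met_levels={"Cycle1": 10.0, "Cycle2": 14.0, "Run1": 8.0, "Run2": 16.0}
    )


@pytest.fixture
def noise_free_session(male_profile, default_protocol):
    return generate_session(
        male_profile, default_protocol, NoiseParams(noise_sd=0.0), rng_seed=0
    )


@pytest.fixture
def noisy_session(male_profile, default_protocol):
    return generate_session(male_profile, default_protocol, NoiseParams(), rng_seed=1)


def make_constant_session(profile, vo2, hr=80.0, n=600, label="Sitting"):
    """A session with constant VO2/HR, for hand-checkable arithmetic."""
    samples = pd.DataFrame(
        {
            "time_s": np.arange(n),
            "hr_bpm": np.full(n, float(hr)),
            "vo2_ml_kg_min": np.full(n, float(vo2)),
            "activity": np.full(n, label, dtype=object),
            "met_true": np.full(n, vo2 / 3.5),
        }
    )
    return SessionRecord(profile=profile, samples=samples)


@pytest.fixture
def short_protocol():
    """Six segments of 60 s each — fast to train on."""
    return ActivityProtocol.default(
        met_levels={"Cycle1": 10.0, "Cycle2": 14.0, "Run1": 8.0, "Run2": 16.0},
        segment_duration_s=60,
    )
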
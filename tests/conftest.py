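import numpy as np
import pytest

from eegmusic.bands import BANDS
from eegmusic.preprocess import analysis_slices, preprocess_trial
from eegmusic.synth import EmotionProfile, GeneratorConfig, default_profiles, generate_trial


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(n_subjects=2, seed=7)


@pytest.fixture(scope="session")
def clean_config():
    """No noise, no line, no drift, no EMG; uniform channel sensitivity."""
    return GeneratorConfig(
        n_subjects=1,
        seed=7,
        noise_sd=0.0,
        line_noise_amp=0.0,
        drift_amp=0.0,
        speech_emg_sd=0.0,
        subject_sd=0.0,
        channel_sensitivity=(1.0,) * 5,
    )


@pytest.fixture(scope="session")
def one_trial(small_config):
    profile = default_profiles()["anger"]
    return generate_trial(small_config, profile, "S000", seed=42)


@pytest.fixture(scope="session")
def trial_slices(one_trial):
    return preprocess_trial(one_trial)


@pytest.fixture(scope="session")
def analysis_set(trial_slices):
    return analysis_slices(trial_slices)


def single_band_profile(band: str, power: float = 1.0) -> EmotionProfile:
    return EmotionProfile(
        emotion="custom",
        band_power={b: (power if b == band else 0.0) for b in BANDS},
        speaking_gain={b: 1.0 for b in BANDS},
    )
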
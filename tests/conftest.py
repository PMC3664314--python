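import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

RATE = 16_000


def harmonic_complex(f0=220.0, duration=2.0, n_harmonics=5, rate=RATE,
                     amplitude=0.8, noise_sd=0.0, seed=0):
    """Deterministic harmonic test signal with known fundamental."""
    t = np.arange(int(duration * rate)) / rate
    x = sum(np.sin(2 * np.pi * h * f0 * t) / h
            for h in range(1, n_harmonics + 1))
    x = x / np.max(np.abs(x))
    if noise_sd:
        x = x + noise_sd * np.random.default_rng(seed).standard_normal(t.size)
        x = x / np.max(np.abs(x))
    return amplitude * x


@pytest.fixture(scope="session")
def extractor():
    from crossaffect.lld import LLDExtractor

    return LLDExtractor()


@pytest.fixture(scope="session")
def feature_index():
    from crossaffect.functionals import build_feature_index

    return build_feature_index()


@pytest.fixture(scope="session")
def tone_clip():
    from crossaffect.audio import AudioClip

    return AudioClip(harmonic_complex(), RATE, clip_id="tone220")


@pytest.fixture(scope="session")
def tone_lld(extractor, tone_clip):
    return extractor.extract(tone_clip)
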
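import numpy as np
import pytest

from rmamnet.synth import CorpusConfig, SpeciesProfile, default_profiles


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def profile_a():
    return default_profiles()[0]


@pytest.fixture
def profile_b():
    return default_profiles()[1]


@pytest.fixture
def fast_profile():
    """Short-decay profile so single-pulse tests stay quick."""
    return SpeciesProfile(
        name="fast",
        band_center_hz=4000.0,
        band_width_hz=1000.0,
        pulse_rate_hz=6.0,
        attack_ms=1.0,
        decay_ms=8.0,
    )


@pytest.fixture
def tiny_corpus_config():
    """Smallest corpus that still supports a 5:1 temporal split."""
    return CorpusConfig(seed=7, minutes_per_class=1.5, sample_rate_hz=44_100)
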
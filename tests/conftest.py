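import numpy as np
import pytest

import myoselect as ms


@pytest.fixture(scope="session")
def small_recording() -> ms.Recording:
    """Well-separated 4-class synthetic recording, 6 trials per class."""
    return ms.generate(ms.SyntheticConfig(trials_per_class=6, seed=11))


@pytest.fixture(scope="session")
def small_features(small_recording) -> ms.FeatureMatrix:
    windows = ms.segment(small_recording, ms.WindowSpec(0.25))
    return ms.extract_all(
        windows, small_recording.fs, channel_names=small_recording.channel_names
    )


@pytest.fixture(scope="session")
def planted_features() -> ms.FeatureMatrix:
    """30 windows/class, 20 features, 3 planted at large effect."""
    return ms.generate_planted_features(
        n_windows=30, n_features=20, planted=[2, 5, 11], effect_size=2.0, seed=5
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
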
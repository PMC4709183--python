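import numpy as np
import pytest

from plvspeller.containers import EpochSet
from plvspeller.synth import make_fixture


@pytest.fixture(scope="session")
def tiny_fixture():
    """Deterministic small synthetic session (4 channels, 250 Hz)."""
    return make_fixture("tiny", rng_seed=7)


@pytest.fixture(scope="session")
def tiny_epochs(tiny_fixture):
    from plvspeller.preprocess import bandpass_filter, extract_epochs

    rec, _ = tiny_fixture
    return extract_epochs(bandpass_filter(rec))


def make_epochs(data, fs=500.0, is_target=None, stimulus_ids=None,
                character_indices=None, t0_ms=-200.0):
    """EpochSet around a raw (trials, channels, samples) array."""
    data = np.asarray(data, float)
    n_trials, n_ch, n_samp = data.shape
    time_ms = t0_ms + np.arange(n_samp) / fs * 1000.0
    return EpochSet(
        data=data,
        time_ms=time_ms,
        fs=fs,
        channel_labels=tuple(f"CH{i}" for i in range(n_ch)),
        is_target=np.zeros(n_trials, bool) if is_target is None else np.asarray(is_target, bool),
        stimulus_ids=np.zeros(n_trials, int) if stimulus_ids is None else np.asarray(stimulus_ids, int),
        character_indices=np.zeros(n_trials, int) if character_indices is None else np.asarray(character_indices, int),
    )
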
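import numpy as np
import pytest

from mmrtf.preprocess import SCALP_CHANNELS, ContinuousEEG, EpochedBlock


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_continuous():
    """30 s of 3-channel sinusoid + noise at 250 Hz."""
    fs = 250.0
    t = np.arange(int(30 * fs)) / fs
    gen = np.random.default_rng(7)
    data = np.vstack([
        np.sin(2 * np.pi * 10 * t),
        0.5 * np.sin(2 * np.pi * 10 * t + 0.3),
        gen.standard_normal(t.size),
    ])
    return ContinuousEEG(data=data, fs=fs, channel_names=["Cz", "Pz", "Fz"])


@pytest.fixture()
def scalp_continuous():
    """60 s of 11-channel noise at 250 Hz with the standard montage."""
    fs = 250.0
    gen = np.random.default_rng(11)
    data = gen.standard_normal((11, int(60 * fs)))
    return ContinuousEEG(data=data, fs=fs, channel_names=list(SCALP_CHANNELS))


def make_block(n_trials=64, n_time=501, fs=250.0, seed=0, labels=None):
    gen = np.random.default_rng(seed)
    trials = gen.standard_normal((n_trials, n_time))
    time_ms = (np.arange(n_time) - n_time // 4) * 1000.0 / fs
    if labels is None:
        labels = np.array(
            ["deviant" if i % 7 == 0 else "standard" for i in range(n_trials)],
            dtype=object,
        )
    return EpochedBlock(trials=trials, labels=labels, time_ms=time_ms, fs=fs)


@pytest.fixture()
def noise_block():
    return make_block()
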
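import numpy as np
import pytest

import polysom as ps


@pytest.fixture(scope="session")
def config():
    return ps.SimConfig()


@pytest.fixture(scope="session")
def default_day(config):
    """24 h ground-truth hypnogram + latent sleep pressure, seed 0."""
    return ps.simulate_hypnogram(config, 24, seed=0)


@pytest.fixture(scope="session")
def short_recording(config):
    """1 h of synthesized EEG/EMG with its ground truth."""
    hyp, s = ps.simulate_hypnogram(config, 1, seed=11)
    rec = ps.simulate_signals(hyp, s, config, seed=12)
    return rec, hyp, s


def sine_recording(freq_hz, fs=128.0, n_epochs=3, amp=50.0, emg=0.0):
    n = int(10 * fs) * n_epochs
    t = np.arange(n) / fs
    eeg = amp * np.sin(2 * np.pi * freq_hz * t)
    rng = np.random.default_rng(0)
    emg_sig = rng.standard_normal(n) * emg
    return ps.Recording(eeg=eeg, emg=emg_sig, fs=fs,
                        schedule=ps.LightSchedule.ld_12_12(n / fs))
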
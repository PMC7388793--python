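import numpy as np
import pytest

from synchnet import preprocess as pp
from synchnet import synthdata as sd


@pytest.fixture(scope="session")
def small_fm():
    """Small forward model shared across tests (32 sensors, 80 sources, 12 nodes)."""
    return sd.make_forward_model(n_sensors=32, n_sources=80, n_nodes=12, seed=1)


@pytest.fixture(scope="session")
def screened_subject(small_fm):
    """One synthetic subject with injected artifacts/drowsiness plus its truth."""
    spec = sd.CouplingSpec(label="g", coupling={"theta": 0.3}, eog_gain=0.3,
                           drowsy_fraction=0.1, artifact_fraction=0.05)
    raw, truth = sd.simulate_subject(small_fm, spec, duration_s=60.0, fs=250.0,
                                     seed=7)
    return raw, truth


def make_epochset(epochs, fs, eog=0):
    """EpochSet from a plain (epochs x channels x samples) array."""
    epochs = np.asarray(epochs, float)
    n_ch = epochs.shape[1]
    labels = tuple(f"ch{i}" for i in range(n_ch))
    eog_channels = labels[n_ch - eog:] if eog else ()
    return pp.EpochSet(epochs=epochs, fs=fs, labels=labels,
                       eog_channels=eog_channels,
                       epoch_len_s=epochs.shape[2] / fs)
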
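import warnings

import numpy as np
import pytest

import cuedecode as cd


@pytest.fixture(scope="session")
def small_session():
    """One small simulated participant: 120 trials, 16 EEG channels."""
    spec = cd.DesignSpec(trials_per_cell=20)
    eeg = cd.EEGSimParams(n_channels=16)
    table, epochs, alpha, info = cd.simulate_session(spec, eeg=eeg, seed=101)
    return table, epochs, alpha, info


@pytest.fixture(scope="session")
def behaviour_only_table():
    """A 936-trial behaviour-only session (no EEG)."""
    table, *_ = cd.simulate_session(eeg=None, seed=17)
    return table


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(autouse=True)
def _quiet_wavelet_warnings():
    """The short prestimulus span flags low wavelet frequencies; expected."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore",
                                message=".*wavelet support exceeds.*")
        yield
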
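import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))   # for oracles.py

from normnet import montage, synth


@pytest.fixture(scope="session")
def layout():
    return montage.default_layout()


@pytest.fixture(scope="session")
def small_session():
    return synth.generate_session(n_trials=20, seed=7, subject="s00")


@pytest.fixture(scope="session")
def small_epochs(layout, small_session):
    """One subject's synthetic EEG at reduced size (20 trials, 250 Hz)."""
    return synth.generate_eeg(small_session, layout,
                              synth.default_effect_spec(),
                              srate=250.0, seed=8)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
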
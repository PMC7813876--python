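import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from trimodal.synth import make_templates, simulate_eeg


@pytest.fixture(scope="session")
def templates_truth():
    """Canonical 32-channel templates and their generating ground truth."""
    return make_templates(32)


@pytest.fixture(scope="session")
def sim_eeg(templates_truth):
    """A 60 s, 32-channel, 125 Hz recording at SNR 4 with its state sequence."""
    _, truth = templates_truth
    rec, states = simulate_eeg(truth, duration_s=60.0, fs=125.0, snr=4.0, seed=11)
    return rec, states


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
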
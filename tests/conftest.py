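"""Shared fixtures: scaled-down synthetic sessions and models.

Session fixtures are module- or session-scoped because generation dominates
test runtime; layouts are deliberately smaller than the full study
structure (which the SessionLayout defaults encode) to keep the suite
fast.
"""

import numpy as np
import pytest

from ssmvep.synth_eeg import ResponseModel, SessionLayout, generate_session


@pytest.fixture(scope="session")
def small_layout():
    return SessionLayout(n_subjects=1, trials_per_run=6,
                         brightness_levels=("medium",))


@pytest.fixture(scope="session")
def default_model():
    return ResponseModel()


@pytest.fixture(scope="session")
def high_snr_model():
    """Strong evoked response against modest noise: separable by design."""
    return ResponseModel(harmonic_amplitudes=(2.0, 0.8), noise_scale=1.0,
                         band_powers={"theta": 0.3, "alpha": 1.0, "beta": 0.2})


@pytest.fixture(scope="session")
def bimodal_session(small_layout, default_model):
    return generate_session(small_layout, default_model, seed=11,
                            paradigms=("bimodal",))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
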
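import logging

import numpy as np
import pytest

from muresp import ModulationParams, Scenario, simulate_recording

logging.getLogger("muresp").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def clean_recording():
    """Noise- and artifact-free recording: d=0.4, r=0.2, no jitter.

    One 60-epoch block fits; the closed-form expected PAmp_resp is 66.67 %.
    """
    sc = Scenario(
        fs=250.0,
        imi=2.0,
        n_triggers=66,
        jitter_sd=0.0,
        noise_sd=0.0,
        blink_rate=0.0,
        eog_noise_sd=0.0,
    )
    rec, truth = simulate_recording(sc, seed=11)
    return rec, truth


@pytest.fixture(scope="session")
def noisy_recording():
    """Recording at realistic noise with blinks and timing jitter."""
    sc = Scenario(fs=250.0, imi=2.0, n_triggers=70)
    rec, truth = simulate_recording(sc, seed=12)
    return rec, truth


@pytest.fixture
def modulation_params():
    return ModulationParams(band="alpha", a_base=10.0, depth=0.4, rebound=0.2)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
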
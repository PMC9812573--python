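import numpy as np
import pytest

import myodecode as md
from myodecode.pipeline import build_training_set, preprocess_stream


@pytest.fixture(scope="session")
def fir():
    return md.default_fir()


@pytest.fixture(scope="session")
def synergy():
    return md.default_synergy_model(seed=0)


@pytest.fixture(scope="session")
def profile(synergy, fir):
    mvc = md.synthesize_mvc(synergy, duration=5.0, seed=99)
    return md.compute_mvc_profile(mvc, fir)


@pytest.fixture(scope="session")
def short_script():
    """~14 s script touching one motion per DOF plus rest."""
    return md.MotionScript.from_pairs(
        [("M0", 1.0), ("M1", 2.0), ("M0", 1.0), ("M3", 2.0),
         ("M0", 1.0), ("M5", 2.0), ("M0", 1.0), ("M10", 2.0), ("M0", 2.0)]
    )


@pytest.fixture(scope="session")
def short_session(short_script, synergy):
    """(angle_stream, emg_stream) for the short script, fixed seed."""
    return md.simulate_session(short_script, synergy, seed=42)


@pytest.fixture(scope="session")
def short_pairs(short_session, profile, fir):
    """Supervised pairs from the short session."""
    angles, emg = short_session
    norm = preprocess_stream(emg, profile, fir)
    return md.pair_and_resample(emg.timestamps, norm, angles)
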
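import numpy as np
import pytest

from alscore.experiments import run_fft1hz_experiment, run_voice_experiment
from alscore.simulate import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Default strong-effect synthetic cohort (60 participants, seed 1)."""
    return simulate_cohort(CohortSpec(seed=1))


@pytest.fixture(scope="session")
def fft_result(cohort):
    """Multi-label MLP on FFT-1Hz features, trained end to end."""
    return run_fft1hz_experiment(cohort, seed=1)


@pytest.fixture(scope="session")
def voice_result(cohort):
    """Voice CNN trained end to end (the slow fixture, minutes on one CPU)."""
    return run_voice_experiment(cohort, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
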
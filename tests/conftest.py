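import numpy as np
import pytest

from patsep.pipeline import RunConfig, simulate_study
from patsep.synthdata import build_pairs, generate_stimulus_set


@pytest.fixture(scope="session")
def stimuli():
    """Full 18-identity, 7-view stimulus set (session-shared, read-only)."""
    return generate_stimulus_set(seed=11)


@pytest.fixture(scope="session")
def pair_design(stimuli):
    return build_pairs(stimuli, seed=11)


@pytest.fixture(scope="session")
def study():
    """One default synthetic study with all ROI x condition patterns."""
    return simulate_study(RunConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
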
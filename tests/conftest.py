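import numpy as np
import pytest

from stepramp.config import AnalysisConfig
from stepramp.trial_design import TrialDesign


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def design():
    """Middle-of-the-grid short-TX rightward trial."""
    return TrialDesign(velocity=15.0, tx=0.1, direction=1, duration=0.65)


@pytest.fixture
def interception_design():
    return TrialDesign(
        velocity=15.0, tx=0.1, direction=1, duration=0.65, task="interception"
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
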
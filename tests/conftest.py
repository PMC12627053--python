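import numpy as np
import pytest

from facedamp.facs import AUVector, ExpressionTrial, PrototypeTable
from facedamp.simulate import SyntheticStudyConfig, generate_study


@pytest.fixture(scope="session")
def table() -> PrototypeTable:
    return PrototypeTable()


@pytest.fixture(scope="session")
def default_study():
    """One full synthetic study at the default configuration (74 participants)."""
    return generate_study(SyntheticStudyConfig(seed=20240915))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_trial(pid="P001", intended="happiness", human=None, machine=None, coded=None):
    human = human if human is not None else AUVector({6: 4, 12: 3, 25: 2})
    return ExpressionTrial(
        participant_id=pid, intended=intended, human=human, machine=machine, coded=coded
    )
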
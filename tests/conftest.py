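import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))   # make tests/oracles.py importable

from kneeload.distributor import solve_cycle
from kneeload.knee_model import DEFAULT_PCSA_CM2, Formulation, MuscleProperties
from kneeload.objectives import OBJECTIVES
from kneeload.synthetic_data import gen_trial

FORMULATIONS = ("RM", "RML", "RFML")


@pytest.fixture(scope="session")
def default_trial():
    """The study condition: 101 frames, seed 0, 56.4 kg, noise off."""
    return gen_trial(seed=0)


@pytest.fixture(scope="session")
def props():
    return MuscleProperties(dict(DEFAULT_PCSA_CM2))


@pytest.fixture(scope="session")
def all_cycles(default_trial, props):
    """All 24 formulation × criterion cycle solutions on the default trial.

    Solved once per session; most integration-level assertions read from
    this cache.
    """
    return {
        (f, j): solve_cycle(default_trial, Formulation(f), OBJECTIVES[j], props)
        for f in FORMULATIONS
        for j in OBJECTIVES
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
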
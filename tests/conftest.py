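import dataclasses

import numpy as np
import pytest

from caffsol import CAFFEINE
from caffsol.fixtures import (
    default_ground_truth,
    solubility_table,
    ss_solvent_reference,
)

EXPERIMENT_TEMPERATURES = (293.15, 298.15, 303.15, 308.15, 313.15)


@pytest.fixture(scope="session")
def solute():
    return CAFFEINE


@pytest.fixture(scope="session")
def ss_solvent():
    return ss_solvent_reference()


@pytest.fixture(scope="session")
def truth():
    """Default ground truth at the study conditions (with noise)."""
    return default_ground_truth(seed=0)


@pytest.fixture(scope="session")
def truth0(truth):
    """Noise-free ground truth for exact-inversion tests."""
    return dataclasses.replace(truth, noise_rho=0.0, noise_eta=0.0, noise_lnx=0.0)


@pytest.fixture(scope="session")
def water_table():
    return solubility_table("water")


@pytest.fixture(scope="session")
def ss_table():
    return solubility_table("ss")
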
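import numpy as np
import pytest

from p53loop import (
    DNA_DAMAGE_DISTRIBUTION,
    MECH_DEFAULTS,
    OPERATING_POINT,
    DiscreteParams,
    GeneratorSpec,
)


@pytest.fixture(scope="session")
def operating_point():
    """Published continuous-model operating point (rates in h^-1)."""
    return OPERATING_POINT


@pytest.fixture(scope="session")
def identified_distribution():
    """NLMS-identified weight distribution under DNA damage."""
    return DNA_DAMAGE_DISTRIBUTION


@pytest.fixture(scope="session")
def dna_damage_params():
    """Mean weights of the DNA-damage distribution as a parameter set."""
    return DiscreteParams(w_xy=1.0, w_zy=0.2662, w_yz=0.1656, w_y=0.8737, w_z=0.3627)


@pytest.fixture(scope="session")
def mech_defaults():
    return MECH_DEFAULTS


#: Marginally stable generating weights (|poles| = 1.0): the oscillation
#: never decays, so the NLMS regressors stay persistently exciting over an
#: arbitrarily long series — the right regime for recovery oracles.
SUSTAINED_WEIGHTS = {
    "w_xy": 0.05,
    "w_zy": 0.3122,
    "w_yz": 0.3122,
    "w_y": 0.95,
    "w_z": 0.95,
}


@pytest.fixture(scope="session")
def sustained_spec():
    return GeneratorSpec(schedule=dict(SUSTAINED_WEIGHTS), n_frames=1000, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
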
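"""Shared fixtures: small chain systems and default kinetics."""

import numpy as np
import pytest

from ligfrac.chains import (CHIP, LIQUOR, ChainRegistry, G, MonomerMasses, S,
                            SystemState)
from ligfrac.kinetics import Kinetics
from ligfrac.macro import MacroParams


@pytest.fixture
def masses():
    return MonomerMasses()


@pytest.fixture
def kinetics():
    return Kinetics()


@pytest.fixture
def macro_params():
    return MacroParams()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_registry(sequences, phase=LIQUOR, masses=None):
    """Registry holding the given unit sequences (lists of 0/1)."""
    reg = ChainRegistry(masses)
    for seq in sequences:
        reg.add_chain(list(seq), phase)
    return reg


def make_state(sequences, phase=LIQUOR, t=353.0, seed=0):
    reg = make_registry(sequences, phase)
    return SystemState(registry=reg, t_c=t, t_f=t,
                       rng=np.random.default_rng(seed))


@pytest.fixture
def toy_liquor_registry():
    """Three liquor chains of lengths 3, 2, 1 ([S,G,S], [G,S], [G])."""
    return make_registry([[S, G, S], [G, S], [G]])
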
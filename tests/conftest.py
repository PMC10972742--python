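import numpy as np
import pytest

from thrkit.blocks import build_linear_thr, build_turn_module
from thrkit.io.fixtures import four_helix_ring_unit, turn_unit, two_helix_unit
from thrkit.assemblies import RingSpec


@pytest.fixture
def unit2():
    return two_helix_unit()


@pytest.fixture
def ring_unit():
    return four_helix_ring_unit()


@pytest.fixture
def linear_block(unit2):
    return build_linear_thr(unit2, d=10.0, dh=0.0, n_repeats=4)


@pytest.fixture
def arm_block():
    return build_linear_thr(two_helix_unit(offy=8.0), d=10.0, dh=0.0, n_repeats=3)


@pytest.fixture
def corner90():
    return build_turn_module(turn_unit(), 0.0, 90.0)


@pytest.fixture
def ring12_c4(ring_unit):
    return RingSpec(12, 3, ring_unit, 20.0)


@pytest.fixture
def ring12_c3(ring_unit):
    return RingSpec(12, 4, ring_unit, 20.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240313)
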
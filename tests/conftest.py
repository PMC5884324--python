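import pytest

from agelimb.constitutive import LIGAMENT_LAW_ELDERLY, LIGAMENT_LAW_YOUNG
from agelimb.geometry import make_synthetic_bone
from agelimb.materials import material_table


@pytest.fixture(scope="session")
def mats30():
    return material_table(30)


@pytest.fixture(scope="session")
def mats70():
    return material_table(70)


@pytest.fixture(scope="session")
def femur_baseline():
    """Synthetic 26-year-old femur geometry and two-layer tube mesh."""
    return make_synthetic_bone("femur")


@pytest.fixture(scope="session")
def young_law():
    return LIGAMENT_LAW_YOUNG


@pytest.fixture(scope="session")
def elderly_law():
    return LIGAMENT_LAW_ELDERLY
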
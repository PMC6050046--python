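import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ftszlat import (
    ContactSpec,
    HelixSpec,
    StructureModel,
    default_subunit,
    make_contact_dimer,
    make_crystal_fixture,
    make_helical_filament,
)


def rotation(axis, degrees) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    return Rotation.from_rotvec(np.radians(degrees) * axis / np.linalg.norm(axis)).as_matrix()


@pytest.fixture
def helix_spec():
    # 60 deg twist / 23.05 A rise: six subunits per turn, pitch 138.3 A
    return HelixSpec(twist=60.0, rise=23.05, n_subunits=6)


@pytest.fixture
def helix(helix_spec):
    return make_helical_filament(helix_spec, seed=0)


@pytest.fixture
def crystal_fixture():
    return make_crystal_fixture(c=138.3, a=100.5)


@pytest.fixture
def contact_dimer():
    return make_contact_dimer(ContactSpec([("LYS", "GLU", 2.8), ("ARG", "ASP", 6.0)]), seed=0)


@pytest.fixture
def single_subunit():
    return StructureModel({"A": default_subunit()})
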
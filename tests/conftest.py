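import numpy as np
import pytest

from crowdxfer import (Molecule, PotentialParams, ToyMoleculeSpec,
                       make_test_system, make_toy_molecule)


@pytest.fixture(scope="session")
def params():
    return PotentialParams()


@pytest.fixture(scope="session")
def hardcore_params():
    return PotentialParams(scale_nonpolar=0.0, scale_elec=0.0)


@pytest.fixture(scope="session")
def toy_molecule():
    return make_toy_molecule(ToyMoleculeSpec(n_atoms=10, envelope_radius=3.2,
                                             seed=11), "toy")


@pytest.fixture(scope="session")
def mini_system():
    """A small two-concentration crowded system shared across tests."""
    return make_test_system([0.08, 0.15], n_configs=2, box_side=36.0, seed=5)


def single_atom_molecule(radius=2.0, lj_a=0.0, lj_b=0.0, charge=0.0,
                         name="atom", pos=(0.0, 0.0, 0.0)):
    return Molecule(name, ["C"], [list(pos)], [radius], [lj_a], [lj_b],
                    [charge])


@pytest.fixture
def make_atom():
    return single_atom_molecule
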
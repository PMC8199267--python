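import math

import numpy as np
import pytest

from antdock.fixtures import ToyComplexSpec, build_template, make_toy_complex
from antdock.ligand_io import Atom, Bond, Molecule, _flag_ring_bonds


def make_molecule(name, heavy, bonds):
    """Molecule from (element, xyz, charge) tuples and (a, b, order) bonds."""
    atoms = [Atom(index=i + 1, element=el, position=np.array(pos, float),
                  partial_charge=q)
             for i, (el, pos, q) in enumerate(heavy)]
    mol = Molecule(name=name, atoms=atoms,
                   bonds=[Bond(a=a, b=b, order=o) for a, b, o in bonds])
    _flag_ring_bonds(mol)
    return mol


def benzene():
    heavy = []
    for k in range(6):
        ang = math.radians(60 * k)
        heavy.append(("C", (1.39 * math.cos(ang), 1.39 * math.sin(ang), 0.0), 0.0))
    for k in range(6):
        ang = math.radians(60 * k)
        heavy.append(("H", (2.48 * math.cos(ang), 2.48 * math.sin(ang), 0.0), 0.0))
    bonds = [(k + 1, (k + 1) % 6 + 1, "ar") for k in range(6)]
    bonds += [(k + 1, k + 7, 1) for k in range(6)]
    return make_molecule("benzene", heavy, bonds)


@pytest.fixture(scope="session")
def butane():
    return build_template("butane")


@pytest.fixture(scope="session")
def amide():
    return build_template("n-methylacetamide")


@pytest.fixture(scope="session")
def aromatic():
    return build_template("3-chloroaniline")


@pytest.fixture(scope="session")
def benzene_mol():
    return benzene()


@pytest.fixture(scope="session")
def toy_complex():
    return make_toy_complex(ToyComplexSpec(seed=100))


@pytest.fixture(scope="session")
def toy_spec():
    return ToyComplexSpec(seed=100)
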
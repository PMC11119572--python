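import pytest

from vecmol.chem import AtomRecord, BondRecord, Molecule
from vecmol.geometry import Vec3


@pytest.fixture
def water_like():
    """3-atom, 2-bond toy (O bonded to two H)."""
    atoms = (
        AtomRecord(index=0, element="O", position=Vec3(0.0, 0.0, 0.0)),
        AtomRecord(index=1, element="H", position=Vec3(0.96, 0.0, 0.0)),
        AtomRecord(index=2, element="H", position=Vec3(-0.24, 0.93, 0.0)),
    )
    bonds = (
        BondRecord(start_index=0, end_index=1),
        BondRecord(start_index=0, end_index=2),
    )
    return Molecule(atoms=atoms, bonds=bonds, name="water")


@pytest.fixture
def ethanol_like():
    """2 C, 1 O, 6 H with 8 bonds (geometric toy, idealized-ish coords)."""
    heavy = [
        AtomRecord(index=0, element="C", position=Vec3(0.0, 0.0, 0.0)),
        AtomRecord(index=1, element="C", position=Vec3(1.54, 0.0, 0.0)),
        AtomRecord(index=2, element="O", position=Vec3(2.3, 1.2, 0.0)),
    ]
    hydrogens = [
        AtomRecord(index=3, element="H", position=Vec3(-0.6, 0.9, 0.0)),
        AtomRecord(index=4, element="H", position=Vec3(-0.6, -0.5, 0.8)),
        AtomRecord(index=5, element="H", position=Vec3(-0.6, -0.5, -0.8)),
        AtomRecord(index=6, element="H", position=Vec3(2.1, -0.5, 0.8)),
        AtomRecord(index=7, element="H", position=Vec3(2.1, -0.5, -0.8)),
        AtomRecord(index=8, element="H", position=Vec3(3.25, 1.1, 0.0)),
    ]
    bonds = [
        BondRecord(start_index=0, end_index=1),
        BondRecord(start_index=1, end_index=2),
        BondRecord(start_index=0, end_index=3),
        BondRecord(start_index=0, end_index=4),
        BondRecord(start_index=0, end_index=5),
        BondRecord(start_index=1, end_index=6),
        BondRecord(start_index=1, end_index=7),
        BondRecord(start_index=2, end_index=8),
    ]
    return Molecule(atoms=tuple(heavy + hydrogens), bonds=tuple(bonds),
                    name="ethanol")


MINIMAL_MOLBLOCK = """\
minimal
  test

  2  1  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.5400    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
M  END
$$$$
"""


@pytest.fixture
def minimal_molblock():
    return MINIMAL_MOLBLOCK
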
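"""Deterministic synthetic conformers and SDF writing.

These generators stand in for downloaded structures in tests, examples and
benchmarks: idealized alkane chains and rings with correct bond lengths
and angles, and seeded random packings that emulate drug-like ligands (10
to 45 heavy atoms drawn from {C, N, O, S}, connected by 10 to 50 bonds,
with realistic 1.4–1.7 Å neighbor spacing). They are geometric stand-ins:
no attempt is made at chemically valid valences.

Every generator is a pure function of its arguments — the same inputs
always give a byte-identical molecule.
"""

from __future__ import annotations

import math
import random


from .chem import AtomRecord, BondRecord, Molecule
from .geometry import Vec3
from .scene import Cylinder, Sphere

__all__ = [
    "make_linear_alkane",
    "make_ring",
    "make_random_packing",
    "make_two_spheres",
    "make_crossed_cylinders",
    "write_sdf",
]

CC_BOND = 1.54          # Å, sp3 carbon-carbon
CH_BOND = 1.09          # Å
TETRAHEDRAL = math.radians(109.47)
MIN_PACKING_DISTANCE = 1.3   # Å, hard floor between packed atoms
MAX_PACKING_BONDS = 50       # bond-count cap in random packings

_TETRA_DIRS = (
    Vec3(1, 1, 1),
    Vec3(1, -1, -1),
    Vec3(-1, 1, -1),
    Vec3(-1, -1, 1),
)


def _hydrogen_directions(neighbors: list[Vec3], k: int) -> list[Vec3]:
    """Unit directions for k hydrogens on a carbon with the given bonded
    neighbor directions (unit vectors), approximately tetrahedral."""
    if not neighbors:
        return [d.normalized() for d in _TETRA_DIRS[:k]]
    mean = Vec3(
        sum(n.x for n in neighbors),
        sum(n.y for n in neighbors),
        sum(n.z for n in neighbors),
    )
    u = (mean * -1.0).normalized()
    if k == 1:
        return [u]
    if len(neighbors) >= 2:
        w = neighbors[0].cross(neighbors[1]).normalized()
    else:
        ref = Vec3(0, 0, 1) if abs(neighbors[0].z) < 0.9 else Vec3(0, 1, 0)
        w = neighbors[0].cross(ref).normalized()
    if k == 2:
        half = TETRAHEDRAL / 2.0
        return [
            (u * math.cos(half) + w * math.sin(half)).normalized(),
            (u * math.cos(half) - w * math.sin(half)).normalized(),
        ]
    # k == 3: terminal CH3 around the single neighbor direction
    n0 = neighbors[0]
    w2 = n0.cross(w).normalized()
    ca, sa = math.cos(TETRAHEDRAL), math.sin(TETRAHEDRAL)
    dirs = []
    for j in range(3):
        phi = 2.0 * math.pi * j / 3.0
        dirs.append(
            (n0 * ca + (w * math.cos(phi) + w2 * math.sin(phi)) * sa).normalized()
        )
    return dirs


def make_linear_alkane(n_heavy: int, with_hydrogens: bool = False) -> Molecule:
    """Idealized zig-zag carbon chain: C–C 1.54 Å, tetrahedral angles.

    Returns ``n_heavy`` carbons and ``n_heavy - 1`` skeleton bonds;
    ``with_hydrogens`` adds idealized hydrogens (C–H 1.09 Å) to fill each
    carbon's four coordination slots.
    """
    if n_heavy < 1:
        raise ValueError(f"need at least one heavy atom, got {n_heavy}")
    dx = CC_BOND * math.sin(TETRAHEDRAL / 2.0)
    dy = CC_BOND * math.cos(TETRAHEDRAL / 2.0)
    carbons = [Vec3(i * dx, (i % 2) * dy, 0.0) for i in range(n_heavy)]
    atoms = [
        AtomRecord(index=i, element="C", position=p) for i, p in enumerate(carbons)
    ]
    bonds = [
        BondRecord(start_index=i, end_index=i + 1) for i in range(n_heavy - 1)
    ]
    if with_hydrogens:
        next_id = n_heavy
        for i, c in enumerate(carbons):
            neigh = []
            if i > 0:
                neigh.append((carbons[i - 1] - c).normalized())
            if i < n_heavy - 1:
                neigh.append((carbons[i + 1] - c).normalized())
            k = 4 - len(neigh)
            for d in _hydrogen_directions(neigh, k):
                atoms.append(
                    AtomRecord(index=next_id, element="H", position=c + d * CH_BOND)
                )
                bonds.append(BondRecord(start_index=i, end_index=next_id))
                next_id += 1
    return Molecule(atoms=tuple(atoms), bonds=tuple(bonds),
                    name=f"alkane-{n_heavy}")


def make_ring(n_heavy: int) -> Molecule:
    """Planar regular carbon ring with 1.54 Å sides."""
    if n_heavy < 3:
        raise ValueError(f"a ring needs at least 3 atoms, got {n_heavy}")
    r = CC_BOND / (2.0 * math.sin(math.pi / n_heavy))
    atoms = []
    for i in range(n_heavy):
        ang = 2.0 * math.pi * i / n_heavy
        atoms.append(
            AtomRecord(
                index=i, element="C",
                position=Vec3(r * math.cos(ang), r * math.sin(ang), 0.0),
            )
        )
    bonds = [
        BondRecord(start_index=i, end_index=(i + 1) % n_heavy)
        for i in range(n_heavy)
    ]
    return Molecule(atoms=tuple(atoms), bonds=tuple(bonds), name=f"ring-{n_heavy}")


_PACKING_ELEMENTS = ("C",) * 14 + ("N",) * 2 + ("O",) * 3 + ("S",)


def make_random_packing(n_heavy: int, seed: int) -> Molecule:
    """Seeded drug-like random cluster: a connected packing of heavy atoms.

    Atoms are grown one at a time at a bonding distance (1.4–1.7 Å) from a
    random anchor atom, rejecting positions closer than 1.3 Å to any placed
    atom. Each new atom bonds to its anchor (guaranteeing one connected
    component and exactly ``n_heavy - 1`` base bonds); additional bonds are
    added between remaining close pairs, nearest first, up to a total of
    50. The result is a pure function of ``(n_heavy, seed)``.
    """
    if n_heavy < 2:
        raise ValueError(f"need at least 2 heavy atoms, got {n_heavy}")
    rng = random.Random(seed)
    positions: list[Vec3] = [Vec3(0.0, 0.0, 0.0)]
    bonds: list[BondRecord] = []
    while len(positions) < n_heavy:
        anchor = rng.randrange(len(positions))
        for _attempt in range(200):
            # uniform direction via normalized gaussian triple
            d = Vec3(rng.gauss(0, 1), rng.gauss(0, 1), rng.gauss(0, 1))
            if d.norm() < 1e-9:
                continue
            d = d.normalized()
            dist = rng.uniform(1.4, 1.7)
            cand = positions[anchor] + d * dist
            if all(cand.distance(p) >= MIN_PACKING_DISTANCE for p in positions):
                bonds.append(BondRecord(start_index=anchor,
                                        end_index=len(positions)))
                positions.append(cand)
                break
        else:
            anchor = rng.randrange(len(positions))  # re-anchor and keep trying
    bonded = {(b.start_index, b.end_index) for b in bonds}
    bonded |= {(j, i) for i, j in bonded}
    extras = []
    for i in range(n_heavy):
        for j in range(i + 1, n_heavy):
            if (i, j) in bonded:
                continue
            d = positions[i].distance(positions[j])
            if d < 1.7:
                extras.append((d, i, j))
    extras.sort()
    for d, i, j in extras:
        if len(bonds) >= MAX_PACKING_BONDS:
            break
        bonds.append(BondRecord(start_index=i, end_index=j))
    atoms = tuple(
        AtomRecord(index=i, element=rng.choice(_PACKING_ELEMENTS), position=p)
        for i, p in enumerate(positions)
    )
    return Molecule(atoms=atoms, bonds=tuple(bonds),
                    name=f"packing-{n_heavy}-{seed}")


def make_two_spheres(
    separation: float, r1: float = 1.0, r2: float = 1.0
) -> list[Sphere]:
    """Two spheres along z separated by ``separation``: the canonical
    occlusion test scene (far sphere at the origin, near sphere in front)."""
    return [
        Sphere(center=Vec3(0.0, 0.0, 0.0), radius=r1),
        Sphere(center=Vec3(0.0, 0.0, separation), radius=r2),
    ]


def make_crossed_cylinders(radius: float = 0.3) -> list[Cylinder]:
    """Two perpendicular crossing cylinders at different depths."""
    return [
        Cylinder(start=Vec3(-2, 0, -0.2), end=Vec3(2, 0, -0.2), radius=radius),
        Cylinder(start=Vec3(0, -2, 0.2), end=Vec3(0, 2, 0.2), radius=radius),
    ]


def write_sdf(mol: Molecule) -> str:
    """Write a molecule as a single V2000 molblock (``$$$$``-terminated).

    Coordinates are written at 4 decimals; ``parse_sdf`` round-trips the
    result exactly at that precision. The V2000 format caps records at 999
    atoms/bonds.
    """
    n_atoms, n_bonds = len(mol.atoms), len(mol.bonds)
    if n_atoms > 999 or n_bonds > 999:
        raise ValueError(
            f"V2000 molblocks hold at most 999 atoms/bonds, "
            f"got {n_atoms}/{n_bonds}"
        )
    if n_atoms == 0:
        raise ValueError("cannot write an empty molecule")
    id_map = {a.index: i + 1 for i, a in enumerate(mol.atoms)}
    lines = [
        mol.name or "",
        "  vecmol",
        "",
        f"{n_atoms:3d}{n_bonds:3d}  0  0  0  0  0  0  0  0999 V2000",
    ]
    for a in mol.atoms:
        p = a.position
        lines.append(
            f"{p.x:10.4f}{p.y:10.4f}{p.z:10.4f} {a.element:<3}"
            " 0  0  0  0  0  0  0  0  0  0  0  0"
        )
    for b in mol.bonds:
        lines.append(
            f"{id_map[b.start_index]:3d}{id_map[b.end_index]:3d}{b.order:3d}  0"
        )
    lines.append("M  END")
    lines.append("$$$$")
    return "\n".join(lines) + "\n"
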
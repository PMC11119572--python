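"""Chemistry-level input: atom/bond records, SDF (V2000) reading, and the
element color and radius tables.

The renderer needs nothing from chemistry beyond element symbol, 3D
position and connectivity, so charges, isotopes and stereo flags found in
molblocks are parsed-and-ignored. Only the V2000 molfile dialect is
accepted; V3000 blocks are rejected with a clear error rather than
silently misread.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable

from .geometry import Vec3

__all__ = [
    "AtomRecord",
    "BondRecord",
    "Molecule",
    "SdfParseError",
    "UnsupportedSdfDialectError",
    "parse_sdf",
    "element_color",
    "element_radius",
    "exclude_atoms",
    "FALLBACK_COLOR",
    "DEFAULT_RADIUS",
]

RGB = tuple[int, int, int]

#: Color returned for element symbols absent from the CPK table.
FALLBACK_COLOR: RGB = (255, 20, 147)

#: Radius (Å) returned for element symbols absent from the radius table.
DEFAULT_RADIUS: float = 1.50


@dataclass(frozen=True)
class AtomRecord:
    """One atom: unique index, element symbol, 3D position in Ångström.

    ``radius`` (Å), ``color`` (RGB 0–255) and ``opacity`` (0–1) override the
    element-table defaults for this atom only.
    """

    index: int
    element: str
    position: Vec3
    radius: float | None = None
    color: RGB | None = None
    opacity: float | None = None

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("atom element symbol must be non-empty")
        if self.opacity is not None and not 0.0 <= self.opacity <= 1.0:
            raise ValueError(f"atom opacity must be in [0, 1], got {self.opacity}")


@dataclass(frozen=True)
class BondRecord:
    """One bond between two atom indices, with an integer bond order."""

    start_index: int
    end_index: int
    order: int = 1
    radius: float | None = None
    color: RGB | None = None
    opacity: float | None = None

    def __post_init__(self) -> None:
        if self.start_index == self.end_index:
            raise ValueError(f"bond endpoints must differ, got {self.start_index} twice")
        if self.order < 1:
            raise ValueError(f"bond order must be a positive integer, got {self.order}")
        if self.opacity is not None and not 0.0 <= self.opacity <= 1.0:
            raise ValueError(f"bond opacity must be in [0, 1], got {self.opacity}")


@dataclass(frozen=True)
class Molecule:
    """Atoms plus bonds; the container an SDF record parses into."""

    atoms: tuple[AtomRecord, ...]
    bonds: tuple[BondRecord, ...] = ()
    name: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "atoms", tuple(self.atoms))
        object.__setattr__(self, "bonds", tuple(self.bonds))
        ids = [a.index for a in self.atoms]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate atom indices in molecule")
        known = set(ids)
        for b in self.bonds:
            if b.start_index not in known or b.end_index not in known:
                raise ValueError(
                    f"bond {b.start_index}-{b.end_index} references a missing atom"
                )

    def atom(self, index: int) -> AtomRecord:
        for a in self.atoms:
            if a.index == index:
                return a
        raise KeyError(index)


class SdfParseError(ValueError):
    """A molblock is internally inconsistent (counts vs. block contents)."""


class UnsupportedSdfDialectError(ValueError):
    """The molblock declares a connection-table dialect other than V2000."""


def _parse_molblock(lines: list[str], record_no: int, line_offset: int) -> Molecule:
    def fail(line_idx: int, msg: str) -> SdfParseError:
        return SdfParseError(
            f"record {record_no}, line {line_offset + line_idx + 1}: {msg}"
        )

    if len(lines) < 4:
        raise fail(len(lines), "molblock truncated before counts line")
    name = lines[0].strip() or None
    counts = lines[3]
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except (ValueError, IndexError):
        raise fail(3, f"unreadable counts line: {counts!r}") from None
    version = counts[33:39].strip() if len(counts) > 33 else ""
    if version and version.upper() != "V2000":
        raise UnsupportedSdfDialectError(
            f"record {record_no}: connection table dialect {version!r} is not "
            "supported (V2000 only)"
        )

    atoms: list[AtomRecord] = []
    for i in range(n_atoms):
        idx = 4 + i
        if idx >= len(lines):
            raise fail(len(lines), f"declared {n_atoms} atoms, found {i}")
        line = lines[idx]
        try:
            x = float(line[0:10])
            y = float(line[10:20])
            z = float(line[20:30])
            symbol = line[31:34].strip()
        except (ValueError, IndexError):
            raise fail(idx, f"declared {n_atoms} atoms, found {i} "
                            f"(unreadable atom line: {line!r})") from None
        if not symbol:
            raise fail(idx, f"empty element symbol in atom line: {line!r}")
        atoms.append(AtomRecord(index=i, element=symbol, position=Vec3(x, y, z)))

    bonds: list[BondRecord] = []
    for i in range(n_bonds):
        idx = 4 + n_atoms + i
        if idx >= len(lines):
            raise fail(len(lines), f"declared {n_bonds} bonds, found {i}")
        line = lines[idx]
        try:
            a = int(line[0:3])
            b = int(line[3:6])
            order = int(line[6:9])
        except (ValueError, IndexError):
            raise fail(idx, f"declared {n_bonds} bonds, found {i} "
                            f"(unreadable bond line: {line!r})") from None
        if not (1 <= a <= n_atoms) or not (1 <= b <= n_atoms):
            raise fail(idx, f"bond references atom out of range: {line!r}")
        # molfile indices are 1-based; internal ids are 0-based
        bonds.append(BondRecord(start_index=a - 1, end_index=b - 1,
                                order=max(order, 1)))
    return Molecule(atoms=tuple(atoms), bonds=tuple(bonds), name=name)


def parse_sdf(text: str) -> list[Molecule]:
    """Parse a (possibly multi-record) SDF document into Molecules.

    Records are separated by ``$$$$``; the final terminator is optional for
    a single record. The property block between ``M  END`` and the record
    separator is ignored.
    """
    molecules: list[Molecule] = []
    block: list[str] = []
    block_start = 0
    record_no = 0
    all_lines = text.splitlines()
    for i, raw in enumerate(all_lines + ["$$$$"]):
        if raw.strip() == "$$$$":
            if any(line.strip() for line in block):
                molecules.append(_parse_molblock(block, record_no, block_start))
                record_no += 1
            block = []
            block_start = i + 1
        else:
            block.append(raw)
    return molecules


def _load_table(filename: str) -> dict[str, list[str]]:
    table: dict[str, list[str]] = {}
    path = resources.files("vecmol.data").joinpath(filename)
    for raw in path.read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        table[parts[0]] = parts[1:]
    return table


_COLOR_TABLE: dict[str, RGB] | None = None
_RADIUS_TABLE: dict[str, float] | None = None


def element_color(element: str) -> RGB:
    """CPK-convention color for an element symbol.

    Unknown symbols return :data:`FALLBACK_COLOR` rather than raising, so a
    molecule with an exotic element still renders.
    """
    global _COLOR_TABLE
    if _COLOR_TABLE is None:
        _COLOR_TABLE = {
            sym: (int(v[0]), int(v[1]), int(v[2]))
            for sym, v in _load_table("cpk_colors.tsv").items()
        }
    return _COLOR_TABLE.get(element, FALLBACK_COLOR)


def element_radius(element: str) -> float:
    """Van der Waals radius (Å) for an element symbol.

    Unknown symbols return :data:`DEFAULT_RADIUS`.
    """
    global _RADIUS_TABLE
    if _RADIUS_TABLE is None:
        _RADIUS_TABLE = {
            sym: float(v[0]) for sym, v in _load_table("atomic_radii.tsv").items()
        }
    return _RADIUS_TABLE.get(element, DEFAULT_RADIUS)


def exclude_atoms(molecule: Molecule, symbols: Iterable[str]) -> Molecule:
    """Drop atoms whose element is in ``symbols``, plus their bonds.

    Matching is case-sensitive on the trimmed symbol (SDF symbols are
    canonical-case). Remaining atoms keep their original indices, so
    per-atom overrides keyed by index stay valid.
    """
    drop = {s.strip() for s in symbols}
    if not drop:
        return molecule
    kept_atoms = tuple(a for a in molecule.atoms if a.element not in drop)
    kept_ids = {a.index for a in kept_atoms}
    kept_bonds = tuple(
        b
        for b in molecule.bonds
        if b.start_index in kept_ids and b.end_index in kept_ids
    )
    return Molecule(atoms=kept_atoms, bonds=kept_bonds, name=molecule.name)
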
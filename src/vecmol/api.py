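"""The ``draw_molecule`` entry point: atoms + bonds in, SVG text out.

This is the uniform-style front door. It resolves CPK colors and element
radii (honoring per-atom/per-bond overrides), filters excluded elements,
builds the scene for the requested depiction style and look, renders, and
serializes. Users who want per-primitive control build a
:class:`~vecmol.scene.Scene` directly instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .chem import AtomRecord, BondRecord, Molecule, exclude_atoms as _exclude
from .depict import build_scene
from .geometry import RotationSpec
from .scene import render_scene
from .style import DepictionStyle, Look
from .svg import build_document, serialize

logger = logging.getLogger("vecmol")

__all__ = ["DrawRequest", "draw_molecule", "EmptyModelError"]


class EmptyModelError(ValueError):
    """Nothing left to draw (no atoms, or all atoms excluded)."""


@dataclass
class DrawRequest:
    """Bundle of every drawing parameter.

    ``atoms``, ``bonds``, ``style`` and ``look`` are required; everything
    else defaults to the documented behavior: resolution 50, no window
    (the SVG root carries only a viewBox), auto-computed view box, no
    rotation, scale 1.0, orthographic projection, no excluded elements,
    logger level ``info``.
    """

    atoms: Sequence[AtomRecord]
    bonds: Sequence[BondRecord]
    style: DepictionStyle
    look: Look
    resolution: int = 50
    window: tuple[float, float] | None = None
    view_box: tuple[float, float, float, float] | None = None
    rotation_over_x_axis: float = 0.0
    rotation_over_y_axis: float = 0.0
    rotation_over_z_axis: float = 0.0
    scale: float = 1.0
    focal_length: float | None = None
    exclude_atoms: Sequence[str] = field(default_factory=tuple)
    verbosity: int | str | None = None

    def __post_init__(self) -> None:
        if self.resolution < 1:
            raise ValueError(f"resolution must be >= 1, got {self.resolution}")
        if self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")


def draw_molecule(request: DrawRequest) -> str:
    """Render a molecule to SVG text according to the request.

    The output is a pure function of the request: repeated calls return
    byte-identical text. Raises :class:`EmptyModelError` when no atoms
    remain after exclusion.
    """
    if request.verbosity is not None:
        logger.setLevel(request.verbosity)

    mol = Molecule(atoms=tuple(request.atoms), bonds=tuple(request.bonds))
    if request.exclude_atoms:
        mol = _exclude(mol, request.exclude_atoms)
    if not mol.atoms:
        raise EmptyModelError("no atoms remain after exclusion; nothing to draw")

    scene = build_scene(
        mol,
        style=request.style,
        look=request.look,
        resolution=request.resolution,
        rotation=RotationSpec(
            request.rotation_over_x_axis,
            request.rotation_over_y_axis,
            request.rotation_over_z_axis,
        ),
        scale=request.scale,
        focal_length=request.focal_length,
    )
    items = render_scene(scene)
    if not items:
        raise EmptyModelError("every primitive was fully occluded or degenerate")
    logger.info("rendered %d of %d primitives", len(items), len(scene.nodes))
    doc = build_document(
        items, window=request.window, view_box=request.view_box
    )
    return serialize(doc)
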
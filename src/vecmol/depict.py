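"""Chemistry-to-geometry bridge: turn a Molecule into a styled Scene.

Four depiction types are supported:

* space-filling — one sphere per atom at its full van der Waals radius;
* ball-and-stick — reduced atom spheres plus thin bond cylinders;
* tube — thick round-capped bond cylinders, no atom spheres;
* wireframe — bare line segments per bond.

Bond color follows the nearer atom: every bond is split at its midpoint and
each half takes the color of its endpoint atom. Two looks are available:
cartoon (solid fill + outline stroke) and glossy (radial gradients on
spheres, linear gradients on cylinders). Wireframes are stroke-only and
look-independent.
"""

from __future__ import annotations

from functools import partial

from .chem import AtomRecord, Molecule, element_color, element_radius
from .geometry import CylinderCap, RotationSpec, Vec3
from .scene import Cylinder, Scene, SceneNode, Sphere, Wire
from .style import RGB, DepictionStyle, FillMode, Look, NodeStyle

__all__ = [
    "DepictionStyle",
    "Look",
    "build_scene",
    "node_policy",
    "BALL_RADIUS_FRACTION",
    "STICK_RADIUS",
    "TUBE_RADIUS",
    "WIRE_STROKE_WIDTH",
]

# Proportions chosen to visually match conventional molecular graphics;
# none are dictated by the rendering algorithm itself.
BALL_RADIUS_FRACTION = 0.33   # atom sphere shrink factor in ball-and-stick
STICK_RADIUS = 0.1            # bond cylinder radius (Å) in ball-and-stick
TUBE_RADIUS = 0.3             # bond cylinder radius (Å) in tube
WIRE_STROKE_WIDTH = 0.05      # wire stroke width in scene units
MARKER_HALF_LENGTH = 0.2      # cross-marker arm (Å) for isolated wire atoms


def node_policy(style: DepictionStyle, a: SceneNode, b: SceneNode) -> bool:
    """Whether an occlusion test should run for this node pair at all.

    Ball-and-stick skips cylinder/cylinder pairs: bond radii are so much
    smaller than atom radii that stick/stick intersections are hidden
    inside the atom spheres. Wireframe runs no tests (wires are only
    depth-sorted). Tube and space-filling test every volumetric pair.
    """
    if a.kind == "wire" or b.kind == "wire":
        return False
    if style is DepictionStyle.WIREFRAME:
        return False
    if (
        style is DepictionStyle.BALL_AND_STICK
        and a.kind == "cylinder"
        and b.kind == "cylinder"
    ):
        return False
    return True


def _sphere_style(look: Look, color: RGB, opacity: float) -> NodeStyle:
    mode = FillMode.RADIAL_GRADIENT if look is Look.GLOSSY else FillMode.SOLID
    return NodeStyle(fill_mode=mode, color=color, opacity=opacity)


def _cylinder_style(look: Look, color: RGB, opacity: float) -> NodeStyle:
    mode = FillMode.LINEAR_GRADIENT if look is Look.GLOSSY else FillMode.SOLID
    return NodeStyle(fill_mode=mode, color=color, opacity=opacity)


def _wire_style(color: RGB, opacity: float) -> NodeStyle:
    return NodeStyle(
        fill_mode=FillMode.STROKE_ONLY,
        color=color,
        opacity=opacity,
        stroke_color=color,
        stroke_width=WIRE_STROKE_WIDTH,
    )


def _atom_color(atom: AtomRecord) -> RGB:
    return atom.color if atom.color is not None else element_color(atom.element)


def _atom_opacity(atom: AtomRecord) -> float:
    return atom.opacity if atom.opacity is not None else 1.0


def _atom_radius(atom: AtomRecord) -> float:
    return atom.radius if atom.radius is not None else element_radius(atom.element)


def _cross_marker(center: Vec3, style: NodeStyle) -> list[Wire]:
    """Minimal visible marker for an atom with no incident bonds."""
    h = MARKER_HALF_LENGTH
    return [
        Wire((center + Vec3(-h, 0, 0), center + Vec3(h, 0, 0)), style=style),
        Wire((center + Vec3(0, -h, 0), center + Vec3(0, h, 0)), style=style),
        Wire((center + Vec3(0, 0, -h), center + Vec3(0, 0, h)), style=style),
    ]


def build_scene(
    mol: Molecule,
    style: DepictionStyle,
    look: Look,
    resolution: int = 50,
    rotation: RotationSpec = RotationSpec(),
    scale: float = 1.0,
    focal_length: float | None = None,
    filter_intersecting: bool = True,
) -> Scene:
    """Assemble the Scene for a molecule under a depiction style and look.

    Per-atom and per-bond radius/color/opacity overrides take precedence
    over the element tables. Bond order is accepted but does not change
    geometry: one (split) cylinder or wire per bond regardless of order.
    """
    if not isinstance(style, DepictionStyle):
        raise ValueError(f"unknown depiction style: {style!r}")
    if not isinstance(look, Look):
        raise ValueError(f"unknown look: {look!r}")

    atom_by_id = {a.index: a for a in mol.atoms}
    bonded_ids = set()
    for b in mol.bonds:
        bonded_ids.add(b.start_index)
        bonded_ids.add(b.end_index)

    nodes: list[SceneNode] = []

    if style in (DepictionStyle.SPACE_FILLING, DepictionStyle.BALL_AND_STICK):
        shrink = 1.0 if style is DepictionStyle.SPACE_FILLING else BALL_RADIUS_FRACTION
        for a in mol.atoms:
            nodes.append(
                Sphere(
                    center=a.position,
                    radius=_atom_radius(a) * shrink,
                    style=_sphere_style(look, _atom_color(a), _atom_opacity(a)),
                )
            )

    if style in (DepictionStyle.BALL_AND_STICK, DepictionStyle.TUBE):
        default_radius = (
            STICK_RADIUS if style is DepictionStyle.BALL_AND_STICK else TUBE_RADIUS
        )
        cap = (
            CylinderCap.ROUND if style is DepictionStyle.TUBE else CylinderCap.NONE
        )
        for b in mol.bonds:
            a1 = atom_by_id[b.start_index]
            a2 = atom_by_id[b.end_index]
            mid = (a1.position + a2.position) * 0.5
            radius = b.radius if b.radius is not None else default_radius
            for a, seg in ((a1, (a1.position, mid)), (a2, (mid, a2.position))):
                color = b.color if b.color is not None else _atom_color(a)
                opacity = b.opacity if b.opacity is not None else _atom_opacity(a)
                nodes.append(
                    Cylinder(
                        start=seg[0],
                        end=seg[1],
                        radius=radius,
                        cap=cap,
                        style=_cylinder_style(look, color, opacity),
                    )
                )
        if style is DepictionStyle.TUBE:
            for a in mol.atoms:
                if a.index not in bonded_ids:
                    nodes.append(
                        Sphere(
                            center=a.position,
                            radius=min(TUBE_RADIUS, _atom_radius(a)),
                            style=_sphere_style(look, _atom_color(a),
                                                _atom_opacity(a)),
                        )
                    )

    if style is DepictionStyle.WIREFRAME:
        for b in mol.bonds:
            a1 = atom_by_id[b.start_index]
            a2 = atom_by_id[b.end_index]
            mid = (a1.position + a2.position) * 0.5
            for a, seg in ((a1, (a1.position, mid)), (a2, (mid, a2.position))):
                color = b.color if b.color is not None else _atom_color(a)
                opacity = b.opacity if b.opacity is not None else _atom_opacity(a)
                nodes.append(Wire(seg, style=_wire_style(color, opacity)))
        for a in mol.atoms:
            if a.index not in bonded_ids:
                nodes.extend(
                    _cross_marker(
                        a.position, _wire_style(_atom_color(a), _atom_opacity(a))
                    )
                )

    return Scene(
        nodes=nodes,
        resolution=resolution,
        rotation=rotation,
        scale=scale,
        focal_length=focal_length,
        filter_intersecting=filter_intersecting,
        pair_policy=partial(node_policy, style),
    )
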
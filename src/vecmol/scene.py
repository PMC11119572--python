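"""Scene graph and the six-step rendering pipeline.

A :class:`Scene` holds styled primitives (spheres, cylinders, wires) plus
global parameters. :func:`render_scene` turns it into 2D draw items by:

1. sampling surface points on every primitive (density set by
   ``resolution``),
2. sorting primitives far-to-near by centroid z and discarding, for each
   primitive, the sampled points that lie inside an earlier (farther)
   primitive's volume — those surface patches sit behind an occluder whose
   polygon would cover them anyway,
3. projecting the surviving points (orthographic, or perspective when a
   focal length is set),
4. dropping the z coordinate,
5. hulling each projected cloud with quickhull, and
6. emitting the polygons in the far-to-near order for painter's-algorithm
   drawing.

Occlusion is approximate by design: no polygon splitting, no ray tracing.
The per-point containment tests are preceded by a cheap vicinity check
(sum of radii against center/axis distances) that can be switched off via
``filter_intersecting=False`` when every intersection must be resolved
exactly at the cost of speed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence, Union

from .geometry import (
    CylinderCap,
    RotationSpec,
    Vec2,
    Vec3,
    cylinder_points,
    inside_cylinder,
    inside_sphere,
    point_segment_distance,
    project,
    rotate_points,
    segment_segment_distance,
    sphere_points,
)
from .hull import quickhull
from .style import FillMode, NodeStyle

logger = logging.getLogger("vecmol")

__all__ = [
    "Sphere",
    "Cylinder",
    "Wire",
    "SceneNode",
    "Scene",
    "DrawItem",
    "sort_nodes",
    "may_intersect",
    "surface_points",
    "visible_points",
    "render_scene",
]


@dataclass(frozen=True)
class Sphere:
    center: Vec3
    radius: float
    style: NodeStyle = NodeStyle()

    kind = "sphere"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"sphere radius must be positive, got {self.radius}")

    def centroid(self) -> Vec3:
        return self.center

    def transformed(self, rot: RotationSpec, scale: float) -> "Sphere":
        (c,) = rotate_points([self.center], rot)
        return replace(self, center=c * scale, radius=self.radius * scale)


@dataclass(frozen=True)
class Cylinder:
    start: Vec3
    end: Vec3
    radius: float
    cap: CylinderCap = CylinderCap.NONE
    style: NodeStyle = NodeStyle()

    kind = "cylinder"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"cylinder radius must be positive, got {self.radius}")
        if self.start.distance(self.end) == 0.0:
            raise ValueError("degenerate cylinder: start == end")

    def centroid(self) -> Vec3:
        return (self.start + self.end) * 0.5

    def transformed(self, rot: RotationSpec, scale: float) -> "Cylinder":
        s, e = rotate_points([self.start, self.end], rot)
        return replace(self, start=s * scale, end=e * scale,
                       radius=self.radius * scale)


@dataclass(frozen=True)
class Wire:
    """Polyline primitive: depth-sorted and drawn as a stroke, never hulled
    and never occlusion-filtered (it has no volume)."""

    points: tuple[Vec3, ...]
    style: NodeStyle = NodeStyle(fill_mode=FillMode.STROKE_ONLY)

    kind = "wire"

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))
        if len(self.points) < 2:
            raise ValueError("wire needs at least 2 points")

    def centroid(self) -> Vec3:
        n = len(self.points)
        sx = sum(p.x for p in self.points)
        sy = sum(p.y for p in self.points)
        sz = sum(p.z for p in self.points)
        return Vec3(sx / n, sy / n, sz / n)

    def transformed(self, rot: RotationSpec, scale: float) -> "Wire":
        pts = tuple(p * scale for p in rotate_points(self.points, rot))
        return replace(self, points=pts)


SceneNode = Union[Sphere, Cylinder, Wire]

#: Pair policy: given (node being filtered, earlier node), return whether the
#: occlusion test for this pair should run at all. ``None`` tests every pair
#: of volumetric primitives.
PairPolicy = Callable[[SceneNode, SceneNode], bool]


@dataclass
class Scene:
    """A renderable collection of styled primitives.

    ``rotation`` and ``scale`` transform the whole model about the origin
    before anything is sampled; ``scale`` multiplies radii as well as
    coordinates so proportions survive. ``focal_length=None`` means
    orthographic projection.
    """

    nodes: list[SceneNode] = field(default_factory=list)
    resolution: int = 50
    rotation: RotationSpec = RotationSpec()
    scale: float = 1.0
    focal_length: float | None = None
    filter_intersecting: bool = True
    pair_policy: PairPolicy | None = None

    def __post_init__(self) -> None:
        if self.resolution < 1:
            raise ValueError(f"resolution must be >= 1, got {self.resolution}")
        if self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")


@dataclass(frozen=True)
class DrawItem:
    """One drawable: a convex polygon (closed) or a wire polyline (open),
    tagged with its pre-projection centroid depth for painter's order."""

    points: tuple[Vec2, ...]
    style: NodeStyle
    depth: float
    closed: bool = True


def sort_nodes(nodes: Sequence[SceneNode]) -> list[SceneNode]:
    """Far-to-near painter's order: ascending centroid z, stable for ties."""
    return sorted(nodes, key=lambda n: n.centroid().z)


def may_intersect(a: SceneNode, b: SceneNode) -> bool:
    """Cheap vicinity pre-check; ``False`` means provably disjoint volumes.

    Sphere centers and cylinder axes are compared against the sum of radii.
    Exact for sphere/sphere and sphere/cylinder; conservative (never a
    false negative) for cylinder/cylinder. Wires have no volume and never
    intersect anything.
    """
    if a.kind == "wire" or b.kind == "wire":
        return False
    if a.kind == "sphere" and b.kind == "sphere":
        return a.center.distance(b.center) < a.radius + b.radius
    if a.kind == "sphere":
        a, b = b, a
    # a is a cylinder now
    if b.kind == "sphere":
        return point_segment_distance(b.center, a.start, a.end) < a.radius + b.radius
    return segment_segment_distance(a.start, a.end, b.start, b.end) < a.radius + b.radius


def surface_points(node: SceneNode, resolution: int) -> list[Vec3]:
    """Raw sampled surface point cloud for a node (wires pass through)."""
    if node.kind == "sphere":
        return sphere_points(node.center, node.radius, resolution)
    if node.kind == "cylinder":
        return cylinder_points(node.start, node.end, node.radius, resolution, node.cap)
    return list(node.points)


def _occludes(blocker: SceneNode, p: Vec3) -> bool:
    if blocker.kind == "sphere":
        return inside_sphere(p, blocker.center, blocker.radius)
    if blocker.kind == "cylinder":
        return inside_cylinder(p, blocker.start, blocker.end, blocker.radius)
    return False


def visible_points(
    node: SceneNode,
    earlier: Sequence[SceneNode],
    filter_intersecting: bool = True,
    resolution: int = 50,
    pair_policy: PairPolicy | None = None,
) -> list[Vec3]:
    """Sample a node's surface and drop points occluded by earlier nodes.

    ``earlier`` must contain only nodes sorted before this one (farther from
    the viewer); their surfaces sit in front of the patches of ``node`` that
    fall inside their volume, so those sampled points are discarded. With
    ``filter_intersecting`` the per-point tests only run against earlier
    nodes that pass the :func:`may_intersect` vicinity check; switching it
    off tests against every earlier volumetric node.
    """
    pts = surface_points(node, resolution)
    if node.kind == "wire":
        return pts
    blockers = []
    for e in earlier:
        if e.kind == "wire":
            continue
        if pair_policy is not None and not pair_policy(node, e):
            continue
        if filter_intersecting and not may_intersect(node, e):
            continue
        blockers.append(e)
    if not blockers:
        return pts
    kept = []
    for p in pts:
        for e in blockers:
            if _occludes(e, p):
                break
        else:
            kept.append(p)
    return kept


def render_scene(scene: Scene) -> list[DrawItem]:
    """Run the full pipeline and return draw items in painter's order."""
    transformed = [n.transformed(scene.rotation, scene.scale) for n in scene.nodes]
    ordered = sort_nodes(transformed)
    items: list[DrawItem] = []
    for i, node in enumerate(ordered):
        depth = node.centroid().z
        if node.kind == "wire":
            pts2 = tuple(project(p, scene.focal_length) for p in node.points)
            items.append(DrawItem(points=pts2, style=node.style,
                                  depth=depth, closed=False))
            continue
        pts = visible_points(
            node,
            ordered[:i],
            filter_intersecting=scene.filter_intersecting,
            resolution=scene.resolution,
            pair_policy=scene.pair_policy,
        )
        if len(pts) < 3:
            logger.debug("node %d fully occluded (%d visible points), skipped",
                         i, len(pts))
            continue
        projected = [project(p, scene.focal_length) for p in pts]
        poly = quickhull(projected)
        if poly.degenerate:
            logger.debug("node %d collapsed to a degenerate hull, skipped", i)
            continue
        items.append(DrawItem(points=poly.vertices, style=node.style,
                              depth=depth, closed=True))
    return items
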
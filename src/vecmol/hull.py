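"""2D convex hull via quickhull.

Each scene item's projected surface points are reduced to their smallest
encapsulating polygon; the polygons are what the SVG finally contains, so
hull vertex counts directly drive file size. Collinear points on a hull
edge are dropped (strict convexity) to keep polygons minimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .geometry import Vec2

__all__ = ["Polygon2D", "quickhull", "polygon_area"]


@dataclass(frozen=True)
class Polygon2D:
    """Convex outline of a projected point cloud.

    Vertices are in counter-clockwise order (y up), starting from the
    lexicographically smallest vertex. ``degenerate`` marks clouds that
    collapse to a point or a line; the renderer skips those or draws a
    segment instead of a polygon.
    """

    vertices: tuple[Vec2, ...]
    degenerate: bool = False


def _cross(o: tuple[float, float], a: tuple[float, float], b: tuple[float, float]) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def _find_hull(
    pts: list[tuple[float, float]],
    a: tuple[float, float],
    b: tuple[float, float],
) -> list[tuple[float, float]]:
    """Points of the hull chain strictly right of directed edge a→b."""
    if not pts:
        return []
    # farthest from the line; ties broken lexicographically for determinism
    c = min(pts, key=lambda p: (_cross(a, b, p), p))
    left: list[tuple[float, float]] = []
    right: list[tuple[float, float]] = []
    for p in pts:
        if p == c:
            continue
        if _cross(a, c, p) < 0.0:
            left.append(p)
        elif _cross(c, b, p) < 0.0:
            right.append(p)
    return _find_hull(left, a, c) + [c] + _find_hull(right, c, b)


def quickhull(points: Sequence[Vec2]) -> Polygon2D:
    """Smallest convex polygon enclosing ``points``.

    Returns vertices counter-clockwise starting from the lexicographically
    smallest input point. Hull vertices are a subset of the input; interior
    and edge-collinear points are dropped. Degenerate inputs (all points
    equal, or all collinear) return the extreme points with the degenerate
    flag set.
    """
    if not points:
        raise ValueError("quickhull requires at least one point")
    uniq = sorted({(p.x, p.y) for p in points})
    if len(uniq) == 1:
        return Polygon2D((Vec2(*uniq[0]),), degenerate=True)
    a, b = uniq[0], uniq[-1]
    below = [p for p in uniq if _cross(a, b, p) < 0.0]
    above = [p for p in uniq if _cross(a, b, p) > 0.0]
    if not below and not above:
        return Polygon2D((Vec2(*a), Vec2(*b)), degenerate=True)
    chain = [a] + _find_hull(below, a, b) + [b] + _find_hull(above, b, a)
    return Polygon2D(tuple(Vec2(*p) for p in chain))


def polygon_area(poly: Polygon2D) -> float:
    """Shoelace area; counter-clockwise vertices give a positive value."""
    verts = poly.vertices
    n = len(verts)
    if n < 3:
        return 0.0
    acc = 0.0
    for i in range(n):
        p, q = verts[i], verts[(i + 1) % n]
        acc += p.x * q.y - q.x * p.y
    return acc / 2.0
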
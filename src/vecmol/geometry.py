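"""3D vector math and surface sampling for the rendering pipeline.

Everything here is pure computation on immutable-ish value types: rigid
rotations about the scene origin, uniform surface grids on spheres and
cylinders, containment predicates used for occlusion filtering, and the
projection from scene space onto the 2D canvas.

Camera convention: the viewer sits on the positive z side looking toward
the origin, so larger z means nearer to the viewer. Every depth-dependent
step in the package (sorting, occlusion, perspective) uses this convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

__all__ = [
    "Vec3",
    "Vec2",
    "RotationSpec",
    "CylinderCap",
    "rotate_points",
    "sphere_points",
    "cylinder_points",
    "inside_sphere",
    "inside_cylinder",
    "point_segment_distance",
    "segment_segment_distance",
    "project",
]


@dataclass(slots=True)
class Vec3:
    """A point or direction in scene space (Ångström × scale)."""

    x: float
    y: float
    z: float

    def __add__(self, other: "Vec3") -> "Vec3":
        return Vec3(self.x + other.x, self.y + other.y, self.z + other.z)

    def __sub__(self, other: "Vec3") -> "Vec3":
        return Vec3(self.x - other.x, self.y - other.y, self.z - other.z)

    def __mul__(self, s: float) -> "Vec3":
        return Vec3(self.x * s, self.y * s, self.z * s)

    __rmul__ = __mul__

    def dot(self, other: "Vec3") -> float:
        return self.x * other.x + self.y * other.y + self.z * other.z

    def cross(self, other: "Vec3") -> "Vec3":
        return Vec3(
            self.y * other.z - self.z * other.y,
            self.z * other.x - self.x * other.z,
            self.x * other.y - self.y * other.x,
        )

    def norm(self) -> float:
        return math.sqrt(self.x * self.x + self.y * self.y + self.z * self.z)

    def distance(self, other: "Vec3") -> float:
        dx = self.x - other.x
        dy = self.y - other.y
        dz = self.z - other.z
        return math.sqrt(dx * dx + dy * dy + dz * dz)

    def normalized(self) -> "Vec3":
        n = self.norm()
        if n == 0.0:
            raise ValueError("cannot normalize the zero vector")
        return Vec3(self.x / n, self.y / n, self.z / n)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass(slots=True)
class Vec2:
    """A projected point on the 2D canvas."""

    x: float
    y: float

    def __add__(self, other: "Vec2") -> "Vec2":
        return Vec2(self.x + other.x, self.y + other.y)

    def __sub__(self, other: "Vec2") -> "Vec2":
        return Vec2(self.x - other.x, self.y - other.y)

    def as_tuple(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass(frozen=True)
class RotationSpec:
    """Rigid model rotation, angles in radians, applied X then Y then Z."""

    over_x: float = 0.0
    over_y: float = 0.0
    over_z: float = 0.0


class CylinderCap(Enum):
    NONE = "none"
    ROUND = "round"


def _snap(v: float) -> float:
    """Snap sines/cosines to exact -1, 0, 1 when within float noise.

    Keeps angles that are exact multiples of π/2 (including full turns)
    producing exact rotation matrices, so e.g. a 2π rotation is a byte-level
    identity for the whole pipeline.
    """
    r = round(v)
    return float(r) if abs(v - r) < 1e-12 else v


def _rotation_coefficients(rot: RotationSpec) -> tuple[float, ...]:
    """Row-major coefficients of Rz @ Ry @ Rx (X applied first)."""
    cx, sx = _snap(math.cos(rot.over_x)), _snap(math.sin(rot.over_x))
    cy, sy = _snap(math.cos(rot.over_y)), _snap(math.sin(rot.over_y))
    cz, sz = _snap(math.cos(rot.over_z)), _snap(math.sin(rot.over_z))
    return (
        cz * cy,
        cz * sy * sx - sz * cx,
        cz * sy * cx + sz * sx,
        sz * cy,
        sz * sy * sx + cz * cx,
        sz * sy * cx - cz * sx,
        -sy,
        cy * sx,
        cy * cx,
    )


def rotate_points(points: Sequence[Vec3], rot: RotationSpec) -> list[Vec3]:
    """Rotate a point cloud rigidly about the scene origin.

    The per-axis angles are composed in the fixed order X, then Y, then Z.
    Pairwise distances are preserved exactly (up to floating point).
    """
    m00, m01, m02, m10, m11, m12, m20, m21, m22 = _rotation_coefficients(rot)
    out = []
    for p in points:
        x, y, z = p.x, p.y, p.z
        out.append(
            Vec3(
                m00 * x + m01 * y + m02 * z,
                m10 * x + m11 * y + m12 * z,
                m20 * x + m21 * y + m22 * z,
            )
        )
    return out


def sphere_points(center: Vec3, radius: float, resolution: int) -> list[Vec3]:
    """Sample a uniform angular grid on a sphere surface.

    The grid takes ``resolution + 1`` azimuthal angles over [0, 2π] times
    ``resolution + 1`` polar angles over [0, π], both inclusive, for exactly
    ``(resolution + 1)**2`` points. Seam and pole duplicates are kept; they
    are harmless to the convex hull and keep the count exact.
    """
    if radius <= 0:
        raise ValueError(f"sphere radius must be positive, got {radius}")
    if resolution < 1:
        raise ValueError(f"resolution must be >= 1, got {resolution}")
    cx, cy, cz = center.x, center.y, center.z
    pts: list[Vec3] = []
    n = resolution
    for i in range(n + 1):
        theta = math.pi * i / n
        st = math.sin(theta)
        rz = radius * math.cos(theta)
        for j in range(n + 1):
            phi = 2.0 * math.pi * j / n
            pts.append(
                Vec3(
                    cx + radius * st * math.cos(phi),
                    cy + radius * st * math.sin(phi),
                    cz + rz,
                )
            )
    return pts


def _perpendicular_basis(axis: Vec3) -> tuple[Vec3, Vec3]:
    """Deterministic orthonormal pair perpendicular to ``axis`` (unit)."""
    ref = Vec3(1.0, 0.0, 0.0) if abs(axis.x) <= 0.9 else Vec3(0.0, 1.0, 0.0)
    v = axis.cross(ref).normalized()
    w = axis.cross(v)
    return v, w


def _hemisphere_points(
    center: Vec3, radius: float, outward: Vec3, resolution: int
) -> list[Vec3]:
    """Round-cap sampling: the half of a sphere grid facing ``outward``."""
    pts = sphere_points(center, radius, resolution)
    ox, oy, oz = outward.x, outward.y, outward.z
    return [
        p
        for p in pts
        if (p.x - center.x) * ox + (p.y - center.y) * oy + (p.z - center.z) * oz
        >= -1e-12
    ]


def cylinder_points(
    start: Vec3,
    end: Vec3,
    radius: float,
    resolution: int,
    cap: CylinderCap = CylinderCap.NONE,
) -> list[Vec3]:
    """Sample the lateral surface of a cylinder, optionally round-capped.

    ``resolution + 1`` circle centers are placed uniformly along the axis
    from start to end; each circle contributes ``resolution`` points on the
    circumference, so the body has ``(resolution + 1) * resolution`` points.
    A round cap appends the outward-facing hemisphere point grid (sampled at
    the same resolution) at each end.
    """
    if radius <= 0:
        raise ValueError(f"cylinder radius must be positive, got {radius}")
    if resolution < 1:
        raise ValueError(f"resolution must be >= 1, got {resolution}")
    axis = end - start
    length = axis.norm()
    if length == 0.0:
        raise ValueError("degenerate cylinder: start == end")
    u = Vec3(axis.x / length, axis.y / length, axis.z / length)
    v, w = _perpendicular_basis(u)

    n = resolution
    pts: list[Vec3] = []
    circle = []
    for k in range(n):
        alpha = 2.0 * math.pi * k / n
        ca, sa = math.cos(alpha), math.sin(alpha)
        circle.append(
            Vec3(
                radius * (ca * v.x + sa * w.x),
                radius * (ca * v.y + sa * w.y),
                radius * (ca * v.z + sa * w.z),
            )
        )
    for i in range(n + 1):
        t = length * i / n
        c = Vec3(start.x + u.x * t, start.y + u.y * t, start.z + u.z * t)
        for q in circle:
            pts.append(Vec3(c.x + q.x, c.y + q.y, c.z + q.z))

    if cap is CylinderCap.ROUND:
        pts.extend(_hemisphere_points(start, radius, Vec3(-u.x, -u.y, -u.z), n))
        pts.extend(_hemisphere_points(end, radius, u, n))
    return pts


def inside_sphere(p: Vec3, center: Vec3, radius: float) -> bool:
    """Strict containment: points exactly on the surface are outside.

    The strict inequality means tangent surfaces never delete each other's
    silhouette points during occlusion filtering.
    """
    dx = p.x - center.x
    dy = p.y - center.y
    dz = p.z - center.z
    return dx * dx + dy * dy + dz * dz < radius * radius


def inside_cylinder(p: Vec3, start: Vec3, end: Vec3, radius: float) -> bool:
    """Strict containment in the open finite cylinder around segment start-end."""
    ax = end.x - start.x
    ay = end.y - start.y
    az = end.z - start.z
    length_sq = ax * ax + ay * ay + az * az
    if length_sq == 0.0:
        raise ValueError("degenerate cylinder: start == end")
    px = p.x - start.x
    py = p.y - start.y
    pz = p.z - start.z
    t = (px * ax + py * ay + pz * az) / length_sq
    if t <= 0.0 or t >= 1.0:
        return False
    dx = px - t * ax
    dy = py - t * ay
    dz = pz - t * az
    return dx * dx + dy * dy + dz * dz < radius * radius


def point_segment_distance(p: Vec3, a: Vec3, b: Vec3) -> float:
    """Distance from a point to the closed segment [a, b]."""
    ab = b - a
    denom = ab.dot(ab)
    if denom == 0.0:
        return p.distance(a)
    t = (p - a).dot(ab) / denom
    t = 0.0 if t < 0.0 else (1.0 if t > 1.0 else t)
    return p.distance(Vec3(a.x + ab.x * t, a.y + ab.y * t, a.z + ab.z * t))


def segment_segment_distance(a1: Vec3, a2: Vec3, b1: Vec3, b2: Vec3) -> float:
    """Minimal Euclidean distance between two closed segments.

    Degenerate segments (coincident endpoints) are treated as points. The
    clamped closest-point formulation follows the standard robust treatment
    of the parallel and near-parallel cases.
    """
    d1 = a2 - a1
    d2 = b2 - b1
    r = a1 - b1
    a = d1.dot(d1)
    e = d2.dot(d2)
    f = d2.dot(r)

    if a == 0.0 and e == 0.0:
        return a1.distance(b1)
    if a == 0.0:
        t = min(1.0, max(0.0, f / e))
        return a1.distance(Vec3(b1.x + d2.x * t, b1.y + d2.y * t, b1.z + d2.z * t))
    c = d1.dot(r)
    if e == 0.0:
        s = min(1.0, max(0.0, -c / a))
        return b1.distance(Vec3(a1.x + d1.x * s, a1.y + d1.y * s, a1.z + d1.z * s))

    b = d1.dot(d2)
    denom = a * e - b * b
    if denom > 0.0:
        s = min(1.0, max(0.0, (b * f - c * e) / denom))
    else:  # parallel
        s = 0.0
    t = (b * s + f) / e
    if t < 0.0:
        t = 0.0
        s = min(1.0, max(0.0, -c / a))
    elif t > 1.0:
        t = 1.0
        s = min(1.0, max(0.0, (b - c) / a))
    pa = Vec3(a1.x + d1.x * s, a1.y + d1.y * s, a1.z + d1.z * s)
    pb = Vec3(b1.x + d2.x * t, b1.y + d2.y * t, b1.z + d2.z * t)
    return pa.distance(pb)


def project(p: Vec3, focal_length: float | None = None) -> Vec2:
    """Project a scene point onto the canvas, dropping depth.

    With no focal length the projection is orthographic: (x, y) pass through
    unchanged. With focal length f the perspective mapping is
    ``(x·f/(f−z), y·f/(f−z))``: nearer points (larger z, under the
    positive-z camera convention) are magnified more, and a smaller f
    exaggerates the size difference between near and far items.
    """
    if focal_length is None:
        return Vec2(p.x, p.y)
    denom = focal_length - p.z
    if denom <= 0.0:
        raise ValueError(
            f"point at z={p.z} is at or behind the focal plane (f={focal_length})"
        )
    s = focal_length / denom
    return Vec2(p.x * s, p.y * s)
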
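import math
import random

import pytest

from vecmol.fixtures import make_crossed_cylinders, make_two_spheres
from vecmol.geometry import CylinderCap, RotationSpec, Vec3, inside_sphere
from vecmol.hull import Polygon2D, polygon_area
from vecmol.scene import (
    Cylinder,
    Scene,
    Sphere,
    Wire,
    may_intersect,
    render_scene,
    sort_nodes,
    surface_points,
    visible_points,
)
from vecmol.style import FillMode, NodeStyle


def sphere_at(z, r=1.0, x=0.0):
    return Sphere(center=Vec3(x, 0.0, z), radius=r)


class TestSorting:
    def test_ascending_centroid_z(self):
        nodes = [sphere_at(2.0), sphere_at(-1.0), sphere_at(0.0)]
        assert [n.centroid().z for n in sort_nodes(nodes)] == [-1.0, 0.0, 2.0]

    def test_stable_for_equal_depth(self):
        a, b = sphere_at(1.0, x=-1.0), sphere_at(1.0, x=1.0)
        assert sort_nodes([a, b]) == [a, b]
        assert sort_nodes([b, a]) == [b, a]

    def test_single_node(self):
        n = sphere_at(0.5)
        assert sort_nodes([n]) == [n]

    def test_cylinder_centroid_is_axis_midpoint(self):
        c = Cylinder(start=Vec3(0, 0, 0), end=Vec3(0, 0, 4), radius=0.5)
        assert c.centroid().as_tuple() == (0, 0, 2)


class TestMayIntersect:
    def test_disjoint_unit_spheres(self):
        assert not may_intersect(sphere_at(0.0), sphere_at(3.0))

    def test_overlapping_unit_spheres(self):
        assert may_intersect(sphere_at(0.0), sphere_at(1.5))

    def test_tangent_spheres_do_not_intersect(self):
        assert not may_intersect(sphere_at(0.0), sphere_at(2.0))

    def test_sphere_cylinder_and_cylinder_cylinder(self):
        cyl = Cylinder(start=Vec3(-2, 0, 0), end=Vec3(2, 0, 0), radius=0.5)
        assert may_intersect(cyl, Sphere(center=Vec3(0, 1.0, 0), radius=0.6))
        assert not may_intersect(cyl, Sphere(center=Vec3(0, 2.0, 0), radius=0.5))
        a, b = make_crossed_cylinders(radius=0.3)
        assert may_intersect(a, b)

    def test_wires_never_flagged(self):
        w = Wire((Vec3(0, 0, 0), Vec3(1, 0, 0)))
        assert not may_intersect(w, sphere_at(0.0))

    def test_no_false_negatives_against_grid_oracle(self):
        rng = random.Random(17)
        for _ in range(30):
            a = Sphere(
                center=Vec3(rng.uniform(-1, 1), rng.uniform(-1, 1), rng.uniform(-1, 1)),
                radius=rng.uniform(0.3, 1.2),
            )
            b = Cylinder(
                start=Vec3(rng.uniform(-2, 2), rng.uniform(-2, 2), rng.uniform(-2, 2)),
                end=Vec3(rng.uniform(-2, 2), rng.uniform(-2, 2), rng.uniform(-2, 2)),
                radius=rng.uniform(0.2, 0.8),
            )
            if b.start.distance(b.end) < 1e-6:
                continue
            overlap_found = False
            n = 24
            for i in range(n):
                for j in range(n):
                    for k in range(n):
                        p = Vec3(-2 + 4 * i / (n - 1), -2 + 4 * j / (n - 1),
                                 -2 + 4 * k / (n - 1))
                        if inside_sphere(p, a.center, a.radius):
                            from vecmol.geometry import inside_cylinder
                            if inside_cylinder(p, b.start, b.end, b.radius):
                                overlap_found = True
                                break
                    if overlap_found:
                        break
                if overlap_found:
                    break
            if overlap_found:
                assert may_intersect(a, b)


class TestVisiblePoints:
    def test_lone_node_keeps_all_samples(self):
        node = sphere_at(0.0)
        pts = visible_points(node, earlier=[], resolution=10)
        assert len(pts) == len(surface_points(node, 10))

    def test_discarded_points_are_inside_far_sphere(self):
        far, near = make_two_spheres(0.8)
        kept = visible_points(near, earlier=[far], resolution=20)
        sampled = surface_points(near, 20)
        assert len(kept) < len(sampled)
        kept_set = {p.as_tuple() for p in kept}
        for p in sampled:
            if p.as_tuple() not in kept_set:
                assert inside_sphere(p, far.center, far.radius)
            else:
                assert not inside_sphere(p, far.center, far.radius)

    def test_prefilter_is_no_op_on_distant_spheres(self):
        nodes = [sphere_at(0.0), sphere_at(5.0), sphere_at(10.0)]
        for i, node in enumerate(nodes):
            with_filter = visible_points(node, nodes[:i], True, 12)
            without = visible_points(node, nodes[:i], False, 12)
            assert [p.as_tuple() for p in with_filter] == [
                p.as_tuple() for p in without
            ]


class TestRenderScene:
    def test_single_sphere_gives_one_enclosing_polygon(self):
        scene = Scene(nodes=[sphere_at(0.0)], resolution=8)
        items = render_scene(scene)
        assert len(items) == 1
        xs = [p.x for p in items[0].points]
        ys = [p.y for p in items[0].points]
        assert min(xs) < 0 < max(xs) and min(ys) < 0 < max(ys)

    def test_disjoint_spheres_drawn_far_to_near(self):
        scene = Scene(nodes=[sphere_at(2.0), sphere_at(-2.0)], resolution=8)
        items = render_scene(scene)
        assert [it.depth for it in items] == [-2.0, 2.0]

    def test_fully_contained_near_sphere_vanishes(self):
        far = Sphere(center=Vec3(0, 0, 0), radius=2.0)
        near = Sphere(center=Vec3(0, 0, 0.5), radius=0.4)  # wholly inside far
        items = render_scene(Scene(nodes=[far, near], resolution=10))
        assert len(items) == 1

    def test_draw_order_is_ascending_depth_on_random_scenes(self):
        rng = random.Random(23)
        for _ in range(10):
            nodes = [
                sphere_at(rng.uniform(-5, 5), r=rng.uniform(0.2, 1.0),
                          x=rng.uniform(-5, 5))
                for _ in range(12)
            ]
            items = render_scene(Scene(nodes=nodes, resolution=4))
            depths = [it.depth for it in items]
            assert depths == sorted(depths)

    def test_unit_sphere_hull_area_converges_to_pi(self):
        items = render_scene(Scene(nodes=[sphere_at(0.0)], resolution=100))
        area = polygon_area(Polygon2D(items[0].points))
        assert area == pytest.approx(math.pi, rel=0.02)

    def test_scale_multiplies_radii_and_coordinates(self):
        items = render_scene(Scene(nodes=[sphere_at(0.0)], resolution=100,
                                   scale=3.0))
        area = polygon_area(Polygon2D(items[0].points))
        assert area == pytest.approx(math.pi * 9.0, rel=0.02)

    def test_rotation_applied_before_sorting(self):
        # two spheres on the x-axis share depth 0; rotating π/2 over y
        # (x -> -z) moves them to distinct depths, which sorting must see
        nodes = [sphere_at(0.0, x=-2.0), sphere_at(0.0, x=2.0)]
        items = render_scene(
            Scene(nodes=nodes, resolution=8,
                  rotation=RotationSpec(over_y=math.pi / 2))
        )
        assert [it.depth for it in items] == pytest.approx([-2.0, 2.0])

    def test_filter_toggle_identical_on_all_sphere_scenes(self):
        rng = random.Random(31)
        nodes = [
            sphere_at(rng.uniform(-3, 3), r=rng.uniform(0.4, 1.2),
                      x=rng.uniform(-3, 3))
            for _ in range(10)
        ]
        fast = render_scene(Scene(nodes=nodes, resolution=10,
                                  filter_intersecting=True))
        exact = render_scene(Scene(nodes=nodes, resolution=10,
                                   filter_intersecting=False))
        assert fast == exact

    def test_rendering_is_deterministic(self):
        nodes = make_two_spheres(0.9) + make_crossed_cylinders()
        a = render_scene(Scene(nodes=nodes, resolution=14))
        b = render_scene(Scene(nodes=nodes, resolution=14))
        assert a == b

    def test_wires_pass_through_as_polylines(self):
        w = Wire((Vec3(0, 0, 0), Vec3(1, 1, 0)),
                 style=NodeStyle(fill_mode=FillMode.STROKE_ONLY))
        items = render_scene(Scene(nodes=[w, sphere_at(-3.0)], resolution=6))
        polyline = [it for it in items if not it.closed]
        assert len(polyline) == 1
        assert len(polyline[0].points) == 2

    def test_round_capped_cylinder_hull_longer_than_uncapped(self):
        base = dict(start=Vec3(-1, 0, 0), end=Vec3(1, 0, 0), radius=0.4)
        capped = Cylinder(**base, cap=CylinderCap.ROUND)
        flat = Cylinder(**base, cap=CylinderCap.NONE)
        (item_c,) = render_scene(Scene(nodes=[capped], resolution=30))
        (item_f,) = render_scene(Scene(nodes=[flat], resolution=30))
        span_c = max(p.x for p in item_c.points) - min(p.x for p in item_c.points)
        span_f = max(p.x for p in item_f.points) - min(p.x for p in item_f.points)
        assert span_c > span_f
        assert span_c == pytest.approx(2.8, rel=0.02)  # body + two cap radii
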
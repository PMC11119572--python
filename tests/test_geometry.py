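import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vecmol.geometry import (
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

finite = st.floats(min_value=-10, max_value=10, allow_nan=False)
angles = st.floats(min_value=-2 * math.pi, max_value=2 * math.pi)


class TestRotation:
    def test_quarter_turn_about_z(self):
        (p,) = rotate_points([Vec3(1, 0, 0)], RotationSpec(over_z=math.pi / 2))
        assert p.distance(Vec3(0, 1, 0)) < 1e-9

    def test_full_turn_over_each_axis_is_identity(self):
        cloud = [Vec3(1.0, -2.0, 3.0), Vec3(0.5, 0.5, -0.5)]
        tau = 2 * math.pi
        out = rotate_points(cloud, RotationSpec(tau, tau, tau))
        for a, b in zip(cloud, out):
            assert a.distance(b) < 1e-9

    @settings(deadline=None, max_examples=30)
    @given(
        pts=st.lists(st.tuples(finite, finite, finite), min_size=2, max_size=20),
        rx=angles, ry=angles, rz=angles,
    )
    def test_pairwise_distances_preserved(self, pts, rx, ry, rz):
        cloud = [Vec3(*t) for t in pts]
        out = rotate_points(cloud, RotationSpec(rx, ry, rz))
        for i in range(len(cloud)):
            for j in range(i + 1, len(cloud)):
                before = cloud[i].distance(cloud[j])
                after = out[i].distance(out[j])
                assert abs(before - after) < 1e-9


class TestSurfaceSampling:
    @pytest.mark.parametrize("resolution", range(1, 21))
    def test_sphere_point_count_formula(self, resolution):
        pts = sphere_points(Vec3(0, 0, 0), 1.0, resolution)
        assert len(pts) == (resolution + 1) ** 2

    @pytest.mark.parametrize("resolution", range(1, 21))
    def test_cylinder_body_point_count_formula(self, resolution):
        pts = cylinder_points(
            Vec3(0, 0, 0), Vec3(0, 0, 2), 1.0, resolution, CylinderCap.NONE
        )
        assert len(pts) == (resolution + 1) * resolution

    def test_sphere_points_lie_on_surface(self):
        center = Vec3(1.0, -2.0, 0.5)
        for p in sphere_points(center, 2.0, 9):
            assert abs(p.distance(center) - 2.0) < 1e-9
        assert len(sphere_points(center, 2.0, 9)) == 100

    def test_cylinder_body_points_on_lateral_surface(self):
        pts = cylinder_points(Vec3(0, 0, -1), Vec3(0, 0, 1), 1.0, 4)
        for p in pts:
            assert abs(math.hypot(p.x, p.y) - 1.0) < 1e-9

    def test_round_cap_appends_points(self):
        args = (Vec3(0, 0, 0), Vec3(0, 0, 2), 0.5, 6)
        assert len(cylinder_points(*args, CylinderCap.ROUND)) > len(
            cylinder_points(*args, CylinderCap.NONE)
        )

    def test_round_cap_points_on_end_hemispheres(self):
        start, end, r = Vec3(0, 0, 0), Vec3(0, 0, 2), 0.5
        body = set(
            p.as_tuple() for p in cylinder_points(start, end, r, 6, CylinderCap.NONE)
        )
        for p in cylinder_points(start, end, r, 6, CylinderCap.ROUND):
            if p.as_tuple() in body:
                continue
            on_start = abs(p.distance(start) - r) < 1e-9 and p.z <= 1e-9
            on_end = abs(p.distance(end) - r) < 1e-9 and p.z >= 2 - 1e-9
            assert on_start or on_end

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            sphere_points(Vec3(0, 0, 0), -1.0, 5)
        with pytest.raises(ValueError):
            sphere_points(Vec3(0, 0, 0), 1.0, 0)
        with pytest.raises(ValueError, match="degenerate"):
            cylinder_points(Vec3(1, 1, 1), Vec3(1, 1, 1), 1.0, 5)


class TestContainment:
    def test_inside_sphere_strictness(self):
        c = Vec3(0, 0, 0)
        assert inside_sphere(Vec3(0, 0, 0.5), c, 1.0)
        assert not inside_sphere(Vec3(1.0, 0, 0), c, 1.0)  # on surface
        assert not inside_sphere(Vec3(2, 0, 0), c, 1.0)

    def test_inside_cylinder_cases(self):
        s, e = Vec3(0, 0, 0), Vec3(0, 0, 2)
        assert inside_cylinder(Vec3(0.5, 0, 1), s, e, 1.0)
        assert not inside_cylinder(Vec3(0, 0, 3), s, e, 1.0)  # beyond end plane
        assert not inside_cylinder(Vec3(1.0, 0, 1), s, e, 1.0)  # on surface

    def test_sampled_surface_points_sit_on_the_boundary(self):
        # strictness margin: surface samples are never deep inside
        c, r = Vec3(0.3, -0.2, 0.1), 1.3
        shrunk = r * (1.0 - 1e-9)
        assert not any(inside_sphere(p, c, shrunk) for p in sphere_points(c, r, 8))


class TestSegmentDistance:
    def test_crossing_perpendicular_segments(self):
        d = segment_segment_distance(
            Vec3(-1, 0, 0), Vec3(1, 0, 0), Vec3(0, -1, 0), Vec3(0, 1, 0)
        )
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_parallel_offset_segments(self):
        d = segment_segment_distance(
            Vec3(0, 0, 0), Vec3(1, 0, 0), Vec3(0, 3, 0), Vec3(1, 3, 0)
        )
        assert d == pytest.approx(3.0)

    def test_degenerate_segments_treated_as_points(self):
        p = Vec3(1, 1, 1)
        assert segment_segment_distance(p, p, Vec3(4, 1, 1), Vec3(4, 1, 1)) == 3.0
        assert point_segment_distance(Vec3(0, 2, 0), Vec3(-1, 0, 0), Vec3(1, 0, 0)) == 2.0

    @settings(deadline=None, max_examples=25)
    @given(
        coords=st.lists(st.tuples(finite, finite, finite), min_size=4, max_size=4)
    )
    def test_matches_dense_sampling_oracle(self, coords):
        a1, a2, b1, b2 = (Vec3(*t) for t in coords)
        exact = segment_segment_distance(a1, a2, b1, b2)
        n = 120
        best = float("inf")
        samples_a = [
            Vec3(a1.x + (a2.x - a1.x) * i / n, a1.y + (a2.y - a1.y) * i / n,
                 a1.z + (a2.z - a1.z) * i / n)
            for i in range(n + 1)
        ]
        samples_b = [
            Vec3(b1.x + (b2.x - b1.x) * i / n, b1.y + (b2.y - b1.y) * i / n,
                 b1.z + (b2.z - b1.z) * i / n)
            for i in range(n + 1)
        ]
        for pa in samples_a:
            for pb in samples_b:
                d = pa.distance(pb)
                if d < best:
                    best = d
        assert exact <= best + 1e-9
        assert best - exact < 0.25  # grid granularity bound


class TestProjection:
    def test_orthographic_passes_xy_through(self):
        assert project(Vec3(3, -2, 7)).as_tuple() == (3, -2)

    def test_origin_fixed_under_any_focal_length(self):
        assert project(Vec3(0, 0, 0), focal_length=5.0).as_tuple() == (0, 0)

    def test_nearer_points_magnified(self):
        near = project(Vec3(1, 0, 2), focal_length=10.0)
        far = project(Vec3(1, 0, -2), focal_length=10.0)
        assert abs(near.x) > abs(far.x)

    def test_magnification_ratio_analytic(self):
        f, z1, z2 = 8.0, 3.0, -5.0
        p1 = project(Vec3(1, 0, z1), focal_length=f)
        p2 = project(Vec3(1, 0, z2), focal_length=f)
        assert p1.x / p2.x == pytest.approx((f - z2) / (f - z1))

    def test_orthographic_left_inverse_of_embedding(self):
        for z in (-3.0, 0.0, 9.0):
            v = Vec2(1.25, -4.5)
            assert project(Vec3(v.x, v.y, z)).as_tuple() == v.as_tuple()

    def test_point_at_or_behind_focal_plane_rejected(self):
        with pytest.raises(ValueError):
            project(Vec3(0, 0, 10.0), focal_length=10.0)
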
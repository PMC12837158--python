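import numpy as np
import pytest
import trimesh
from hypothesis import given, settings
from hypothesis import strategies as st

from eritwin import (
    GeometryError,
    PlanarContour,
    SurfaceMesh,
    centroid_centerline,
    polar_discretize,
    resample_centerline,
    slice_mesh,
)
from eritwin.geometry import (
    NonWatertightSliceError,
    PlaneOutsideMeshError,
    loft_closed_tube,
)


def analytic_contour(points2d):
    """PlanarContour in the z=0 plane from explicit 2-D boundary points."""
    return PlanarContour(
        index=0, s=0.0, origin=[0.0, 0.0, 0.0], normal=[0.0, 0.0, 1.0],
        basis=[[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]], points=points2d,
    )


def ellipse_points(a, b, n=2000, rotation=0.0):
    t = 2 * np.pi * np.arange(n) / n
    pts = np.column_stack([a * np.cos(t), b * np.sin(t)])
    c, s = np.cos(rotation), np.sin(rotation)
    return pts @ np.array([[c, s], [-s, c]])


class TestSliceMesh:
    def test_cylinder_normal_section_is_circle(self, cylinder_mesh):
        c = slice_mesh(cylinder_mesh, [0, 0, 0], [0, 0, 1])
        r = np.linalg.norm(c.points - c.centroid2d, axis=1)
        # faceting puts diagonal-edge crossings a chord-sagitta inside
        assert np.allclose(r, 10.0, atol=1e-3)

    def test_cylinder_perimeter_matches_circumference(self, cylinder_mesh):
        c = slice_mesh(cylinder_mesh, [0, 0, 0], [0, 0, 1])
        assert c.perimeter == pytest.approx(2 * np.pi * 10.0, rel=0.005)

    def test_oblique_section_is_ellipse(self, cylinder_mesh):
        # 45-degree plane: semi-axes r and r/cos(45) = 14.142
        normal = np.array([0.0, 1.0, 1.0]) / np.sqrt(2)
        c = slice_mesh(cylinder_mesh, [0, 0, 0], normal)
        r = np.linalg.norm(c.points - c.centroid2d, axis=1)
        assert r.min() == pytest.approx(10.0, rel=0.01)
        assert r.max() == pytest.approx(10.0 * np.sqrt(2), rel=0.01)

    def test_plane_outside_mesh_raises(self, cylinder_mesh):
        with pytest.raises(PlaneOutsideMeshError):
            slice_mesh(cylinder_mesh, [0, 0, 100.0], [0, 0, 1])

    def test_open_surface_raises(self):
        # cylinder with an angular strip of wall removed -> the section at
        # mid-height is an open polyline, not a closed contour
        tm = trimesh.creation.cylinder(radius=5.0, height=10.0, sections=64)
        centers = tm.triangles.mean(axis=1)
        hole = (np.abs(np.arctan2(centers[:, 1], centers[:, 0])) < 0.3) & (
            np.abs(tm.face_normals[:, 2]) < 0.9
        )
        open_mesh = SurfaceMesh(tm.vertices, tm.faces[~hole])
        with pytest.raises((NonWatertightSliceError, GeometryError)):
            slice_mesh(open_mesh, [0, 0, 0], [0, 0, 1])

    def test_contour_is_ccw_about_normal(self, cylinder_mesh):
        c = slice_mesh(cylinder_mesh, [0, 0, 0], [0, 0, 1])
        v = c.points
        nxt = np.roll(v, -1, axis=0)
        signed = (v[:, 0] * nxt[:, 1] - v[:, 1] * nxt[:, 0]).sum() / 2.0
        assert signed > 0

    def test_centroid_inside_polygon(self, cylinder_mesh):
        import shapely.geometry as sgeom

        c = slice_mesh(cylinder_mesh, [0, 0, 0], [0, 0, 1])
        assert c.polygon.contains(sgeom.Point(c.centroid2d))


class TestPolarDiscretize:
    def test_circle_gives_constant_radius(self):
        c = analytic_contour(ellipse_points(10.0, 10.0))
        phi, r = polar_discretize(c, [0.0, 0.0, 0.0], 200)
        assert len(r) == 200
        assert np.allclose(r, 10.0, atol=1e-3)
        assert np.allclose(phi, 2 * np.pi * np.arange(200) / 200)

    def test_ellipse_axis_radii(self):
        c = analytic_contour(ellipse_points(11.0, 9.0))
        _, r = polar_discretize(c, [0.0, 0.0, 0.0], 8)
        assert r[0] == pytest.approx(11.0, abs=1e-3)
        assert r[2] == pytest.approx(9.0, abs=1e-3)
        assert r[4] == pytest.approx(11.0, abs=1e-3)
        assert r[6] == pytest.approx(9.0, abs=1e-3)

    def test_offset_center_ray_circle(self):
        # center 2 mm off the centroid: far side 12 mm, near side 8 mm
        c = analytic_contour(ellipse_points(10.0, 10.0))
        _, r = polar_discretize(c, [-2.0, 0.0, 0.0], 8)
        assert r[0] == pytest.approx(12.0, abs=1e-3)
        assert r[4] == pytest.approx(8.0, abs=1e-3)

    def test_center_outside_raises(self):
        c = analytic_contour(ellipse_points(10.0, 10.0))
        with pytest.raises(GeometryError):
            polar_discretize(c, [15.0, 0.0, 0.0], 16)

    def test_too_few_angles_raises(self):
        c = analytic_contour(ellipse_points(10.0, 10.0))
        with pytest.raises(GeometryError):
            polar_discretize(c, [0.0, 0.0, 0.0], 4)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        a=st.floats(5.0, 20.0),
        b=st.floats(5.0, 20.0),
        rot=st.floats(0.0, np.pi),
    )
    def test_polygon_reconstruction_preserves_convex_area(self, a, b, rot):
        c = analytic_contour(ellipse_points(a, b, rotation=rot))
        _, r = polar_discretize(c, [0.0, 0.0, 0.0], 200)
        dphi = 2 * np.pi / 200
        area = 0.5 * np.sum(r * np.roll(r, -1) * np.sin(dphi))
        assert area == pytest.approx(np.pi * a * b, rel=0.01)

    def test_radii_invariant_under_joint_rigid_motion(self, cylinder_mesh):
        rng = np.random.default_rng(4)
        R = trimesh.transformations.random_rotation_matrix(rng.random(3))
        R[:3, 3] = [5.0, -3.0, 2.0]
        origin, normal, u = [0, 0, 3.0], [0, 0, 1.0], [1.0, 0, 0]
        c1 = slice_mesh(cylinder_mesh, origin, normal, u=u)
        _, r1 = polar_discretize(c1, c1.centroid + [1.0, 0.5, 0.0], 64)
        moved = cylinder_mesh.transformed(R)
        o2 = R[:3, :3] @ origin + R[:3, 3]
        c2 = slice_mesh(moved, o2, R[:3, :3] @ normal, u=R[:3, :3] @ u)
        center2 = R[:3, :3] @ (c1.centroid + [1.0, 0.5, 0.0]) + R[:3, 3]
        _, r2 = polar_discretize(c2, center2, 64)
        assert np.allclose(r1, r2, atol=1e-6)


class TestCenterline:
    def test_straight_segment_resampling(self):
        path = resample_centerline([[0, 0, 0], [0, 0, 20.0]], 0.5)
        assert len(path.points) == 41
        assert path.length == pytest.approx(20.0)
        assert np.allclose(path.tangents, [0, 0, 1.0])

    def test_quarter_circle_arclength(self):
        R = 30.0
        t = np.linspace(0, np.pi / 2, 500)
        pts = np.column_stack([R * np.cos(t), R * np.sin(t), np.zeros_like(t)])
        path = resample_centerline(pts, R / 100)
        assert path.length == pytest.approx(np.pi * R / 2, rel=0.01)

    def test_single_point_raises(self):
        with pytest.raises(GeometryError):
            resample_centerline([[1.0, 2.0, 3.0]], 0.5)

    def test_duplicate_points_collapsed_with_warning(self):
        with pytest.warns(UserWarning, match="duplicate"):
            path = resample_centerline(
                [[0, 0, 0], [0, 0, 0], [0, 0, 10.0]], 1.0
            )
        assert path.length == pytest.approx(10.0)

    def test_strictly_increasing_arclength_enforced(self):
        from eritwin import CenterlinePath

        with pytest.raises(GeometryError):
            CenterlinePath(
                points=[[0, 0, 0], [0, 0, 1], [0, 0, 2]],
                s=[0.0, 0.0, 1.0],
                tangents=[[0, 0, 1]] * 3,
            )

    def test_frames_are_orthonormal(self):
        t = np.linspace(0, np.pi / 2, 200)
        pts = np.column_stack([20 * np.cos(t), 20 * np.sin(t), 3 * t])
        path = resample_centerline(pts, 0.5)
        U, V = path.frames()
        T = path.tangents
        assert np.allclose(np.einsum("ij,ij->i", U, T), 0, atol=1e-8)
        assert np.allclose(np.einsum("ij,ij->i", U, V), 0, atol=1e-8)
        assert np.allclose(np.linalg.norm(U, axis=1), 1, atol=1e-8)


class TestCentroidCenterline:
    def test_straight_cylinder_recovers_axis(self, cylinder_mesh):
        path = centroid_centerline(cylinder_mesh, [0, 0, 1.0], spacing=1.0)
        assert np.abs(path.points[:, :2]).max() < 0.05

    def test_bent_tube_recovers_bend_angle(self):
        # straight / 25-degree arc / straight tube of radius 5
        angle = np.radians(25.0)
        R = 30.0
        seg1 = np.column_stack([np.zeros(41), np.zeros(41), np.linspace(0, 20, 41)])
        ts = np.linspace(0, angle, 31)
        arc = seg1[-1] + np.column_stack(
            [R * (1 - np.cos(ts)), np.zeros_like(ts), R * np.sin(ts)]
        )
        d_end = np.array([np.sin(angle), 0.0, np.cos(angle)])
        seg3 = arc[-1] + np.outer(np.linspace(0, 20, 41), d_end)
        spine = np.vstack([seg1, arc[1:], seg3[1:]])
        path0 = resample_centerline(spine, 0.5)
        U, V = path0.frames()
        phi = 2 * np.pi * np.arange(64) / 64
        rings = (
            path0.points[:, None, :]
            + 5.0 * np.cos(phi)[None, :, None] * U[:, None, :]
            + 5.0 * np.sin(phi)[None, :, None] * V[:, None, :]
        )
        from eritwin.geometry import loft_closed_tube

        tube = loft_closed_tube(rings)
        path = centroid_centerline(tube, [0, 0, 1.0], spacing=1.0)
        # stay clear of the tilted end caps when reading off tangents
        t_in = path.tangents[5]
        t_out = path.tangents[-8]
        bend = np.degrees(np.arccos(np.clip(np.dot(t_in, t_out), -1, 1)))
        assert bend == pytest.approx(25.0, abs=2.0)

    def test_sphere_warns_non_tubular(self):
        sphere = SurfaceMesh.from_trimesh(trimesh.creation.icosphere(3, 5.0))
        with pytest.warns(UserWarning, match="non-tubular"):
            centroid_centerline(sphere, [0, 0, 1.0], spacing=0.1)


class TestLoft:
    def test_lofted_tube_is_watertight_with_positive_volume(self):
        z = np.linspace(0, 10, 11)
        phi = 2 * np.pi * np.arange(32) / 32
        rings = np.stack(
            [np.column_stack([5 * np.cos(phi), 5 * np.sin(phi), np.full(32, zi)])
             for zi in z]
        )
        mesh = loft_closed_tube(rings)
        assert mesh.is_watertight
        assert mesh.volume == pytest.approx(np.pi * 25 * 10, rel=0.02)
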
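"""Rigid transforms, biplanar rig geometry, and silhouette projection."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

import kneereg as kr
from kneereg.errors import (
    DegenerateRigError,
    InvalidTransformError,
    ProjectionOutOfBoundsError,
)
from kneereg.geometry import (
    Mesh,
    ProjectionView,
    RigidTransform,
    apply_transform,
    load_mesh,
    make_biplanar_rig,
    project_points,
    project_silhouette,
    save_mesh,
)

from conftest import random_rigid


class TestApplyTransform:
    def test_identity_leaves_vertices_unchanged(self, femoral_mesh):
        out = apply_transform(femoral_mesh, RigidTransform())
        np.testing.assert_array_equal(out.vertices, femoral_mesh.vertices)

    def test_pure_translation_shifts_every_vertex(self, unit_tetrahedron):
        out = apply_transform(unit_tetrahedron, RigidTransform(0, 0, 0, 5, 0, 0))
        np.testing.assert_allclose(
            out.vertices, unit_tetrahedron.vertices + [5, 0, 0], atol=1e-12
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rigidity_preserves_pairwise_distances(self, femoral_mesh, seed):
        # brute-force oracle: the full inter-vertex distance matrix
        rng = np.random.default_rng(seed)
        t = random_rigid(rng)
        sub = femoral_mesh.vertices[::7]
        mesh = Mesh(vertices=sub, faces=np.array([[0, 1, 2]]))
        out = apply_transform(mesh, t)
        np.testing.assert_allclose(pdist(out.vertices), pdist(sub), atol=1e-9)

    def test_inverse_recovers_vertices(self, femoral_mesh):
        t = RigidTransform(10.0, -7.0, 3.0, 4.0, -2.0, 8.0)
        moved = apply_transform(femoral_mesh, t)
        back = apply_transform(moved, t.inverse())
        np.testing.assert_allclose(back.vertices, femoral_mesh.vertices, atol=1e-9)

    def test_nonfinite_parameter_rejected(self):
        with pytest.raises(InvalidTransformError):
            RigidTransform(np.nan, 0, 0, 0, 0, 0)

    def test_topology_unchanged(self, femoral_mesh):
        out = apply_transform(femoral_mesh, RigidTransform(1, 2, 3, 4, 5, 6))
        np.testing.assert_array_equal(out.faces, femoral_mesh.faces)


class TestBiplanarRig:
    def test_principal_rays_meet_at_origin_at_ninety_degrees(self):
        a, b = make_biplanar_rig(45.0, 135.0)
        da = -a.source / np.linalg.norm(a.source)
        db = -b.source / np.linalg.norm(b.source)
        assert abs(np.dot(da, db)) < 1e-12  # 90 degrees apart
        # both principal rays pass through the origin by construction
        for v in (a, b):
            assert abs(np.cross(v.source, v.normal)).max() < 1e-9

    def test_frontal_lateral_rig(self):
        a, b = make_biplanar_rig(0.0, 90.0)
        assert a.view_angle == 0.0 and b.view_angle == 90.0
        np.testing.assert_allclose(a.source, [1000.0, 0.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(b.source, [0.0, 1000.0, 0.0], atol=1e-12)

    def test_origin_projects_to_principal_point(self, rig):
        for view in rig:
            xy = project_points(np.zeros((1, 3)), view)[0]
            rows, cols = view.image_size
            np.testing.assert_allclose(
                xy, [(cols - 1) / 2, (rows - 1) / 2], atol=1e-9
            )

    def test_coincident_views_rejected(self):
        with pytest.raises(DegenerateRigError):
            make_biplanar_rig(30.0, 210.0)

    def test_point_between_views_magnification(self):
        # closed-form perspective: point at (0,0,10) stays on the vertical
        # detector axis and scales by (s + d) / s
        view = make_biplanar_rig()[0]
        xy = project_points(np.array([[0.0, 0.0, 10.0]]), view)[0]
        expected_rows_up = 10.0 * 1.2 / view.pixel_spacing
        assert abs(xy[1] - ((view.image_size[0] - 1) / 2 - expected_rows_up)) < 1e-9


def _cube_mesh(side):
    import trimesh

    tm = trimesh.creation.box(extents=[side] * 3)
    return Mesh(
        vertices=np.asarray(tm.vertices, float),
        faces=np.asarray(tm.faces, np.int64),
        watertight=True,
    )


class TestProjectSilhouette:
    def test_cube_area_matches_analytic_perspective(self):
        # cube face toward the detector: its front face at depth z has
        # magnification (s + d) / (s - z); interior area within 2%
        side = 30.0
        view = make_biplanar_rig(0.0, 90.0)[0]
        mesh = _cube_mesh(side)
        sil = project_silhouette(mesh, RigidTransform(), view)
        s, d = 1000.0, 200.0
        mag = (s + d) / (s - side / 2)
        expected = (side * mag / view.pixel_spacing) ** 2
        assert abs(sil.n_interior - expected) / expected < 0.02

    def test_sphere_area_matches_circle(self, rig):
        import trimesh

        tm = trimesh.creation.icosphere(subdivisions=3, radius=15.0)
        mesh = Mesh(
            vertices=np.asarray(tm.vertices, float),
            faces=np.asarray(tm.faces, np.int64),
            watertight=True,
        )
        sil = project_silhouette(mesh, RigidTransform(), rig[0])
        r_px = 15.0 * 1.2 / rig[0].pixel_spacing
        expected = np.pi * r_px**2
        assert abs(sil.n_interior - expected) / expected < 0.02

    def test_contour_pixels_touch_interior_and_exterior(self, femoral_mesh, rig):
        sil = project_silhouette(femoral_mesh, RigidTransform(2, 1, -3, 4, 0, 2), rig[0])
        full = sil.interior_mask
        for x, y in sil.contour[::25]:
            x, y = int(x), int(y)
            patch = full[max(y - 1, 0) : y + 2, max(x - 1, 0) : x + 2]
            assert full[y, x]  # contour pixels are interior-boundary pixels
            assert not patch.all()  # touches the exterior

    def test_contour_is_closed_chain(self, femoral_mesh, rig):
        sil = project_silhouette(femoral_mesh, RigidTransform(), rig[0])
        d = np.abs(np.diff(np.vstack([sil.contour, sil.contour[:1]]), axis=0))
        assert d.max() <= 1  # 8-connected, closed
        assert sil.n_contour == len(np.unique(sil.contour, axis=0))  # simple

    def test_tangents_unit_norm(self, femoral_mesh, rig):
        sil = project_silhouette(femoral_mesh, RigidTransform(), rig[0])
        np.testing.assert_allclose(
            np.hypot(sil.tangents[:, 0], sil.tangents[:, 1]), 1.0, atol=1e-12
        )

    def test_coarser_pixels_scale_area(self, femoral_mesh):
        fine = make_biplanar_rig(pixel_spacing=0.2)[0]
        coarse = make_biplanar_rig(pixel_spacing=0.4)[0]
        a_fine = project_silhouette(femoral_mesh, RigidTransform(), fine).n_interior
        a_coarse = project_silhouette(femoral_mesh, RigidTransform(), coarse).n_interior
        assert abs(a_fine / a_coarse - 4.0) < 0.1

    def test_moving_toward_source_enlarges_silhouette(self, femoral_mesh, rig):
        # fluoroscopic magnification: closer to the source, larger the image
        view = rig[0]
        u = view.source / np.linalg.norm(view.source)
        areas = []
        for step in (0.0, 10.0, 20.0):
            t = RigidTransform(0, 0, 0, *(u * step))
            areas.append(project_silhouette(femoral_mesh, t, view).n_interior)
        assert areas[0] < areas[1] < areas[2]

    def test_mesh_behind_source_rejected(self, femoral_mesh, rig):
        view = rig[0]
        u = view.source / np.linalg.norm(view.source)
        with pytest.raises(ProjectionOutOfBoundsError):
            project_silhouette(
                femoral_mesh, RigidTransform(0, 0, 0, *(u * 1100.0)), view
            )

    def test_far_off_detector_rejected(self, femoral_mesh, rig):
        with pytest.raises(ProjectionOutOfBoundsError):
            project_silhouette(
                femoral_mesh, RigidTransform(0, 0, 0, 0, 0, 500.0), rig[0]
            )


def test_mesh_io_roundtrip(tmp_path, femoral_mesh):
    path = tmp_path / "mesh.stl"
    save_mesh(femoral_mesh, path)
    back = load_mesh(path)
    assert back.watertight
    assert back.faces.shape == femoral_mesh.faces.shape
    # STL stores per-face vertices; compare via sorted coordinates
    np.testing.assert_allclose(
        np.sort(back.vertices, axis=0), np.sort(femoral_mesh.vertices, axis=0),
        atol=1e-5,
    )


def test_pose_yaml_roundtrip(tmp_path):
    from kneereg.geometry import load_pose, save_pose

    t = RigidTransform(1.5, -2.5, 3.0, 0.25, -0.75, 9.0)
    save_pose(t, tmp_path / "pose.yaml")
    assert load_pose(tmp_path / "pose.yaml") == t
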
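"""Surface generation, region selection, plate exclusion, ICP, Procrustes."""

import numpy as np
import pytest

from jawmotion.geometry import RigidTransform, SegmentMotion, from_parameters, transform_error
from jawmotion.io import Volume, TriMesh
from jawmotion.surface import (
    IsoSurfaceParams, ICPParams, extract_isosurface, select_matching_region,
    exclude_high_density, register_icp, compute_planned_transform, kabsch,
)
from jawmotion.voxel import RegistrationError


@pytest.fixture(scope="module")
def sphere_volume():
    """Radial distance field; the level set at 10 is a sphere of radius 10 mm."""
    n, d = 64, 0.5
    ax = (np.arange(n) - (n - 1) / 2) * d
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    data = np.sqrt(X**2 + Y**2 + Z**2).astype(np.float32)
    origin = np.full(3, -(n - 1) / 2 * d)
    return Volume(data, spacing=[d, d, d], origin=origin)


@pytest.fixture(scope="module")
def sphere_mesh(sphere_volume):
    return extract_isosurface(sphere_volume, IsoSurfaceParams(threshold=10.0))


@pytest.fixture(scope="module")
def blob_volume():
    """Anisotropic blob: no rotational symmetry, so all 6 DOF are observable."""
    n, d = 64, 0.5
    ax = (np.arange(n) - (n - 1) / 2) * d
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    data = np.sqrt((X / 1.3) ** 2 + (Y - 0.2 * Z) ** 2 + (Z / 0.8) ** 2)
    return Volume(data.astype(np.float32), spacing=[d, d, d],
                  origin=np.full(3, -(n - 1) / 2 * d))


@pytest.fixture(scope="module")
def blob_mesh(blob_volume):
    return extract_isosurface(blob_volume, IsoSurfaceParams(threshold=8.0))


class TestIsosurface:
    def test_sphere_area_matches_analytic(self, sphere_mesh):
        area = sphere_mesh.to_trimesh().area
        assert area == pytest.approx(4 * np.pi * 10.0**2, rel=0.05)

    def test_threshold_outside_range_rejected(self, sphere_volume):
        with pytest.raises(ValueError, match="outside"):
            extract_isosurface(sphere_volume, IsoSurfaceParams(threshold=100.0))

    def test_constant_volume_rejected(self):
        flat = Volume(np.ones((8, 8, 8), dtype=np.float32), [1, 1, 1], [0, 0, 0])
        with pytest.raises(ValueError):
            extract_isosurface(flat, IsoSurfaceParams(threshold=0.5))

    def test_small_components_removed(self, sphere_volume):
        data = sphere_volume.data.copy()
        data[2:4, 2:4, 2:4] = 0.0  # a speck far from the sphere
        speckled = Volume(data, sphere_volume.spacing, sphere_volume.origin)
        dirty = extract_isosurface(speckled, IsoSurfaceParams(threshold=10.0))
        clean = extract_isosurface(speckled, IsoSurfaceParams(threshold=10.0,
                                                              min_component_size=100))
        assert len(clean.faces) < len(dirty.faces)
        assert np.linalg.norm(clean.vertices, axis=1).max() < 11.0


class TestRegionSelection:
    def test_halfspace_selects_caudal_vertices(self, sphere_mesh):
        sel = select_matching_region(
            sphere_mesh, {"type": "halfspace", "normal": [0, 0, 1], "offset": -5.0})
        assert sel.selection.sum() >= 100
        assert sel.vertices[sel.selection][:, 2].max() <= -5.0 + 1e-9

    def test_empty_selection_rejected(self, sphere_mesh):
        with pytest.raises(ValueError, match="selection too small"):
            select_matching_region(
                sphere_mesh, {"type": "halfspace", "normal": [0, 0, 1], "offset": -50.0})

    def test_intersection_region(self, sphere_mesh):
        cfg = {"type": "intersection", "parts": [
            {"type": "halfspace", "normal": [0, 0, 1], "offset": -5.0},
            {"type": "box", "lower": [-4, -40, -40], "upper": [4, 40, 40]},
        ]}
        sel = select_matching_region(sphere_mesh, cfg)
        picked = sel.vertices[sel.selection]
        assert picked[:, 2].max() <= -5.0 + 1e-9
        assert np.abs(picked[:, 0]).max() <= 4.0 + 1e-9


class TestExcludeHighDensity:
    def _volume_with_plate(self, plate=True):
        data = np.full((20, 20, 20), 700.0, dtype=np.float32)
        if plate:
            data[8:12, 8:12, 16:19] = 3000.0
        return Volume(data, [1, 1, 1], [0, 0, 0])

    def test_without_plate_selection_unchanged(self, sphere_mesh):
        vol = self._volume_with_plate(plate=False)
        mesh = TriMesh(sphere_mesh.vertices + 10.0, sphere_mesh.faces,
                       np.ones(len(sphere_mesh.vertices), dtype=bool))
        out = exclude_high_density(mesh, vol, upper_threshold=2250.0, radius=2.0)
        assert out.selection.all()

    def test_vertices_near_plate_deselected(self):
        vol = self._volume_with_plate()
        # vertices on a line passing near the plate (plate voxels at
        # world indices 8..11 / 16..18)
        verts = np.array([[10.0, 10.0, z] for z in np.linspace(0, 19, 20)])
        faces = [[i, i + 1, (i + 2) % 20] for i in range(18)]
        mesh = TriMesh(verts, faces)
        out = exclude_high_density(mesh, vol, upper_threshold=2250.0, radius=2.0)
        near = np.array([v[2] >= 14.0 for v in verts])  # within 2 mm of plate
        assert not out.selection[near].any()
        assert out.selection[~near].all()

    def test_radius_zero_only_exact_hits(self):
        vol = self._volume_with_plate()
        verts = np.array([[10.0, 10.0, 17.0],   # exactly a plate voxel center
                          [10.0, 10.0, 15.0],   # 1 mm away
                          [0.0, 0.0, 0.0]])
        mesh = TriMesh(verts, [[0, 1, 2]])
        out = exclude_high_density(mesh, vol, upper_threshold=2250.0, radius=0.0)
        assert not out.selection[0]
        assert out.selection[1] and out.selection[2]


class TestIcp:
    def test_exact_overlap_recovers_truth_with_tiny_rms(self, sphere_mesh):
        t = from_parameters(SegmentMotion(t_rl=1.0, t_ap=-2.0, t_si=0.5,
                                          pitch=2.0, yaw=-3.0))
        moving = sphere_mesh
        fixed = moving.transformed(t)
        # init within 3 mm / 5 degrees of the truth
        init = from_parameters(SegmentMotion(t_rl=1.5, t_ap=-1.0, t_si=0.0,
                                             pitch=0.0, yaw=-1.0))
        res = register_icp(fixed, moving, ICPParams(variant="point_to_point"), init)
        assert res.rms < 1e-6
        mm, deg = transform_error(res.transform, t, [0, 0, 0])
        assert mm < 1e-6 and deg < 1e-6

    def test_point_to_plane_exact_overlap(self, blob_mesh):
        t = from_parameters(SegmentMotion(t_ap=2.0, yaw=2.0))
        fixed = blob_mesh.transformed(t)
        res = register_icp(fixed, blob_mesh, ICPParams(), RigidTransform.identity())
        mm, deg = transform_error(res.transform, t, [0, 0, 0])
        assert mm < 0.01 and deg < 0.01

    def test_rms_trace_non_increasing(self, sphere_mesh):
        t = from_parameters(SegmentMotion(t_ap=2.0, pitch=3.0))
        fixed = sphere_mesh.transformed(t)
        res = register_icp(fixed, sphere_mesh, ICPParams(variant="point_to_point"),
                           RigidTransform.identity())
        trace = np.array(res.rms_trace)
        assert np.all(np.diff(trace) <= 1e-9)

    def test_non_overlapping_meshes_rejected(self, sphere_mesh):
        far = sphere_mesh.transformed(RigidTransform.translation([500, 0, 0]))
        with pytest.raises(RegistrationError, match="overlap"):
            register_icp(far, sphere_mesh, ICPParams())

    def test_degenerate_geometry_rejected(self):
        # collinear points leave rotation unconstrained
        line = np.column_stack([np.linspace(0, 10, 50), np.zeros(50), np.zeros(50)])
        faces = [[i, i + 1, (i + 2) % 50] for i in range(48)]
        fixed = TriMesh(line, faces)
        moving = TriMesh(line + [0.1, 0, 0], faces)
        with pytest.raises((RegistrationError, ValueError)):
            register_icp(fixed, moving, ICPParams(variant="point_to_point"))

    def test_phantom_chin_surfaces_recover_truth(self, small_case, small_inputs):
        """Resampled pre/post chin surfaces (no exact correspondence)."""
        from jawmotion.pipeline import (align_nhp, chin_surfaces, _shifted_region,
                                        RigidTransform as RT)
        case, inputs = small_case, small_inputs
        shift = -inputs.landmarks.upper_incisor
        pre_f = align_nhp(inputs.pre_volume, inputs.nhp, inputs.landmarks)
        post_map = RT.translation(shift).compose(inputs.nhp.to_rigid())
        post_f = inputs.post_volume.transformed(post_map)
        boxes = {k: b.translated(shift) for k, b in inputs.roi_boxes.items()}
        regions = {k: _shifted_region(inputs.chin_regions[k], shift)
                   for k in ("fixed", "moving")}
        fixed, moving = chin_surfaces(inputs, pre_f, post_f, boxes, regions)
        res = register_icp(fixed, moving, inputs.icp_params,
                           init=case.truth["chin"].planned_transform)
        mm, deg = transform_error(res.transform, case.truth["chin"].executed_transform,
                                  case.rotation_points["chin"])
        assert mm < 0.3 and deg < 0.7


class TestPlannedTransform:
    def test_identity_for_unmoved_mesh(self, sphere_mesh):
        t = compute_planned_transform(sphere_mesh, sphere_mesh)
        assert np.allclose(t.matrix, np.eye(4), atol=1e-12)

    def test_exact_on_matched_topology(self, sphere_mesh):
        planned = from_parameters(SegmentMotion(t_ap=4.0, yaw=2.0))
        moved = sphere_mesh.transformed(planned)
        rec = compute_planned_transform(sphere_mesh, moved)
        assert np.abs(rec.matrix - planned.matrix).max() < 1e-9

    def test_icp_fallback_on_retriangulated_mesh(self, blob_volume, blob_mesh):
        # a remeshed planning export: same surface, different triangulation
        coarse = Volume(blob_volume.data[::2, ::2, ::2],
                        spacing=blob_volume.spacing * 2,
                        origin=blob_volume.origin)
        remeshed = extract_isosurface(coarse, IsoSurfaceParams(threshold=8.0))
        planned = from_parameters(SegmentMotion(t_ap=4.0, yaw=2.0))
        moved = remeshed.transformed(planned)
        rec = compute_planned_transform(blob_mesh, moved)
        mm, deg = transform_error(rec, planned, [0, 0, 0])
        assert mm < 0.1 and deg < 0.1

    def test_kabsch_rejects_rank_deficient_points(self):
        line = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        with pytest.raises(ValueError, match="underconstrained"):
            kabsch(line, line + 1.0)

    def test_kabsch_matches_trimesh_procrustes(self, rng):
        import trimesh
        src = rng.uniform(-10, 10, (40, 3))
        t = from_parameters(SegmentMotion(t_rl=2.0, pitch=5.0, yaw=-7.0))
        dst = t.apply(src)
        ours = kabsch(src, dst)
        ref, _, _ = trimesh.registration.procrustes(src, dst, reflection=False,
                                                    scale=False)
        assert np.allclose(ours.matrix, ref, atol=1e-8)
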
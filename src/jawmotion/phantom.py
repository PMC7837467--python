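"""Synthetic skull phantom with known ground-truth segment motions.

The phantom emulates the inputs of a bimaxillary-surgery-plus-genioplasty
accuracy analysis: a pre-operative and a post-operative CT-like volume, a
pair of (original, planned) surface models per bone segment, the four
anatomical rotation points, ROI boxes, and an NHP matrix — all with the
true planned/executed/difference motion of every segment on record.

The skull is stylized, not anatomical: a cranial vault shell with forehead
and zygomatic bars (the surgically unaffected reference region), a
maxillary block with a tooth ridge carrying the upper-incisor landmark, a
mandibular horseshoe, a chin wedge separated by a horizontal genioplasty
cut, two ramus slabs topped by condylar spheres, and (post-operatively) a
high-density osteosynthesis plate on the chin.  Solids are voxelized with
2x supersampling (partial volume), blurred, and corrupted with seeded
Gaussian noise; five intensity classes (air < soft tissue < bone < teeth <
plate) provide CT-like contrast without any claim to calibrated HU.

All internal geometry lives in the analysis frame ("F"): NHP axes with the
upper incisor at the origin.  Scanner-frame outputs are produced through a
seeded rigid scan pose, and the NHP matrix maps them back.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import RigidTransform, LandmarkSet, SegmentMotion, from_parameters, decompose
from .io import Volume, TriMesh, NHPMatrix
from .surface import IsoSurfaceParams, extract_isosurface
from .voxel import ROIBox

__all__ = [
    "PhantomSpec",
    "PhantomCase",
    "SegmentCollisionError",
    "build_phantom",
    "default_validation_spec",
    "default_validation_case",
    "to_case_inputs",
    "truth_frame",
    "write_case",
    "check_segment_collisions",
    "SEGMENTS",
    "JAW_SEGMENTS",
    "RAMUS_SEGMENTS",
    "DEFAULT_LEVELS",
]

JAW_SEGMENTS = ("maxilla", "mandible", "chin")
RAMUS_SEGMENTS = ("ramus_left", "ramus_right")
SEGMENTS = JAW_SEGMENTS + RAMUS_SEGMENTS

DEFAULT_LEVELS = {"air": 0.0, "soft_tissue": 60.0, "bone": 700.0,
                  "teeth": 1400.0, "plate": 3000.0}

# position of the upper incisor (the analysis origin) in the NHP frame
INCISOR_NHP = np.array([1.5, -2.5, 3.0])


class SegmentCollisionError(RuntimeError):
    """Transformed bone segments intersect; the phantom would be ambiguous."""


# ---------------------------------------------------------------------------
# analytic solids
# ---------------------------------------------------------------------------

class _Solid:
    def contains_xyz(self, x, y, z):  # pragma: no cover - interface
        raise NotImplementedError

    def contains(self, pts):
        pts = np.asarray(pts)
        return self.contains_xyz(pts[..., 0], pts[..., 1], pts[..., 2])


class _Box(_Solid):
    def __init__(self, lower, upper):
        self.lower = np.asarray(lower, dtype=float)
        self.upper = np.asarray(upper, dtype=float)

    def contains_xyz(self, x, y, z):
        return ((x >= self.lower[0]) & (x <= self.upper[0])
                & (y >= self.lower[1]) & (y <= self.upper[1])
                & (z >= self.lower[2]) & (z <= self.upper[2]))

    @property
    def bbox(self):
        return self.lower, self.upper


class _Sphere(_Solid):
    def __init__(self, center, radius):
        self.center = np.asarray(center, dtype=float)
        self.radius = float(radius)

    def contains_xyz(self, x, y, z):
        d2 = (x - self.center[0]) ** 2 + (y - self.center[1]) ** 2 + (z - self.center[2]) ** 2
        return d2 <= self.radius ** 2

    @property
    def bbox(self):
        return self.center - self.radius, self.center + self.radius


class _Ellipsoid(_Solid):
    def __init__(self, center, semiaxes):
        self.center = np.asarray(center, dtype=float)
        self.semiaxes = np.asarray(semiaxes, dtype=float)

    def contains_xyz(self, x, y, z):
        q = ((x - self.center[0]) / self.semiaxes[0]) ** 2
        q += ((y - self.center[1]) / self.semiaxes[1]) ** 2
        q += ((z - self.center[2]) / self.semiaxes[2]) ** 2
        return q <= 1.0

    @property
    def bbox(self):
        return self.center - self.semiaxes, self.center + self.semiaxes


class _ShellCap(_Solid):
    """Spherical shell (inner..outer radius) cut to z >= zmin: the vault."""

    def __init__(self, center, r_inner, r_outer, zmin):
        self.center = np.asarray(center, dtype=float)
        self.r_inner = float(r_inner)
        self.r_outer = float(r_outer)
        self.zmin = float(zmin)

    def contains_xyz(self, x, y, z):
        d2 = (x - self.center[0]) ** 2 + (y - self.center[1]) ** 2 + (z - self.center[2]) ** 2
        return (d2 >= self.r_inner ** 2) & (d2 <= self.r_outer ** 2) & (z >= self.zmin)

    @property
    def bbox(self):
        lo = self.center - self.r_outer
        lo[2] = self.zmin
        return lo, self.center + self.r_outer


class _Difference(_Solid):
    def __init__(self, base, *subtract):
        self.base = base
        self.subtract = subtract

    def contains_xyz(self, x, y, z):
        mask = self.base.contains_xyz(x, y, z)
        for s in self.subtract:
            mask &= ~s.contains_xyz(x, y, z)
        return mask

    @property
    def bbox(self):
        return self.base.bbox


def _bbox_union(solids):
    los, his = zip(*[s.bbox for s in solids])
    return np.min(los, axis=0), np.max(his, axis=0)


# ---------------------------------------------------------------------------
# skull geometry (F frame: NHP axes, upper incisor at the origin)
# ---------------------------------------------------------------------------

def skull_geometry(include_plate: bool = True) -> dict:
    """Analytic description of the phantom skull.

    Returns static parts (cranial base, soft tissue), per-segment bone
    parts, landmarks, ROI boxes and the chin matching regions, all in the
    F frame (mm).
    """
    vault = _ShellCap(center=(0, -12, 16), r_inner=20, r_outer=26, zmin=14)
    forehead = _Box((-20, 8, 14), (20, 14, 30))
    zygoma_l = _Box((26, 0, 6), (34, 10, 14))
    zygoma_r = _Box((-34, 0, 6), (-26, 10, 14))
    # the soft-tissue envelope is wide enough that its (static) air
    # boundary stays clear of the moving-segment ROI boxes; like a real
    # head it may be clipped by the scan field of view
    soft = _Ellipsoid(center=(0, -8, 5), semiaxes=(40, 38, 42))

    maxilla_bone = _Box((-16, -18, 4), (16, 2, 14))
    tooth_ridge = _Box((-13, -5, -2), (13, 1, 4))

    # rounded chin wedge: an ellipsoid cut by the horizontal genioplasty
    # plane (z = -14); the curved caudal surface constrains all six DOF of
    # the surface match, like a real bony chin
    chin_solid = _Difference(
        _Ellipsoid(center=(0, -1, -16.5), semiaxes=(10.5, 5.5, 3.6)),
        _Box((-20, -20, -14), (20, 20, 0)),
    )
    # the genioplasty kerf: the chin is subtracted from the mandible with a
    # 1.5 mm margin so pre-op segments never touch
    chin_lo, chin_hi = np.array([-10.5, -6.5, -20.1]), np.array([10.5, 4.5, -14.0])
    chin_cut = _Box(chin_lo - 1.5, chin_hi + 1.5)
    mandible = _Difference(
        _Box((-17, -20, -19), (17, 3, -9)),
        _Box((-11.5, -20, -19), (11.5, -6, -9)),   # lingual void of the horseshoe
        chin_cut,
    )

    # each ramus: vertical slab + condylar sphere + a coronoid-like
    # anterior process (the asymmetry anchors all three rotation axes)
    ramus_left = [_Box((21, -18, -15), (27, -6, 6)), _Sphere((24, -12, 6), 3.5),
                  _Sphere((24, -7.5, 4.5), 2.8)]
    ramus_right = [_Box((-27, -18, -15), (-21, -6, 6)), _Sphere((-24, -12, 6), 3.5),
                   _Sphere((-24, -7.5, 4.5), 2.8)]

    plate = _Box((-5, 4.3, -15.3), (5, 5.5, -14.2))

    segments = {
        "maxilla": [(maxilla_bone, "bone"), (tooth_ridge, "teeth")],
        "mandible": [(mandible, "bone")],
        "chin": [(chin_solid, "bone")] + ([(plate, "plate")] if include_plate else []),
        "ramus_left": [(s, "bone") for s in ramus_left],
        "ramus_right": [(s, "bone") for s in ramus_right],
    }
    landmarks = LandmarkSet(
        upper_incisor=(0.0, 0.0, 0.0),
        pogonion=(0.0, 3.8, -16.5),
        condyle_left=(24.0, -12.0, 9.2),
        condyle_right=(-24.0, -12.0, 9.2),
    )
    roi_boxes = {
        "cranial_base": ROIBox((-36, -40, 15), (36, 16, 44), "cranial_base"),
        "maxilla": ROIBox((-21, -19, -7), (21, 11, 13), "maxilla"),
        "mandible": ROIBox((-19, -27, -24), (19, 6, -8), "mandible"),
        "ramus_left": ROIBox((19.5, -21, -17.5), (29, -3.5, 12), "ramus_left"),
        "ramus_right": ROIBox((-29, -21, -17.5), (-19.5, -3.5, 12), "ramus_right"),
        "chin": ROIBox((-15, -6, -25), (15, 13.5, -11), "chin"),
        "chin_pre": ROIBox((-13, -9, -22.5), (13, 7, -11.5), "chin"),
    }
    # matching region for the chin SBM: the |x| limit keeps lateral
    # mandible wall fragments inside the chin ROI box out of the
    # correspondence search; the coarse z guard drops the supra-osteotomy
    # mandible band; the adaptive caudal bands (lowest mm of the remaining
    # surface) emulate painting the unaltered under-side of the chin on
    # each model, wherever the segment actually sits
    _chin_lateral = {"type": "box", "lower": [-11.0, -40.0, -40.0],
                     "upper": [11.0, 40.0, 40.0]}
    chin_regions = {
        "fixed": {"type": "intersection", "parts": [
            {"type": "halfspace", "normal": [0.0, 0.0, 1.0], "offset": -13.0},
            _chin_lateral]},
        "moving": {"type": "intersection", "parts": [
            {"type": "halfspace", "normal": [0.0, 0.0, 1.0], "offset": -15.0},
            _chin_lateral]},
        "bands_mm": {
            "fixed": {"caudal_mm": 3.5, "anterior_mm": 3.0, "anterior_depth_mm": 6.0},
            "moving": {"caudal_mm": 3.0, "anterior_mm": 2.5, "anterior_depth_mm": 5.0},
        },
    }
    return {
        "static": [(vault, "bone"), (forehead, "bone"), (zygoma_l, "bone"), (zygoma_r, "bone")],
        "soft": [(soft, "soft_tissue")],
        "segments": segments,
        "landmarks": landmarks,
        "roi_boxes": roi_boxes,
        "chin_regions": chin_regions,
        "rotation_points": {
            "maxilla": landmarks.upper_incisor,
            "mandible": landmarks.pogonion,
            "chin": landmarks.pogonion,
            "ramus_left": landmarks.condyle_left,
            "ramus_right": landmarks.condyle_right,
        },
    }


# ---------------------------------------------------------------------------
# phantom specification
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Everything that determines a phantom case; same spec => same bits.

    ``planned`` and ``executed`` map segment names to 6-DOF parameter
    dicts (``t_rl, t_ap, t_si`` mm; ``pitch, roll, yaw`` deg) about the
    segment's anatomical rotation point.  ``scan_rotation_deg`` /
    ``scan_translation`` give the rigid scanner pose relative to the NHP
    frame (what the NHP matrix undoes).
    """

    grid_shape: tuple[int, int, int] = (160, 160, 160)
    spacing: float = 0.5
    levels: dict = field(default_factory=lambda: dict(DEFAULT_LEVELS))
    noise_sigma: float = 20.0
    blur_sigma_voxels: float = 0.6
    supersample: int = 2
    planned: dict = field(default_factory=dict)
    executed: dict = field(default_factory=dict)
    include_plate: bool = True
    scan_rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    scan_translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        order = ["air", "soft_tissue", "bone", "teeth", "plate"]
        vals = [self.levels[k] for k in order]
        if not all(a < b for a, b in zip(vals, vals[1:])):
            raise ValueError(f"intensity levels must be strictly increasing, got {vals}")
        if self.supersample < 1:
            raise ValueError("supersample must be >= 1")


@dataclass
class SegmentTruth:
    planned: SegmentMotion
    executed: SegmentMotion
    difference: SegmentMotion
    planned_transform: RigidTransform
    executed_transform: RigidTransform


@dataclass
class PhantomCase:
    """A fully assembled synthetic case plus its ground truth."""

    spec: PhantomSpec
    pre_volume: Volume
    post_volume: Volume
    nhp: NHPMatrix
    landmarks: LandmarkSet          # NHP coordinates
    roi_boxes: dict                 # label -> ROIBox, NHP coordinates
    meshes: dict                    # segment -> (original, planned) TriMesh, scanner frame
    chin_regions: dict              # matching-region predicates, NHP coordinates
    truth: dict                     # segment -> SegmentTruth (F frame)
    scan_to_nhp: RigidTransform     # scanner -> NHP rigid map
    rotation_points: dict           # segment -> F-frame rotation point


def _motion_from_params(params: dict, rotation_point) -> SegmentMotion:
    return SegmentMotion(rotation_point=rotation_point, **params)


def _scan_pose(spec: PhantomSpec) -> RigidTransform:
    """Rigid scanner->F map from the spec's scan pose (F = NHP at incisor)."""
    rx, ry, rz = spec.scan_rotation_deg
    pose = from_parameters(SegmentMotion(pitch=rx, roll=ry, yaw=rz,
                                         t_rl=spec.scan_translation[0],
                                         t_ap=spec.scan_translation[1],
                                         t_si=spec.scan_translation[2]))
    return pose.invert()  # pose maps F -> scanner; we want scanner -> F


def _grid_origin(spec: PhantomSpec, scan_to_f: RigidTransform) -> np.ndarray:
    center_f = np.array([0.0, -12.0, 10.0])  # skull bone centroid, F frame
    center_s = scan_to_f.invert().apply(center_f)
    half = (np.asarray(spec.grid_shape) - 1) / 2.0 * spec.spacing
    return center_s - half


def _paint_part(solid, local_map: RigidTransform, axes, intensity, level_value,
                occupancy=None) -> None:
    """Evaluate one solid on the sub-grid covered by its bounding box.

    ``local_map`` sends scanner coordinates into the solid's own frame;
    only the scanner-axis-aligned bounding box of the solid's world
    footprint is visited, which keeps rendering proportional to solid
    size rather than grid size.
    """
    lo, hi = solid.bbox
    corners = np.array([[lo[i] if b & (1 << i) == 0 else hi[i] for i in range(3)]
                        for b in range(8)])
    world = local_map.invert().apply(corners)  # solid frame -> scanner frame
    wlo, whi = world.min(axis=0), world.max(axis=0)
    idx = []
    for a, ax in enumerate(axes):
        i0 = int(np.searchsorted(ax, wlo[a] - 1e-9))
        i1 = int(np.searchsorted(ax, whi[a] + 1e-9))
        if i0 >= i1:
            return
        idx.append((i0, i1))
    (x0, x1), (y0, y1), (z0, z1) = idx
    X = axes[0][x0:x1, None, None]
    Y = axes[1][None, y0:y1, None]
    Z = axes[2][None, None, z0:z1]
    A = local_map.rotation
    b = local_map.translation_vector
    px = A[0, 0] * X + A[0, 1] * Y + A[0, 2] * Z + b[0]
    py = A[1, 0] * X + A[1, 1] * Y + A[1, 2] * Z + b[1]
    pz = A[2, 0] * X + A[2, 1] * Y + A[2, 2] * Z + b[2]
    mask = solid.contains_xyz(px, py, pz)
    sub = intensity[x0:x1, y0:y1, z0:z1]
    np.maximum(sub, np.where(mask, np.float32(level_value), sub.dtype.type(-np.inf)),
               out=sub)
    if occupancy is not None:
        occupancy[x0:x1, y0:y1, z0:z1] |= mask


def _render_volume(spec: PhantomSpec, geometry: dict, transforms: dict,
                   scan_to_f: RigidTransform, origin: np.ndarray,
                   rng: np.random.Generator, include_plate: bool) -> Volume:
    """Voxelize the (possibly transformed) solids onto the scanner grid."""
    nx, ny, nz = spec.grid_shape
    s = spec.supersample
    d = spec.spacing
    lv = spec.levels

    # supersample coordinates along each axis (scanner frame, mm)
    def axis_coords(n, o):
        u = np.arange(n * s)
        return (o + ((u + 0.5) / s - 0.5) * d).astype(np.float32)

    axes = [axis_coords(nx, origin[0]), axis_coords(ny, origin[1]),
            axis_coords(nz, origin[2])]
    f_to_local = scan_to_f  # scanner -> F; solids of static parts live in F

    intensity = np.full((nx * s, ny * s, nz * s), lv["air"], dtype=np.float32)
    occ_count = np.zeros(intensity.shape, dtype=np.int8)
    group_occ = np.zeros(intensity.shape, dtype=bool)

    for solid, level in geometry["soft"]:
        _paint_part(solid, f_to_local, axes, intensity, lv[level])

    group_occ[:] = False
    for solid, level in geometry["static"]:
        _paint_part(solid, f_to_local, axes, intensity, lv[level], occupancy=group_occ)
    occ_count += group_occ

    for name, parts in geometry["segments"].items():
        T = transforms.get(name) or RigidTransform.identity()
        local_map = T.invert().compose(scan_to_f)  # scanner -> segment frame
        group_occ[:] = False
        for solid, level in parts:
            if level == "plate" and not include_plate:
                continue
            _paint_part(solid, local_map, axes, intensity, lv[level], occupancy=group_occ)
        occ_count += group_occ

    collisions = int(np.count_nonzero(occ_count > 1))
    if collisions:
        raise SegmentCollisionError(
            f"segment collision: {collisions} supersampled points claimed by more "
            "than one bone segment after applying the requested motions"
        )
    del occ_count, group_occ

    out = intensity.reshape(nx, s, ny, s, nz, s).mean(axis=(1, 3, 5))
    del intensity
    if spec.blur_sigma_voxels > 0:
        out = gaussian_filter(out, sigma=spec.blur_sigma_voxels)
    if spec.noise_sigma > 0:
        out = out + rng.normal(0.0, spec.noise_sigma, size=out.shape).astype(np.float32)
    return Volume(data=out.astype(np.float32), spacing=np.full(3, d), origin=origin)


def _segment_mesh(parts, spacing: float, pad: float = 3.0) -> TriMesh:
    """Mesh of a segment's bone solids via partial-volume sampling + marching cubes."""
    solids = [s for s, level in parts if level != "plate"]
    lo, hi = _bbox_union(solids)
    lo, hi = lo - pad, hi + pad
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 2)
    ss = 2
    axes = [lo[a] + ((np.arange(shape[a] * ss) + 0.5) / ss - 0.5) * spacing for a in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij", copy=False)
    pts = np.stack([X, Y, Z], axis=-1)
    ind = np.zeros(pts.shape[:-1], dtype=np.float32)
    for s in solids:
        ind = np.maximum(ind, s.contains(pts).astype(np.float32))
    frac = ind.reshape(shape[0], ss, shape[1], ss, shape[2], ss).mean(axis=(1, 3, 5))
    frac = gaussian_filter(frac, sigma=0.5)
    vol = Volume(data=frac, spacing=np.full(3, spacing), origin=lo)
    return extract_isosurface(vol, IsoSurfaceParams(threshold=0.5))


def check_segment_collisions(spec: PhantomSpec, resolution: float = 1.0) -> int:
    """Count sample points claimed by more than one bone part under the
    executed motions (coarse analytic check; 0 means no collision)."""
    geometry = skull_geometry(spec.include_plate)
    transforms = _executed_transforms(spec, geometry)
    all_solids = [s for s, _ in geometry["static"]]
    for parts in geometry["segments"].values():
        all_solids += [s for s, _ in parts]
    lo, hi = _bbox_union(all_solids)
    lo, hi = lo - 3, hi + 3
    axes = [np.arange(lo[a], hi[a], resolution) for a in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij", copy=False)
    pts = np.stack([X, Y, Z], axis=-1)
    occ = np.zeros(pts.shape[:-1], dtype=np.int8)
    m = np.zeros(pts.shape[:-1], dtype=bool)
    for solid, _ in geometry["static"]:
        m |= solid.contains(pts)
    occ += m
    for name, parts in geometry["segments"].items():
        inv = transforms[name].invert()
        pts_seg = pts @ inv.rotation.T + inv.translation_vector
        m = np.zeros(pts.shape[:-1], dtype=bool)
        for solid, level in parts:
            if level == "plate" and not spec.include_plate:
                continue
            m |= solid.contains(pts_seg)
        occ += m
    return int(np.count_nonzero(occ > 1))


def _executed_transforms(spec: PhantomSpec, geometry: dict) -> dict:
    rp = geometry["rotation_points"]
    return {name: from_parameters(_motion_from_params(spec.executed.get(name, {}), rp[name]))
            for name in geometry["segments"]}


def build_phantom(spec: PhantomSpec) -> PhantomCase:
    """Construct the full synthetic case described by ``spec``."""
    geometry = skull_geometry(spec.include_plate)
    rp = geometry["rotation_points"]
    landmarks_f = geometry["landmarks"]

    planned_motions = {s: _motion_from_params(spec.planned.get(s, {}), rp[s])
                       for s in geometry["segments"]}
    executed_motions = {s: _motion_from_params(spec.executed.get(s, {}), rp[s])
                        for s in geometry["segments"]}
    planned_tf = {s: from_parameters(m) for s, m in planned_motions.items()}
    executed_tf = {s: from_parameters(m) for s, m in executed_motions.items()}

    scan_to_f = _scan_pose(spec)
    origin = _grid_origin(spec, scan_to_f)
    rng = np.random.default_rng(spec.seed)

    pre = _render_volume(spec, geometry, {}, scan_to_f, origin, rng,
                         include_plate=False)
    post = _render_volume(spec, geometry, executed_tf, scan_to_f, origin, rng,
                          include_plate=spec.include_plate)

    # meshes: original in F, planned = rigidly moved copy (same topology),
    # both emitted in the scanner frame like a planning export
    f_to_scan = scan_to_f.invert()
    meshes = {}
    for name, parts in geometry["segments"].items():
        original_f = _segment_mesh(parts, spec.spacing)
        planned_f = original_f.transformed(planned_tf[name])
        meshes[name] = (original_f.transformed(f_to_scan), planned_f.transformed(f_to_scan))

    # ground truth: parameter-wise difference; the chin difference uses the
    # mandible-corrected achieved transform, exactly as reported
    e_m = executed_tf["mandible"].compose(planned_tf["mandible"].invert())
    truth = {}
    for name in geometry["segments"]:
        if name == "chin":
            corrected = e_m.invert().compose(executed_tf["chin"])
            achieved_params = decompose(corrected, rp["chin"])
            diff = achieved_params.subtract(planned_motions["chin"])
        else:
            diff = executed_motions[name].subtract(planned_motions[name])
        truth[name] = SegmentTruth(
            planned=planned_motions[name],
            executed=executed_motions[name],
            difference=diff,
            planned_transform=planned_tf[name],
            executed_transform=executed_tf[name],
        )

    scan_to_nhp = RigidTransform.translation(INCISOR_NHP).compose(scan_to_f)
    return PhantomCase(
        spec=spec,
        pre_volume=pre,
        post_volume=post,
        nhp=NHPMatrix(scan_to_nhp.matrix),
        landmarks=landmarks_f.translated(INCISOR_NHP),
        roi_boxes={k: b.translated(INCISOR_NHP) for k, b in geometry["roi_boxes"].items()},
        meshes=meshes,
        chin_regions=_shift_regions(geometry["chin_regions"], INCISOR_NHP),
        truth=truth,
        scan_to_nhp=scan_to_nhp,
        rotation_points=rp,
    )


def _shift_regions(regions: dict, offset: np.ndarray) -> dict:
    from .pipeline import _shifted_region

    return {key: _shifted_region(cfg, offset) if isinstance(cfg, (list, tuple))
            or (isinstance(cfg, dict) and "type" in cfg) else cfg
            for key, cfg in regions.items()}


# ---------------------------------------------------------------------------
# the canonical validation case
# ---------------------------------------------------------------------------

# ---------------------------------------------------------------------------
# bridging a phantom case into the analysis pipeline
# ---------------------------------------------------------------------------

def to_case_inputs(case: PhantomCase, voxel_params=None, icp_params=None):
    """Package a phantom case as in-memory pipeline inputs."""
    from .pipeline import CaseInputs, PlateExclusion

    lv = case.spec.levels
    kwargs = {}
    if voxel_params is not None:
        kwargs["voxel_params"] = voxel_params
    if icp_params is not None:
        kwargs["icp_params"] = icp_params
    return CaseInputs(
        pre_volume=case.pre_volume,
        post_volume=case.post_volume,
        nhp=case.nhp,
        landmarks=case.landmarks,
        roi_boxes=case.roi_boxes,
        meshes=case.meshes,
        chin_regions=case.chin_regions,
        iso_params=IsoSurfaceParams(
            threshold=0.5 * (lv["soft_tissue"] + lv["bone"]), min_component_size=10),
        plate_exclusion=PlateExclusion(
            enabled=True, upper_threshold=0.75 * lv["plate"], radius=2.0),
        **kwargs,
    )


def truth_frame(case: PhantomCase):
    """Ground truth as a long-format DataFrame (segment, parameter, columns)."""
    import pandas as pd

    rows = []
    for seg, t in case.truth.items():
        params = (("pitch", "roll", "yaw") if seg in RAMUS_SEGMENTS
                  else ("t_rl", "t_ap", "t_si", "pitch", "roll", "yaw"))
        for p in params:
            rows.append({
                "segment": seg, "parameter": p,
                "planned": getattr(t.planned, p),
                "executed": getattr(t.executed, p),
                "difference": getattr(t.difference, p),
            })
    return pd.DataFrame(rows)


def write_case(case: PhantomCase, outdir) -> "Path":
    """Serialize a phantom case to disk as a runnable file-based analysis case.

    Writes NIfTI volumes, STL meshes, the NHP matrix XML, the ground-truth
    table, and a ``case.yaml`` consumable by ``jawmotion analyze``.
    Returns the path of the case file.
    """
    import yaml
    from pathlib import Path
    from .io import write_volume_nifti, write_stl, write_matrix_xml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_volume_nifti(case.pre_volume, outdir / "pre.nii.gz")
    write_volume_nifti(case.post_volume, outdir / "post.nii.gz")
    write_matrix_xml(case.nhp, outdir / "nhp.xml")
    mesh_cfg = {}
    for seg, (orig, plan) in case.meshes.items():
        write_stl(orig, outdir / f"{seg}_original.stl")
        write_stl(plan, outdir / f"{seg}_planned.stl")
        mesh_cfg[seg] = {"original": f"{seg}_original.stl", "planned": f"{seg}_planned.stl"}
    truth_frame(case).to_csv(outdir / "truth.csv", index=False)

    lv = case.spec.levels
    config = {
        "pre_volume": "pre.nii.gz",
        "post_volume": "post.nii.gz",
        "nhp_matrix": "nhp.xml",
        "meshes": mesh_cfg,
        "landmarks": {k: [float(v) for v in getattr(case.landmarks, k)]
                      for k in ("upper_incisor", "pogonion", "condyle_left", "condyle_right")},
        "roi_boxes": [{"key": key, "label": box.label,
                       "lower": [float(v) for v in box.lower],
                       "upper": [float(v) for v in box.upper]}
                      for key, box in case.roi_boxes.items()],
        "chin_regions": case.chin_regions,
        "iso_params": {"threshold": 0.5 * (lv["soft_tissue"] + lv["bone"]),
                       "min_component_size": 10},
        "plate_exclusion": {"enabled": True, "upper_threshold": 0.75 * lv["plate"],
                            "radius": 2.0},
    }
    import json
    path = outdir / "case.yaml"
    # numpy scalars -> plain floats for a clean YAML file
    path.write_text(yaml.safe_dump(json.loads(json.dumps(config, default=float)),
                                   sort_keys=False))
    return path


DEFAULT_PLANNED = {
    "maxilla": {"t_ap": 4.0, "t_si": -2.0, "yaw": 2.0},
    "mandible": {"t_ap": -3.0, "pitch": 3.0},
    "chin": {"t_ap": 5.0, "t_si": -1.0},
    "ramus_left": {"pitch": -2.0, "yaw": 1.5, "roll": 0.8},
    "ramus_right": {"pitch": -2.0, "yaw": -1.5, "roll": -0.8},
}

_JAW_PARAMS = ("t_rl", "t_ap", "t_si", "pitch", "roll", "yaw")
_RAMUS_PARAMS = ("pitch", "roll", "yaw")


def default_validation_spec(
    seed: int = 0,
    grid_size: int = 160,
    spacing: float = 0.5,
    include_plate: bool = True,
    max_error_mm: float = 1.5,
    max_error_deg: float = 1.5,
) -> PhantomSpec:
    """Specification of the canonical phantom (see default_validation_case)."""
    rng = np.random.default_rng(seed)
    geometry = skull_geometry(include_plate)
    rp = geometry["rotation_points"]

    planned = {k: dict(v) for k, v in DEFAULT_PLANNED.items()}
    errors = {}
    for seg in SEGMENTS:
        params = _RAMUS_PARAMS if seg in RAMUS_SEGMENTS else _JAW_PARAMS
        errors[seg] = {
            p: float(rng.uniform(-1, 1) * (max_error_deg if p in _RAMUS_PARAMS
                                           else max_error_mm))
            for p in params
        }

    executed = {}
    for seg in SEGMENTS:
        if seg == "chin":
            continue
        executed[seg] = {p: planned[seg].get(p, 0.0) + errors[seg].get(p, 0.0)
                         for p in (_RAMUS_PARAMS if seg in RAMUS_SEGMENTS else _JAW_PARAMS)}
    # chin: own plan + own error, carried on the mandibular execution error
    p_m = from_parameters(SegmentMotion(rotation_point=rp["mandible"], **planned["mandible"]))
    a_m = from_parameters(SegmentMotion(rotation_point=rp["mandible"], **executed["mandible"]))
    e_m = a_m.compose(p_m.invert())
    chin_own = {p: planned["chin"].get(p, 0.0) + errors["chin"].get(p, 0.0)
                for p in _JAW_PARAMS}
    t_chin = e_m.compose(from_parameters(SegmentMotion(rotation_point=rp["chin"], **chin_own)))
    chin_exec = decompose(t_chin, rp["chin"])
    executed["chin"] = chin_exec.parameters()

    scan_rot = tuple(rng.uniform(-3.0, 3.0, size=3))
    scan_tr = tuple(rng.uniform(-4.0, 4.0, size=3))
    return PhantomSpec(
        grid_shape=(grid_size,) * 3,
        spacing=spacing,
        planned=planned,
        executed=executed,
        include_plate=include_plate,
        scan_rotation_deg=scan_rot,
        scan_translation=scan_tr,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def default_validation_case(
    seed: int = 0,
    grid_size: int = 160,
    spacing: float = 0.5,
    include_plate: bool = True,
    max_error_mm: float = 1.5,
    max_error_deg: float = 1.5,
) -> PhantomCase:
    """The canonical phantom: surgery executed with seeded errors.

    Planned moves are clinically typical (maxillary advancement/impaction
    with slight yaw, mandibular setback with counter-clockwise pitch, chin
    advancement, small ramus rotations).  Executed motions equal the plan
    plus per-parameter errors drawn uniformly within ±1.5 mm / ±1.5 deg.
    The chin additionally rides on the mandibular execution error, as a
    plated genioplasty segment does, so its corrected difference equals
    its own injected error exactly.
    """
    return build_phantom(default_validation_spec(
        seed, grid_size, spacing, include_plate, max_error_mm, max_error_deg))
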
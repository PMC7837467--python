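"""Surface model generation and surface-based matching (SBM).

The chin segment is matched on surfaces rather than voxels: the
high-density osteosynthesis plate fixed over the genioplasty osteotomy
biases greyscale matching of the small chin volume (most visibly as a
pitch deviation), so the chin is registered with a trimmed
iterative-closest-point match restricted to the unaltered caudal part of
the bone surface, with vertices near high-density material excluded.

SBM is also used to recover the *planned* motion of every segment from the
planning export: when the planned STL is a rigidly moved copy of the
pre-operative STL (same vertex topology), the motion follows exactly from
the orthogonal Procrustes problem; otherwise ICP is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import RigidTransform
from .io import TriMesh, Volume

__all__ = [
    "IsoSurfaceParams",
    "ICPParams",
    "ICPResult",
    "Region",
    "HalfSpace",
    "BoxRegion",
    "SphereRegion",
    "extract_isosurface",
    "select_matching_region",
    "exclude_high_density",
    "register_icp",
    "compute_planned_transform",
    "kabsch",
]


# ---------------------------------------------------------------------------
# isosurface extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IsoSurfaceParams:
    """Marching-cubes parameters for bone surface generation.

    ``threshold`` is the (uncalibrated) intensity of the bone isosurface,
    typically midway between the soft-tissue and bone levels of the scan;
    connected components with fewer than ``min_component_size`` faces are
    dropped as segmentation noise.
    """

    threshold: float
    min_component_size: int = 0
    smoothing_iterations: int = 0

    def __post_init__(self) -> None:
        if self.min_component_size < 0 or self.smoothing_iterations < 0:
            raise ValueError("counts must be >= 0")


def extract_isosurface(volume: Volume, params: IsoSurfaceParams) -> TriMesh:
    """Extract the bone isosurface of ``volume`` as a mesh in world mm."""
    from skimage import measure

    lo, hi = float(volume.data.min()), float(volume.data.max())
    if not (lo < params.threshold < hi):
        raise ValueError(
            f"isosurface threshold {params.threshold} outside the volume's "
            f"intensity range [{lo}, {hi}]"
        )
    verts, faces, _, _ = measure.marching_cubes(
        np.asarray(volume.data, dtype=np.float32),
        level=params.threshold,
        spacing=tuple(volume.spacing),
    )
    world = volume.origin + verts @ volume.orientation.T

    mesh = TriMesh(vertices=world, faces=faces)
    if params.min_component_size > 0:
        mesh = _drop_small_components(mesh, params.min_component_size)
        if len(mesh.faces) == 0:
            raise ValueError("no surface component survives the size filter")
    if params.smoothing_iterations > 0:
        tm = mesh.to_trimesh()
        import trimesh.smoothing as sm
        sm.filter_taubin(tm, iterations=params.smoothing_iterations)
        mesh = TriMesh(vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces))
    return mesh


def _drop_small_components(mesh: TriMesh, min_faces: int) -> TriMesh:
    import trimesh

    tm = mesh.to_trimesh()
    parts = tm.split(only_watertight=False)
    keep = [p for p in parts if len(p.faces) >= min_faces]
    if not keep:
        return TriMesh(vertices=np.zeros((0, 3)), faces=np.zeros((0, 3), dtype=int))
    merged = trimesh.util.concatenate(keep)
    return TriMesh(vertices=np.asarray(merged.vertices), faces=np.asarray(merged.faces))


# ---------------------------------------------------------------------------
# matching-region selection
# ---------------------------------------------------------------------------

class Region:
    """Geometric predicate over mm points; unions are lists of regions."""

    def contains(self, points: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @staticmethod
    def from_config(cfg) -> "Region":
        if isinstance(cfg, Region):
            return cfg
        if isinstance(cfg, (list, tuple)):
            return UnionRegion([Region.from_config(c) for c in cfg])
        kind = cfg["type"]
        if kind == "halfspace":
            return HalfSpace(cfg["normal"], cfg["offset"])
        if kind == "box":
            return BoxRegion(cfg["lower"], cfg["upper"])
        if kind == "sphere":
            return SphereRegion(cfg["center"], cfg["radius"])
        if kind == "intersection":
            return IntersectionRegion([Region.from_config(c) for c in cfg["parts"]])
        if kind == "union":
            return UnionRegion([Region.from_config(c) for c in cfg["parts"]])
        raise ValueError(f"unknown region type {kind!r}")


@dataclass(frozen=True)
class HalfSpace(Region):
    """Points with ``normal . x <= offset`` (e.g. the caudal part of the chin)."""

    normal: np.ndarray
    offset: float

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float).reshape(3)
        object.__setattr__(self, "normal", n)
        object.__setattr__(self, "offset", float(self.offset))

    def contains(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.normal <= self.offset


@dataclass(frozen=True)
class BoxRegion(Region):
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "lower", np.asarray(self.lower, dtype=float).reshape(3))
        object.__setattr__(self, "upper", np.asarray(self.upper, dtype=float).reshape(3))

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        return np.all((pts >= self.lower) & (pts <= self.upper), axis=1)


@dataclass(frozen=True)
class SphereRegion(Region):
    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float).reshape(3))

    def contains(self, points: np.ndarray) -> np.ndarray:
        return np.linalg.norm(np.atleast_2d(points) - self.center, axis=1) <= self.radius


@dataclass(frozen=True)
class UnionRegion(Region):
    parts: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "parts", tuple(self.parts))

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        mask = np.zeros(len(pts), dtype=bool)
        for p in self.parts:
            mask |= p.contains(pts)
        return mask


@dataclass(frozen=True)
class IntersectionRegion(Region):
    parts: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "parts", tuple(self.parts))

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        mask = np.ones(len(pts), dtype=bool)
        for p in self.parts:
            mask &= p.contains(pts)
        return mask


def select_matching_region(mesh: TriMesh, region, min_vertices: int = 100) -> TriMesh:
    """Mark the vertices inside ``region`` as the matching surface.

    Mirrors the interactive step of painting the unaltered caudal part of
    the chin: only selected vertices take part in correspondence search.
    An existing selection is intersected with the region.
    """
    region = Region.from_config(region)
    mask = region.contains(mesh.vertices)
    if mesh.selection is not None:
        mask &= mesh.selection
    if mask.sum() < min_vertices:
        raise ValueError(
            f"selection too small: {int(mask.sum())} vertices selected "
            f"(minimum {min_vertices})"
        )
    return TriMesh(mesh.vertices.copy(), mesh.faces.copy(), mask)


def exclude_high_density(
    mesh: TriMesh, volume: Volume, upper_threshold: float, radius: float
) -> TriMesh:
    """Deselect vertices near high-density material (osteosynthesis plate).

    Any vertex whose surrounding sphere of ``radius`` mm contains a voxel
    above ``upper_threshold`` is removed from the matching selection.
    ``radius`` 0 deselects only vertices coincident with such voxels.
    """
    hot = np.argwhere(volume.data > upper_threshold)
    selection = (np.ones(len(mesh.vertices), dtype=bool)
                 if mesh.selection is None else mesh.selection.copy())
    if len(hot):
        hot_world = volume.world_from_index(hot)
        d, _ = cKDTree(hot_world).query(mesh.vertices)
        selection &= d > radius
    return TriMesh(mesh.vertices.copy(), mesh.faces.copy(), selection)


# ---------------------------------------------------------------------------
# trimmed ICP
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ICPParams:
    """Trimmed point-to-point ICP settings.

    ``trim_fraction`` is the fraction of candidate correspondences kept at
    each iteration (the closest ones), which makes the match robust to the
    altered cranial part of the chin and to resection edges;
    ``max_correspondence_distance`` (mm) discards pairs beyond plausible
    surgical displacement residuals.  Iterations stop when neither the
    trimmed RMS nor any matched point moves by more than
    ``convergence_rms_delta`` mm in one update (re-trimming makes the RMS
    jitter at sub-micrometre scale, far below surgical relevance).
    """

    max_iterations: int = 200
    trim_fraction: float = 0.9
    convergence_rms_delta: float = 1e-6
    max_correspondence_distance: float = 10.0
    variant: str = "point_to_plane"

    def __post_init__(self) -> None:
        if not (0 < self.trim_fraction <= 1):
            raise ValueError("trim_fraction must be in (0, 1]")
        if self.convergence_rms_delta <= 0:
            raise ValueError("convergence_rms_delta must be > 0")
        if self.variant not in ("point_to_point", "point_to_plane"):
            raise ValueError(f"unknown ICP variant {self.variant!r}")


@dataclass
class ICPResult:
    transform: RigidTransform
    rms: float
    iterations: int
    rms_trace: list[float] = field(default_factory=list)


def kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping ``src`` onto ``dst`` (Kabsch/SVD).

    Raises on rank-deficient (collinear or coincident) point sets, which
    leave rotation components unconstrained.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    src0, dst0 = src - cs, dst - cd
    H = src0.T @ dst0
    U, S, Vt = np.linalg.svd(H)
    scale = np.linalg.norm(src0) * np.linalg.norm(dst0)
    if scale > 0 and S[1] / (S[0] + 1e-300) < 1e-9:
        raise ValueError("underconstrained: correspondence geometry is rank-deficient")
    D = np.eye(3)
    D[2, 2] = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ D @ U.T
    return RigidTransform.from_rotation_translation(R, cd - R @ cs)


def _vertex_normals(mesh: TriMesh) -> np.ndarray:
    tm = mesh.to_trimesh()
    return np.asarray(tm.vertex_normals, dtype=float)


def _point_to_plane_update(src, dst, normals) -> RigidTransform:
    """One linearized point-to-plane step: minimize sum(n . (src + w x src + t - dst))^2."""
    A = np.hstack([np.cross(src, normals), normals])
    b = np.einsum("ij,ij->i", normals, dst - src)
    s = np.linalg.svd(A, compute_uv=False)
    if s[-1] / (s[0] + 1e-300) < 1e-9:
        raise ValueError("underconstrained: correspondence geometry is rank-deficient")
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    from scipy.spatial.transform import Rotation
    R = Rotation.from_rotvec(x[:3]).as_matrix()
    return RigidTransform.from_rotation_translation(R, x[3:])


def register_icp(
    fixed: TriMesh,
    moving: TriMesh,
    params: ICPParams | None = None,
    init: RigidTransform | None = None,
) -> ICPResult:
    """Trimmed ICP of ``moving``'s selection onto ``fixed``.

    Returns the rigid transform mapping moving-frame points to fixed-frame
    points that minimizes the trimmed distance between selected moving
    vertices and the selected fixed surface.  The default point-to-plane
    variant lets correspondences slide tangentially along the fixed
    surface, which removes the discretization bias of matching two
    independently triangulated surfaces; ``point_to_point`` (Kabsch on
    nearest neighbors) is available for exactly corresponding meshes.
    """
    from .voxel import RegistrationError

    params = params or ICPParams()
    T = init or RigidTransform.identity()

    fixed_sel = (np.ones(len(fixed.vertices), dtype=bool)
                 if fixed.selection is None else fixed.selection)
    fixed_pts = fixed.vertices[fixed_sel]
    moving_pts = moving.selected_vertices
    if len(fixed_pts) < 3 or len(moving_pts) < 3:
        raise ValueError("need at least 3 selected vertices on each mesh")
    tree = cKDTree(fixed_pts)
    if params.variant == "point_to_plane":
        fixed_normals = _vertex_normals(fixed)[fixed_sel]

    trace: list[float] = []
    best_rms = np.inf
    best_T = T
    best_iteration = 0
    stall = 0
    converged = False
    for iteration in range(1, params.max_iterations + 1):
        mv = T.apply(moving_pts)
        d, idx = tree.query(mv)
        in_range = d <= params.max_correspondence_distance
        n_pairs = int(in_range.sum())
        if n_pairs < 3:
            raise RegistrationError(
                f"insufficient surface overlap: {n_pairs} correspondences within "
                f"{params.max_correspondence_distance} mm", trace,
            )
        keep_n = max(3, int(np.floor(params.trim_fraction * n_pairs)))
        candidates = np.where(in_range)[0]
        order = np.argsort(d[candidates], kind="stable")
        keep = candidates[order[:keep_n]]

        if params.variant == "point_to_plane":
            # rank poses by the actual objective: vertex-to-vertex NN
            # distance is floored by the two independent triangulations
            # and would bias the pose toward lattice alignment
            resid = np.einsum("ij,ij->i", fixed_normals[idx[keep]],
                              mv[keep] - fixed_pts[idx[keep]])
            new_rms = float(np.sqrt(np.mean(resid ** 2)))
        else:
            new_rms = float(np.sqrt(np.mean(d[keep] ** 2)))
        trace.append(new_rms)
        if new_rms < best_rms - params.convergence_rms_delta:
            best_rms, best_T, best_iteration = new_rms, T, iteration
            stall = 0
        else:
            # re-trimming can limit-cycle at sub-micrometre amplitude; a
            # plateau of the best RMS is the convergence signal
            stall += 1
            if stall >= 10:
                converged = True
                break
        try:
            if params.variant == "point_to_point":
                T = kabsch(moving_pts[keep], fixed_pts[idx[keep]])
            else:
                delta = _point_to_plane_update(
                    mv[keep], fixed_pts[idx[keep]], fixed_normals[idx[keep]])
                T = delta.compose(T)
        except ValueError as exc:
            raise RegistrationError(str(exc), trace) from exc
    if not converged:
        raise RegistrationError(
            f"ICP did not converge in {params.max_iterations} iterations "
            f"(last RMS {trace[-1]:.4g} mm)", trace,
        )
    return ICPResult(transform=best_T, rms=best_rms, iterations=best_iteration,
                     rms_trace=trace)


# ---------------------------------------------------------------------------
# planned motion from the planning export
# ---------------------------------------------------------------------------

def compute_planned_transform(
    preop_mesh: TriMesh,
    planned_mesh: TriMesh,
    icp_params: ICPParams | None = None,
) -> RigidTransform:
    """Recover the planned rigid motion from original and planned STL models.

    Planning software moves segments rigidly, so the exported planned mesh
    usually shares its vertex topology with the pre-operative mesh; the
    motion then follows exactly from corresponding vertices (orthogonal
    Procrustes).  When the export broke topology (decimation, remeshing),
    a trimmed ICP fallback is used.
    """
    same_topology = (
        len(preop_mesh.vertices) == len(planned_mesh.vertices)
        and preop_mesh.faces.shape == planned_mesh.faces.shape
        and np.array_equal(preop_mesh.faces, planned_mesh.faces)
    )
    if same_topology:
        return kabsch(preop_mesh.vertices, planned_mesh.vertices)

    params = icp_params or ICPParams(max_correspondence_distance=25.0)
    # centroid shift as rough initialization; planned moves are small
    init = RigidTransform.translation(
        planned_mesh.vertices.mean(axis=0) - preop_mesh.vertices.mean(axis=0)
    )
    return register_icp(planned_mesh, preop_mesh, params, init).transform
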
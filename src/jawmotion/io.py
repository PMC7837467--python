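"""Readers and writers for the formats the pipeline touches.

Volumes come in as DICOM series or NIfTI-1 images and are carried as
:class:`Volume` (scalar grid + spacing/origin/orientation in mm, world
coordinates in the DICOM LPS convention).  Segment models are STL meshes,
the natural-head-position matrix is a small XML file, and the final
accuracy report is CSV.

CBCT grey values are uncalibrated, so intensities are treated as arbitrary
scalars; every threshold downstream is configuration, not a fixed HU.
"""

from __future__ import annotations

import os
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

try:  # SimpleITK is only needed for the voxel-registration bridge
    import SimpleITK as sitk
except ImportError:  # pragma: no cover
    sitk = None

__all__ = [
    "Volume",
    "TriMesh",
    "NHPMatrix",
    "read_dicom_series",
    "read_volume_nifti",
    "write_volume_nifti",
    "read_stl",
    "write_stl",
    "read_matrix_xml",
    "write_matrix_xml",
    "write_report",
    "read_report",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Volume:
    """A 3D scalar grid with world geometry.

    ``data[i, j, k]`` sits at world position
    ``origin + orientation @ (spacing * (i, j, k))`` (mm).  ``orientation``
    is a proper rotation (orthonormal, det +1); its columns are the world
    directions of the three index axes.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"volume data must be 3D with positive dims, got {self.data.shape}")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.orientation = np.asarray(self.orientation, dtype=float).reshape(3, 3)
        if np.abs(self.orientation.T @ self.orientation - np.eye(3)).max() > 1e-6:
            raise ValueError("orientation must be orthonormal")
        if np.linalg.det(self.orientation) < 0:
            raise ValueError("orientation must be right-handed (det +1)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def world_from_index(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        return self.origin + (ijk * self.spacing) @ self.orientation.T

    def index_from_world(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return ((xyz - self.origin) @ self.orientation) / self.spacing

    def transformed(self, transform) -> "Volume":
        """The same voxel grid expressed in a rigidly transformed world frame.

        Only the geometry metadata changes; no resampling happens.
        """
        R = transform.rotation
        return Volume(
            data=self.data,
            spacing=self.spacing,
            origin=transform.apply(self.origin),
            orientation=R @ self.orientation,
        )

    # -- SimpleITK bridge --------------------------------------------
    def to_sitk(self):
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.data.T).astype(np.float32))
        img.SetSpacing(tuple(self.spacing))
        img.SetOrigin(tuple(self.origin))
        img.SetDirection(tuple(self.orientation.flatten()))
        return img

    @classmethod
    def from_sitk(cls, img) -> "Volume":
        return cls(
            data=sitk.GetArrayFromImage(img).T,
            spacing=np.array(img.GetSpacing()),
            origin=np.array(img.GetOrigin()),
            orientation=np.array(img.GetDirection()).reshape(3, 3),
        )


@dataclass
class TriMesh:
    """A triangle surface mesh in mm world coordinates.

    ``selection`` is an optional per-vertex boolean mask marking the
    matching region used by surface-based registration (the surface a user
    would paint); ``None`` means all vertices participate.
    """

    vertices: np.ndarray
    faces: np.ndarray
    selection: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        n = len(self.vertices)
        if len(self.faces) and (self.faces.min() < 0 or self.faces.max() >= n):
            raise ValueError("face indices out of range")
        if self.selection is not None:
            self.selection = np.asarray(self.selection, dtype=bool).reshape(-1)
            if len(self.selection) != n:
                raise ValueError("selection mask length must equal vertex count")

    @property
    def selected_vertices(self) -> np.ndarray:
        if self.selection is None:
            return self.vertices
        return self.vertices[self.selection]

    def transformed(self, transform) -> "TriMesh":
        return TriMesh(transform.apply(self.vertices), self.faces.copy(),
                       None if self.selection is None else self.selection.copy())

    def to_trimesh(self):
        import trimesh
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)


@dataclass(frozen=True)
class NHPMatrix:
    """4x4 homogeneous matrix mapping the scanner frame to natural head position."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"expected 4x4 matrix, got {m.shape}")
        R = m[:3, :3]
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-4:
            raise ValueError("NHP rotation block is not orthonormal (scale/shear present)")
        if np.linalg.det(R) < 0:
            raise ValueError("NHP rotation block is a reflection (det -1)")
        if not np.allclose(m[3], [0, 0, 0, 1], atol=1e-6):
            raise ValueError("last row of NHP matrix must be (0, 0, 0, 1)")
        m = m.copy()
        m.flags.writeable = False
        object.__setattr__(self, "matrix", m)

    def to_rigid(self):
        from .geometry import RigidTransform
        # re-orthonormalize: XML matrices are stored at limited precision
        U, _, Vt = np.linalg.svd(self.matrix[:3, :3])
        R = U @ Vt
        if np.linalg.det(R) < 0:
            U[:, -1] *= -1
            R = U @ Vt
        return RigidTransform.from_rotation_translation(R, self.matrix[:3, 3])


# ---------------------------------------------------------------------------
# DICOM
# ---------------------------------------------------------------------------

def read_dicom_series(directory: str | os.PathLike) -> Volume:
    """Assemble a single-frame CT/CBCT series into a :class:`Volume`.

    Slices are sorted by their position along the slice normal; per-slice
    rescale slope/intercept is applied.  Mixed series UIDs and non-uniform
    slice spacing (beyond 1e-3 mm) are rejected.
    """
    import pydicom

    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file() and p.suffix.lower() != ".txt")
    datasets = []
    for p in files:
        try:
            datasets.append(pydicom.dcmread(p))
        except Exception:
            continue
    if not datasets:
        raise ValueError(f"no readable DICOM files in {directory}")

    uids = {ds.SeriesInstanceUID for ds in datasets}
    if len(uids) > 1:
        raise ValueError(f"directory mixes {len(uids)} series UIDs: {sorted(uids)}")
    if len(datasets) < 2:
        raise ValueError("series has a single slice; slice spacing cannot be inferred")

    iop = np.array(datasets[0].ImageOrientationPatient, dtype=float)
    row_dir, col_dir = iop[:3], iop[3:]
    normal = np.cross(row_dir, col_dir)
    positions = np.array([np.dot(ds.ImagePositionPatient, normal) for ds in datasets])
    order = np.argsort(positions)
    datasets = [datasets[i] for i in order]
    positions = positions[order]

    gaps = np.diff(positions)
    if np.any(gaps <= 0):
        raise ValueError("duplicate slice positions in series")
    if gaps.max() - gaps.min() > 1e-3:
        i = int(np.argmax(np.abs(gaps - np.median(gaps))))
        raise ValueError(
            f"non-uniform slice spacing: gap {gaps[i]:.4f} mm between slices {i} and {i + 1} "
            f"vs median {np.median(gaps):.4f} mm"
        )
    slice_spacing = float(np.mean(gaps))

    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float32)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    stack = np.stack(slices, axis=0)  # (slice, row, col)

    ps = np.array(datasets[0].PixelSpacing, dtype=float)  # (row, col)
    # data[i, j, k]: i along row_dir (in-slice column index), j along
    # col_dir (in-slice row index), k along the slice normal
    data = stack.transpose(2, 1, 0)
    orientation = np.column_stack([row_dir, col_dir, normal])
    origin = np.array(datasets[0].ImagePositionPatient, dtype=float)
    return Volume(data=data, spacing=np.array([ps[1], ps[0], slice_spacing]),
                  origin=origin, orientation=orientation)


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

_RAS_TO_LPS = np.diag([-1.0, -1.0, 1.0])


def read_volume_nifti(path: str | os.PathLike) -> Volume:
    """Read a NIfTI-1 image; the RAS affine is converted to LPS world.

    Affines with shear or scale beyond floating-point noise are rejected:
    the pipeline's world geometry is strictly rigid.
    """
    import nibabel as nib

    img = nib.load(str(path))
    affine = img.affine.copy()
    affine[:2] *= -1  # RAS -> LPS
    A = affine[:3, :3]
    spacing = np.linalg.norm(A, axis=0)
    if np.any(spacing <= 0):
        raise ValueError("degenerate NIfTI affine (zero column)")
    orientation = A / spacing
    if np.abs(orientation.T @ orientation - np.eye(3)).max() > 1e-4:
        raise ValueError("NIfTI affine is not rigid (shear present)")
    if np.linalg.det(orientation) < 0:
        raise ValueError("left-handed NIfTI orientation; expected a proper rotation")
    data = np.asarray(img.dataobj).astype(np.float32)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D image, got {data.ndim}D")
    # re-orthonormalize against header round-off
    U, _, Vt = np.linalg.svd(orientation)
    return Volume(data=data, spacing=spacing, origin=affine[:3, 3], orientation=U @ Vt)


def write_volume_nifti(volume: Volume, path: str | os.PathLike) -> None:
    import nibabel as nib

    affine = np.eye(4)
    affine[:3, :3] = volume.orientation * volume.spacing
    affine[:3, 3] = volume.origin
    affine[:2] *= -1  # LPS -> RAS
    nib.save(nib.Nifti1Image(volume.data.astype(np.float32), affine), str(path))


# ---------------------------------------------------------------------------
# STL
# ---------------------------------------------------------------------------

def read_stl(path: str | os.PathLike) -> TriMesh:
    """Read an ASCII or binary STL; vertices are deduplicated within 1e-6 mm."""
    import trimesh

    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"empty or missing STL file: {path}")
    try:
        m = trimesh.load(str(path), file_type="stl", process=False)
    except Exception as exc:
        raise ValueError(f"unreadable STL file {path}: {exc}") from exc
    if not hasattr(m, "vertices") or len(m.vertices) == 0 or len(m.faces) == 0:
        raise ValueError(f"STL file {path} contains no triangles")
    verts = np.asarray(m.vertices, dtype=float)
    faces = np.asarray(m.faces, dtype=np.int64)
    # dedup within 1e-6 mm by rounding to that grid
    key = np.round(verts / 1e-6).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    verts = verts[np.sort(first)]
    remap = np.empty(len(first), dtype=np.int64)
    remap[np.argsort(first)] = np.arange(len(first))
    faces = remap[inverse][faces]
    # drop degenerate faces (repeated vertex after dedup)
    ok = (faces[:, 0] != faces[:, 1]) & (faces[:, 1] != faces[:, 2]) & (faces[:, 0] != faces[:, 2])
    return TriMesh(vertices=verts, faces=faces[ok])


def write_stl(mesh: TriMesh, path: str | os.PathLike) -> None:
    mesh.to_trimesh().export(str(path), file_type="stl")


# ---------------------------------------------------------------------------
# XML transformation matrix
# ---------------------------------------------------------------------------
#
# Minimal vendor-agnostic schema:
#
#   <transform rows="4" cols="4">
#     1 0 0 0   0 1 0 0   0 0 1 0   0 0 0 1
#   </transform>
#
# 16 whitespace-separated floats, row-major.  Vendor planning exports can be
# adapted by registering a parser hook keyed on the XML root tag.

_XML_DIALECTS: dict[str, callable] = {}


def register_xml_dialect(root_tag: str, parser) -> None:
    """Register ``parser(ElementTree root) -> 4x4 array`` for a vendor dialect."""
    _XML_DIALECTS[root_tag] = parser


def read_matrix_xml(path: str | os.PathLike) -> NHPMatrix:
    tree = ET.parse(str(path))
    root = tree.getroot()
    if root.tag in _XML_DIALECTS:
        values = np.asarray(_XML_DIALECTS[root.tag](root), dtype=float)
    elif root.tag == "transform":
        text = root.text or ""
        parts = text.split()
        if len(parts) != 16:
            raise ValueError(f"expected 16 matrix entries, found {len(parts)}")
        values = np.array([float(v) for v in parts]).reshape(4, 4)
    else:
        raise ValueError(
            f"unknown XML matrix dialect with root <{root.tag}>; "
            "register a parser with register_xml_dialect()"
        )
    return NHPMatrix(values)


def write_matrix_xml(matrix: NHPMatrix | np.ndarray, path: str | os.PathLike) -> None:
    m = matrix.matrix if isinstance(matrix, NHPMatrix) else np.asarray(matrix, dtype=float)
    NHPMatrix(m)  # validate
    rows = "\n  ".join(" ".join(f"{v:.17g}" for v in row) for row in m)
    Path(path).write_text(f'<transform rows="4" cols="4">\n  {rows}\n</transform>\n')


# ---------------------------------------------------------------------------
# accuracy report CSV
# ---------------------------------------------------------------------------

JAW_SEGMENTS = ("maxilla", "mandible", "chin")
RAMUS_SEGMENTS = ("ramus_left", "ramus_right")
TRANSLATION_PARAMS = ("t_rl", "t_ap", "t_si")
ROTATION_PARAMS = ("pitch", "roll", "yaw")


def write_report(report, path: str | os.PathLike, decimals: int = 4) -> None:
    """Write an accuracy report as CSV: one row per (segment, parameter).

    Jaw segments (maxilla, mandible, chin) report three translations and
    three rotations; ramus segments report rotations only.
    """
    import pandas as pd

    rows = []
    for segment in JAW_SEGMENTS + RAMUS_SEGMENTS:
        entry = report.segments[segment]
        params = (TRANSLATION_PARAMS + ROTATION_PARAMS
                  if segment in JAW_SEGMENTS else ROTATION_PARAMS)
        for p in params:
            rows.append({
                "segment": segment,
                "parameter": p,
                "unit": "mm" if p.startswith("t_") else "deg",
                "planned": round(getattr(entry.planned, p), decimals),
                "achieved": round(getattr(entry.achieved, p), decimals),
                "difference": round(getattr(entry.difference, p), decimals),
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_report(path: str | os.PathLike):
    import pandas as pd

    return pd.read_csv(path)
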
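"""End-to-end orchestration: from raw inputs to the accuracy report.

The analysis expresses everything in the NHP frame with the upper incisor
at the origin, then

1. recovers each segment's *planned* motion by matching the original
   planning model to the planned model (Procrustes/SBM),
2. aligns the post-operative scan to the pre-operative scan on the
   surgically unaffected cranial-base ROI (global VBM),
3. recovers each segment's *achieved* motion — VBM on a segment ROI box
   for maxilla, mandible and both rami; trimmed-ICP surface matching of
   the caudal chin with high-density (plate) exclusion for the chin,
4. corrects the achieved chin transform for the mandibular execution
   error, so the chin is judged only on its own osteotomy,
5. decomposes every transform about its anatomical rotation point and
   reports planned / achieved / difference per parameter.

The difference is the parameter-wise ``achieved - planned``, matching the
three-column clinical report layout.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .geometry import (RigidTransform, LandmarkSet, SegmentMotion,
                       decompose, ramus_rotations)
from .io import (Volume, TriMesh, NHPMatrix, read_volume_nifti, read_dicom_series,
                 read_stl, read_matrix_xml, write_report)
from .surface import (IsoSurfaceParams, ICPParams, extract_isosurface,
                      select_matching_region, exclude_high_density, register_icp,
                      compute_planned_transform)
from .voxel import ROIBox, VoxelRegistrationParams, register_rigid_voxel, extract_roi

__all__ = [
    "CaseInputs",
    "CaseConfig",
    "AccuracyReport",
    "SegmentResult",
    "PipelineStageError",
    "align_nhp",
    "assign_rotation_points",
    "correct_chin",
    "analyze_case",
    "run_case",
]

JAW_SEGMENTS = ("maxilla", "mandible", "chin")
RAMUS_SEGMENTS = ("ramus_left", "ramus_right")
SEGMENTS = JAW_SEGMENTS + RAMUS_SEGMENTS
VBM_SEGMENTS = ("maxilla", "mandible", "ramus_left", "ramus_right")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the partial log."""

    def __init__(self, stage: str, cause: Exception, log: list):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
        self.log = log


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PlateExclusion:
    enabled: bool = True
    upper_threshold: float = 2250.0   # default: plate level x 0.75
    radius: float = 2.0               # mm around each surface vertex


@dataclass
class CaseInputs:
    """All in-memory inputs of one case (scanner/NHP coordinates as noted)."""

    pre_volume: Volume                  # scanner frame
    post_volume: Volume                 # scanner frame
    nhp: NHPMatrix                      # scanner -> NHP
    landmarks: LandmarkSet              # NHP coordinates
    roi_boxes: dict                     # label -> ROIBox, NHP coordinates
    meshes: dict                        # segment -> (original, planned), scanner frame
    chin_regions: dict                  # {'fixed': cfg, 'moving': cfg}, NHP coordinates
    iso_params: IsoSurfaceParams = field(
        default_factory=lambda: IsoSurfaceParams(threshold=380.0, min_component_size=10))
    icp_params: ICPParams = field(default_factory=ICPParams)
    voxel_params: VoxelRegistrationParams = field(default_factory=VoxelRegistrationParams)
    plate_exclusion: PlateExclusion = field(default_factory=PlateExclusion)

    def __post_init__(self) -> None:
        missing = [s for s in SEGMENTS if s not in self.meshes]
        if missing:
            raise ValueError(f"segments missing planning meshes: {missing}")
        need = {"cranial_base", "maxilla", "mandible", "ramus_left", "ramus_right",
                "chin", "chin_pre"}
        absent = need - set(self.roi_boxes)
        if absent:
            raise ValueError(f"missing ROI boxes: {sorted(absent)}")


@dataclass
class CaseConfig:
    """File-based case description (what ``jawmotion analyze`` reads)."""

    pre_volume: str
    post_volume: str
    nhp_matrix: str
    meshes: dict                 # segment -> {original: path, planned: path}
    landmarks: dict              # name -> [x, y, z] in NHP mm
    roi_boxes: list              # [{label, lower, upper}] in NHP mm
    chin_regions: dict
    iso_params: dict = field(default_factory=dict)
    icp_params: dict = field(default_factory=dict)
    voxel_params: dict = field(default_factory=dict)
    plate_exclusion: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "CaseConfig":
        import yaml
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) else json.loads(text)
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def load(self, base_dir=None) -> CaseInputs:
        base = Path(base_dir) if base_dir else Path(".")

        def p(rel):
            path = Path(rel)
            return path if path.is_absolute() else base / path

        def load_volume(path):
            path = p(path)
            return read_dicom_series(path) if path.is_dir() else read_volume_nifti(path)

        meshes = {seg: (read_stl(p(d["original"])), read_stl(p(d["planned"])))
                  for seg, d in self.meshes.items()}
        # the chin needs two boxes (pre and post position); an optional
        # "key" field disambiguates while "label" stays a known ROI label
        boxes = {}
        for b in self.roi_boxes:
            key = b.get("key", b["label"])
            boxes[key] = ROIBox(b["lower"], b["upper"], b["label"])
        return CaseInputs(
            pre_volume=load_volume(self.pre_volume),
            post_volume=load_volume(self.post_volume),
            nhp=read_matrix_xml(p(self.nhp_matrix)),
            landmarks=LandmarkSet(**{k: np.asarray(v, dtype=float)
                                     for k, v in self.landmarks.items()}),
            roi_boxes=boxes,
            meshes=meshes,
            chin_regions=self.chin_regions,
            iso_params=IsoSurfaceParams(**{"threshold": 380.0, **self.iso_params}),
            icp_params=ICPParams(**self.icp_params),
            voxel_params=VoxelRegistrationParams(**self.voxel_params),
            plate_exclusion=PlateExclusion(**self.plate_exclusion),
        )


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

@dataclass
class SegmentResult:
    planned: SegmentMotion
    achieved: SegmentMotion
    difference: SegmentMotion


@dataclass
class AccuracyReport:
    segments: dict                    # segment -> SegmentResult
    provenance: dict = field(default_factory=dict)
    log: list = field(default_factory=list)

    def write_csv(self, path) -> None:
        write_report(self, path)

    def parameter(self, segment: str, name: str, column: str = "difference") -> float:
        return getattr(getattr(self.segments[segment], column), name)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def align_nhp(obj, nhp: NHPMatrix, landmarks: LandmarkSet):
    """Express a Volume or TriMesh in the NHP frame with the upper incisor
    at the origin (metadata/vertex transform only; no resampling)."""
    to_f = RigidTransform.translation(-landmarks.upper_incisor).compose(nhp.to_rigid())
    return obj.transformed(to_f)


def assign_rotation_points(landmarks: LandmarkSet) -> dict:
    """Map each segment to its anatomical rotation point."""
    return {
        "maxilla": landmarks.upper_incisor,
        "mandible": landmarks.pogonion,
        "chin": landmarks.pogonion,
        "ramus_left": landmarks.condyle_left,
        "ramus_right": landmarks.condyle_right,
    }


def correct_chin(
    achieved_chin: RigidTransform,
    achieved_mandible: RigidTransform,
    planned_mandible: RigidTransform,
) -> RigidTransform:
    """Remove the mandibular execution error from the achieved chin motion.

    The genioplasty segment is fixed to the distal mandible, so any
    mandibular error carries over to the chin.  With the mandibular
    execution error ``E_m = achieved_mandible o planned_mandible^-1``, the
    corrected chin transform is ``E_m^-1 o achieved_chin``: what the chin
    did relative to a mandible that had been executed exactly as planned.
    """
    e_m = achieved_mandible.compose(planned_mandible.invert())
    return e_m.invert().compose(achieved_chin)


def _shifted_region(cfg, offset: np.ndarray):
    """Translate a region-predicate config by ``offset`` (recursively)."""
    if isinstance(cfg, (list, tuple)):
        return [_shifted_region(c, offset) for c in cfg]
    cfg = dict(cfg)
    if cfg["type"] == "halfspace":
        cfg["offset"] = float(cfg["offset"] + np.dot(cfg["normal"], offset))
    elif cfg["type"] == "box":
        cfg["lower"] = list(np.asarray(cfg["lower"], dtype=float) + offset)
        cfg["upper"] = list(np.asarray(cfg["upper"], dtype=float) + offset)
    elif cfg["type"] == "sphere":
        cfg["center"] = list(np.asarray(cfg["center"], dtype=float) + offset)
    elif cfg["type"] in ("intersection", "union"):
        cfg["parts"] = [_shifted_region(c, offset) for c in cfg["parts"]]
    return cfg


def _chin_bands(mesh: TriMesh, bands: dict) -> TriMesh:
    """Adaptive matching bands on the unaltered chin cortex.

    Emulates painting the matching surface on the model itself, wherever
    the segment ended up: the lowest ``caudal_mm`` of the selected surface
    (the under-side of the chin) plus the most anterior ``anterior_mm``
    within ``anterior_depth_mm`` of the bottom (the anterior cortex below
    the plate).  The anterior patch is what constrains pitch, the
    clinically most demanding parameter of the chin.
    """
    sel = (np.ones(len(mesh.vertices), dtype=bool)
           if mesh.selection is None else mesh.selection.copy())
    z = mesh.vertices[:, 2]
    y = mesh.vertices[:, 1]
    zmin = z[sel].min()
    keep = sel & (z <= zmin + bands.get("caudal_mm", 3.5))
    if bands.get("anterior_mm"):
        depth = sel & (z <= zmin + bands.get("anterior_depth_mm", 6.0))
        ymax = y[depth].max()
        keep |= depth & (y >= ymax - bands["anterior_mm"])
    return TriMesh(mesh.vertices.copy(), mesh.faces.copy(), keep)


def _chin_surface(volume: Volume, box: ROIBox, inputs: CaseInputs,
                  region_cfg, exclude_plate: bool,
                  bands: dict | None = None) -> TriMesh:
    roi = extract_roi(volume, box)
    mesh = extract_isosurface(roi, inputs.iso_params)
    mesh = select_matching_region(mesh, region_cfg)
    # plate exclusion first: the adaptive bands must be measured on bone,
    # not on the isosurface bump over the fixation plate
    if exclude_plate and inputs.plate_exclusion.enabled:
        mesh = exclude_high_density(
            mesh, roi,
            upper_threshold=inputs.plate_exclusion.upper_threshold,
            radius=inputs.plate_exclusion.radius,
        )
    if bands:
        mesh = _chin_bands(mesh, bands)
    return mesh


def chin_surfaces(inputs: CaseInputs, pre_f: Volume, post_f: Volume,
                  boxes_f: dict, regions_f: dict) -> tuple[TriMesh, TriMesh]:
    """(fixed, moving) chin matching surfaces in the analysis frame."""
    bands = inputs.chin_regions.get("bands_mm", {})
    fixed = _chin_surface(post_f, boxes_f["chin"], inputs, regions_f["fixed"],
                          exclude_plate=True, bands=bands.get("fixed"))
    moving = _chin_surface(pre_f, boxes_f["chin_pre"], inputs, regions_f["moving"],
                           exclude_plate=False, bands=bands.get("moving"))
    return fixed, moving


def analyze_case(inputs: CaseInputs, log_path=None) -> AccuracyReport:
    """Run the full workflow on in-memory inputs; see the module docstring."""
    log: list = []

    def record(stage, transform=None, **extra):
        entry = {"stage": stage, **extra}
        if transform is not None:
            entry["matrix"] = [float(v) for v in np.asarray(transform.matrix).flatten()]
        log.append(entry)

    def run(stage, fn):
        try:
            return fn()
        except Exception as exc:
            raise PipelineStageError(stage, exc, log) from exc

    shift = -inputs.landmarks.upper_incisor
    landmarks_f = inputs.landmarks.translated(shift)
    rotation_points = assign_rotation_points(landmarks_f)
    boxes_f = {k: b.translated(shift) for k, b in inputs.roi_boxes.items()}
    regions_f = {k: _shifted_region(inputs.chin_regions[k], shift)
                 for k in ("fixed", "moving")}

    # 1 — NHP alignment (incisor to origin)
    pre_f = run("nhp_alignment", lambda: align_nhp(
        inputs.pre_volume, inputs.nhp, inputs.landmarks))
    meshes_f = {seg: (align_nhp(o, inputs.nhp, inputs.landmarks),
                      align_nhp(p, inputs.nhp, inputs.landmarks))
                for seg, (o, p) in inputs.meshes.items()}
    record("nhp_alignment", transform=RigidTransform.translation(shift).compose(
        inputs.nhp.to_rigid()))

    # 2 — planned motion per segment from the planning export
    planned_tf = {}
    for seg in SEGMENTS:
        orig, plan = meshes_f[seg]
        planned_tf[seg] = run(f"planned_{seg}",
                              lambda o=orig, p=plan: compute_planned_transform(o, p))
        record(f"planned_{seg}", transform=planned_tf[seg])

    # 3 — global cranial-base VBM: post scan into the pre-op NHP frame
    nhp_init = RigidTransform.translation(shift).compose(inputs.nhp.to_rigid())
    global_res = run("global_vbm", lambda: register_rigid_voxel(
        pre_f, inputs.post_volume, boxes_f["cranial_base"],
        init=nhp_init, params=inputs.voxel_params))
    post_f = inputs.post_volume.transformed(global_res.transform)
    record("global_vbm", transform=global_res.transform,
           metric=global_res.metric_final, iterations=global_res.iterations)

    # 4 — achieved motion: per-segment VBM (pre segment onto post scan)
    achieved_tf = {}
    for seg in VBM_SEGMENTS:
        res = run(f"vbm_{seg}", lambda s=seg: register_rigid_voxel(
            post_f, pre_f, boxes_f[s], init=planned_tf[s], params=inputs.voxel_params))
        achieved_tf[seg] = res.transform
        record(f"vbm_{seg}", transform=res.transform,
               metric=res.metric_final, iterations=res.iterations)

    # 4b — achieved chin via SBM on the caudal chin surface
    bands = inputs.chin_regions.get("bands_mm", {})
    fixed_mesh = run("chin_surface_post", lambda: _chin_surface(
        post_f, boxes_f["chin"], inputs, regions_f["fixed"], exclude_plate=True,
        bands=bands.get("fixed")))
    moving_mesh = run("chin_surface_pre", lambda: _chin_surface(
        pre_f, boxes_f["chin_pre"], inputs, regions_f["moving"], exclude_plate=False,
        bands=bands.get("moving")))
    icp_res = run("sbm_chin", lambda: register_icp(
        fixed_mesh, moving_mesh, inputs.icp_params, init=planned_tf["chin"]))
    achieved_tf["chin"] = icp_res.transform
    record("sbm_chin", transform=icp_res.transform,
           rms=icp_res.rms, iterations=icp_res.iterations)

    # 5 — mandibular correction of the chin
    corrected_chin = run("chin_correction", lambda: correct_chin(
        achieved_tf["chin"], achieved_tf["mandible"], planned_tf["mandible"]))
    record("chin_correction", transform=corrected_chin)

    # 6/7 — decomposition about rotation points, parameter-wise difference
    segments = {}
    for seg in SEGMENTS:
        rp = rotation_points[seg]
        if seg in RAMUS_SEGMENTS:
            planned_m = ramus_rotations(planned_tf[seg], rp)
            achieved_m = ramus_rotations(achieved_tf[seg], rp)
        elif seg == "chin":
            planned_m = decompose(planned_tf[seg], rp)
            achieved_m = decompose(corrected_chin, rp)
        else:
            planned_m = decompose(planned_tf[seg], rp)
            achieved_m = decompose(achieved_tf[seg], rp)
        segments[seg] = SegmentResult(
            planned=planned_m,
            achieved=achieved_m,
            difference=achieved_m.subtract(planned_m),
        )

    provenance = {
        "software_version": __version__,
        "registration_seed": inputs.voxel_params.seed,
        "config_hash": _inputs_hash(inputs),
    }
    report = AccuracyReport(segments=segments, provenance=provenance, log=log)
    if log_path is not None:
        with open(log_path, "w") as fh:
            for entry in log:
                fh.write(json.dumps(entry) + "\n")
    return report


def _inputs_hash(inputs: CaseInputs) -> str:
    h = hashlib.sha256()
    for arr in (inputs.pre_volume.data, inputs.post_volume.data,
                inputs.nhp.matrix, inputs.landmarks.upper_incisor):
        h.update(np.ascontiguousarray(arr).tobytes())
    h.update(str(inputs.voxel_params).encode())
    h.update(str(inputs.icp_params).encode())
    return h.hexdigest()[:16]


def run_case(config: CaseConfig, base_dir=None, log_path=None) -> AccuracyReport:
    """Load a file-based case and analyze it."""
    return analyze_case(config.load(base_dir), log_path=log_path)
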
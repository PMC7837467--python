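"""Voxel-based matching (VBM): rigid greyscale registration of an ROI.

A region of interest of the fixed volume — the cranial base for the global
alignment, a box around each osteotomized segment otherwise — is rigidly
registered to the moving volume by maximizing Mattes mutual information.
MI is used because pre- and post-operative scans routinely come from
different scanners and protocols, so grey values need not correspond.

The optimization runs a 3-level multi-resolution pyramid with a
regular-step gradient descent over a 6-parameter rigid (Euler) transform,
with seeded random voxel sampling for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

from .geometry import RigidTransform
from .io import Volume

__all__ = [
    "ROIBox",
    "VoxelRegistrationParams",
    "RegistrationResult",
    "RegistrationError",
    "extract_roi",
    "register_rigid_voxel",
]

ROI_LABELS = ("cranial_base", "maxilla", "mandible", "ramus_left", "ramus_right", "chin")


class RegistrationError(RuntimeError):
    """Registration failed; carries the metric trace when available."""

    def __init__(self, message: str, trace: list[float] | None = None):
        super().__init__(message)
        self.trace = trace or []


@dataclass(frozen=True)
class ROIBox:
    """Axis-aligned box (mm, fixed volume's NHP frame) restricting a registration."""

    lower: np.ndarray
    upper: np.ndarray
    label: str = "cranial_base"

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float).reshape(3)
        hi = np.asarray(self.upper, dtype=float).reshape(3)
        if np.any(lo >= hi):
            raise ValueError(f"ROI box must satisfy lower < upper, got {lo} / {hi}")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.all((pts >= self.lower) & (pts <= self.upper), axis=1)

    def translated(self, offset) -> "ROIBox":
        o = np.asarray(offset, dtype=float)
        return ROIBox(self.lower + o, self.upper + o, self.label)

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (self.lower + self.upper)


@dataclass
class VoxelRegistrationParams:
    """Tunables of the MI registration; defaults suit 0.3–0.7 mm (CB)CT."""

    histogram_bins: int = 50
    sampling_fraction: float = 0.10
    min_samples: int = 5000           # floor per pyramid level for stable MI
    shrink_factors: tuple[int, ...] = (4, 2, 1)
    smoothing_sigmas: tuple[float, ...] = (2.0, 1.0, 0.0)
    max_iterations: int = 500
    learning_rate: float = 1.0
    min_step: float = 1e-4
    relaxation_factor: float = 0.5
    intensity_std_floor: float = 1e-3  # below this the ROI is uninformative
    seed: int = 1


@dataclass
class RegistrationResult:
    """Transform plus diagnostics of one VBM run."""

    transform: RigidTransform
    metric_initial: float
    metric_final: float
    iterations: int
    stop_condition: str
    metric_trace: list[float] = field(default_factory=list)


def extract_roi(volume: Volume, box: ROIBox) -> Volume:
    """Crop ``volume`` to the voxels whose world position falls in ``box``.

    The crop keeps the voxels whose *center* can lie inside the box (for
    oblique volumes this is the index bounding range of the box corners);
    geometry metadata is preserved exactly.
    """
    corners = np.array([[box.lower[i] if b & (1 << i) == 0 else box.upper[i]
                         for i in range(3)] for b in range(8)])
    idx = volume.index_from_world(corners)
    lo = np.maximum(np.ceil(idx.min(axis=0) - 1e-9).astype(int), 0)
    hi = np.minimum(np.floor(idx.max(axis=0) + 1e-9).astype(int) + 1, volume.shape)
    if np.any(lo >= hi):
        raise ValueError(
            f"ROI box {box.label!r} ({box.lower}..{box.upper}) does not intersect the volume"
        )
    sub = volume.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    return Volume(data=sub, spacing=volume.spacing,
                  origin=volume.world_from_index(lo), orientation=volume.orientation)


def _euler_to_rigid(tx: sitk.Euler3DTransform) -> RigidTransform:
    R = np.array(tx.GetMatrix()).reshape(3, 3)
    c = np.array(tx.GetCenter())
    t = np.array(tx.GetTranslation())
    # sitk: x -> R (x - c) + c + t
    return RigidTransform.from_rotation_translation(R, c + t - R @ c)


def _rigid_to_euler(transform: RigidTransform, center: np.ndarray) -> sitk.Euler3DTransform:
    tx = sitk.Euler3DTransform()
    tx.SetCenter(tuple(center))
    tx.SetMatrix(tuple(transform.rotation.flatten()), 1e-8)
    t = transform.translation_vector + transform.rotation @ center - center
    tx.SetTranslation(tuple(t))
    return tx


def register_rigid_voxel(
    fixed: Volume,
    moving: Volume,
    box: ROIBox,
    init: RigidTransform | None = None,
    params: VoxelRegistrationParams | None = None,
) -> RegistrationResult:
    """Register ``moving`` onto the ROI of ``fixed`` by mutual information.

    Returns the rigid transform mapping *moving-frame points to
    fixed-frame points* that locally maximizes MI over the ROI, along with
    the metric trace and convergence diagnostics.

    Raises :class:`RegistrationError` when the ROI is uninformative
    (near-constant intensity) or the optimizer fails to converge.
    """
    params = params or VoxelRegistrationParams()
    init = init or RigidTransform.identity()

    fixed_roi = extract_roi(fixed, box)
    if float(np.std(fixed_roi.data)) < params.intensity_std_floor:
        raise RegistrationError(
            f"uninformative ROI {box.label!r}: intensity std "
            f"{float(np.std(fixed_roi.data)):.3g} below floor {params.intensity_std_floor}"
        )

    f_img = fixed_roi.to_sitk()
    m_img = moving.to_sitk()
    # exact box mask: the index-space crop of an oblique box keeps a margin
    # outside the ROI, which must not contribute to the metric
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in fixed_roi.shape), indexing="ij")
    world = fixed_roi.world_from_index(
        np.stack([ii, jj, kk], axis=-1).reshape(-1, 3))
    in_box = box.contains(world).reshape(fixed_roi.shape)
    mask_img = sitk.GetImageFromArray(np.ascontiguousarray(in_box.T).astype(np.uint8))
    mask_img.CopyInformation(f_img)

    n_roi = int(np.prod(fixed_roi.shape))
    fraction = min(1.0, max(params.sampling_fraction, params.min_samples / max(n_roi, 1)))

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=params.histogram_bins)
    reg.SetMetricFixedMask(mask_img)
    if fraction < 1.0:
        reg.SetMetricSamplingStrategy(reg.RANDOM)
        reg.SetMetricSamplingPercentage(fraction, params.seed)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=params.learning_rate,
        minStep=params.min_step,
        numberOfIterations=params.max_iterations,
        relaxationFactor=params.relaxation_factor,
        gradientMagnitudeTolerance=1e-8,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    levels = len(params.shrink_factors)
    reg.SetShrinkFactorsPerLevel(list(params.shrink_factors))
    reg.SetSmoothingSigmasPerLevel(list(params.smoothing_sigmas))
    reg.SetSmoothingSigmasAreSpecifiedInPhysicalUnits(False)

    # sitk estimates transforms mapping fixed-space points into moving space
    center = box.center
    initial_tx = _rigid_to_euler(init.invert(), center)
    reg.SetInitialTransform(initial_tx, inPlace=False)

    trace: list[float] = []
    reg.AddCommand(sitk.sitkIterationEvent, lambda: trace.append(reg.GetMetricValue()))

    metric_initial = reg.MetricEvaluate(f_img, m_img)
    try:
        final_tx = reg.Execute(f_img, m_img)
    except RuntimeError as exc:
        raise RegistrationError(f"registration failed: {exc}", trace) from exc

    stop = reg.GetOptimizerStopConditionDescription()
    iterations = reg.GetOptimizerIteration()
    metric_final = reg.GetMetricValue()
    if "Maximum number of iterations" in stop and levels > 0:
        raise RegistrationError(
            f"optimizer did not converge within {params.max_iterations} iterations "
            f"at the final level (stop: {stop})", trace,
        )

    concrete = final_tx.Downcast() if hasattr(final_tx, "Downcast") else final_tx
    if isinstance(concrete, sitk.CompositeTransform):
        concrete = concrete.GetNthTransform(0).Downcast()
    final_euler = sitk.Euler3DTransform(concrete)
    # invert: sitk's fixed->moving map, reported as moving->fixed
    result = _euler_to_rigid(final_euler).invert()
    return RegistrationResult(
        transform=result,
        metric_initial=float(metric_initial),
        metric_final=float(metric_final),
        iterations=int(iterations),
        stop_condition=stop,
        metric_trace=trace,
    )
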
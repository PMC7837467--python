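"""Rigid-motion algebra and the clinical 6-DOF parameterization.

All motions are expressed in the natural-head-position (NHP) frame:

* ``+x`` — patient left (right-left axis, RL)
* ``+y`` — anterior (antero-posterior axis, AP)
* ``+z`` — superior (supero-inferior axis, SI)

Rotations are named after the anatomical plane they act in: *pitch* rotates
in the sagittal plane (about the RL axis), *roll* in the frontal/coronal
plane (about the AP axis) and *yaw* in the axial plane (about the SI axis).
Signs follow the right-hand rule on the respective ``+`` axis: positive
pitch tips the incisal edge superiorly-anteriorly.

The clinical readout decomposes a rigid transform about an anatomical
rotation point ``p`` (upper incisor, pogonion or a condylar head)::

    x  ->  R (x - p) + p + t

with ``R = R_roll @ R_pitch @ R_yaw`` (fixed-axes composition) and
``t = (t_rl, t_ap, t_si)``.  Angles are reported in degrees and
translations in millimetres, matching clinical reporting practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RigidTransform",
    "LandmarkSet",
    "SegmentMotion",
    "GimbalLockError",
    "from_parameters",
    "decompose",
    "ramus_rotations",
    "transform_error",
]

_ORTHO_TOL = 1e-9


class GimbalLockError(ValueError):
    """Pitch magnitude at/beyond 89.9 deg: yaw and roll are not separable.

    Such a motion is far outside the range of orthognathic surgery; the
    case should be inspected rather than silently decomposed.
    """


def _check_rotation(R: np.ndarray, tol: float = _ORTHO_TOL) -> None:
    err = np.abs(R.T @ R - np.eye(3)).max()
    if err > tol:
        raise ValueError(f"rotation block not orthonormal (max |R'R - I| = {err:.3g})")
    if np.linalg.det(R) < 0:
        raise ValueError("rotation block has determinant -1 (reflection, not a rotation)")


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion stored as a 4x4 homogeneous matrix (mm)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"expected a 4x4 matrix, got shape {m.shape}")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=1e-9):
            raise ValueError("last row of a homogeneous rigid transform must be (0,0,0,1)")
        _check_rotation(m[:3, :3])
        m = m.copy()
        m[3] = (0.0, 0.0, 0.0, 1.0)
        m.flags.writeable = False
        object.__setattr__(self, "matrix", m)

    # -- constructors -------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_translation(cls, R: np.ndarray, t: np.ndarray) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = t
        return cls(m)

    @classmethod
    def translation(cls, t) -> "RigidTransform":
        return cls.from_rotation_translation(np.eye(3), np.asarray(t, dtype=float))

    # -- accessors ----------------------------------------------------
    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation_vector(self) -> np.ndarray:
        return self.matrix[:3, 3]

    # -- algebra ------------------------------------------------------
    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self @ other`` (``other`` acts first)."""
        return RigidTransform(self.matrix @ other.matrix)

    def invert(self) -> "RigidTransform":
        R = self.rotation
        t = self.translation_vector
        return RigidTransform.from_rotation_translation(R.T, -R.T @ t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (N, 3) array (or a single 3-vector) of mm points."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        out = pts @ self.rotation.T + self.translation_vector
        return out[0] if single else out

    def rotation_angle_deg(self) -> float:
        """Total rotation angle (degrees) of the rotation block."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    return a.compose(b)


def invert(a: RigidTransform) -> RigidTransform:
    return a.invert()


def apply(a: RigidTransform, points: np.ndarray) -> np.ndarray:
    return a.apply(points)


@dataclass(frozen=True)
class LandmarkSet:
    """The four anatomical rotation points, in NHP coordinates (mm).

    upper_incisor
        Most mesial point on the incisal edge of the right central upper
        incisor (element 11); also the origin of the analysis frame.
    pogonion
        Most anterior point of the osseous chin.
    condyle_left / condyle_right
        Most cranial points of the left and right condylar heads.
    """

    upper_incisor: np.ndarray
    pogonion: np.ndarray
    condyle_left: np.ndarray
    condyle_right: np.ndarray

    def __post_init__(self) -> None:
        for name in ("upper_incisor", "pogonion", "condyle_left", "condyle_right"):
            p = np.asarray(getattr(self, name), dtype=float).reshape(3)
            if not np.all(np.isfinite(p)):
                raise ValueError(f"landmark {name!r} is not finite: {p}")
            object.__setattr__(self, name, p)
        if self.condyle_left[0] == self.condyle_right[0]:
            raise ValueError("left and right condylar points share the same RL coordinate")

    def translated(self, offset) -> "LandmarkSet":
        o = np.asarray(offset, dtype=float)
        return LandmarkSet(
            self.upper_incisor + o,
            self.pogonion + o,
            self.condyle_left + o,
            self.condyle_right + o,
        )


@dataclass(frozen=True)
class SegmentMotion:
    """Clinical 6-DOF readout of one bone segment about its rotation point.

    Translations ``t_rl``/``t_ap``/``t_si`` are in mm along the NHP axes;
    ``pitch``/``roll``/``yaw`` are in degrees. For ramus segments the
    translational part is zero by convention (condylar heads are assumed
    untranslated) and only the rotations are meaningful.
    """

    t_rl: float = 0.0
    t_ap: float = 0.0
    t_si: float = 0.0
    pitch: float = 0.0
    roll: float = 0.0
    yaw: float = 0.0
    rotation_point: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        p = np.asarray(self.rotation_point, dtype=float).reshape(3)
        object.__setattr__(self, "rotation_point", p)
        for name in ("t_rl", "t_ap", "t_si", "pitch", "roll", "yaw"):
            v = float(getattr(self, name))
            if not np.isfinite(v):
                raise ValueError(f"{name} is not finite")
            object.__setattr__(self, name, v)
        for name in ("pitch", "roll", "yaw"):
            v = getattr(self, name)
            if not (-180.0 < v <= 180.0):
                raise ValueError(f"{name} = {v} outside (-180, 180]")

    @property
    def translations(self) -> np.ndarray:
        return np.array([self.t_rl, self.t_ap, self.t_si])

    @property
    def rotations(self) -> np.ndarray:
        return np.array([self.pitch, self.roll, self.yaw])

    def parameters(self) -> dict[str, float]:
        return {
            "t_rl": self.t_rl,
            "t_ap": self.t_ap,
            "t_si": self.t_si,
            "pitch": self.pitch,
            "roll": self.roll,
            "yaw": self.yaw,
        }

    def subtract(self, other: "SegmentMotion") -> "SegmentMotion":
        """Parameter-wise difference ``self - other`` (same rotation point)."""
        return replace(
            self,
            t_rl=self.t_rl - other.t_rl,
            t_ap=self.t_ap - other.t_ap,
            t_si=self.t_si - other.t_si,
            pitch=self.pitch - other.pitch,
            roll=self.roll - other.roll,
            yaw=self.yaw - other.yaw,
        )

    def add(self, other: "SegmentMotion") -> "SegmentMotion":
        return replace(
            self,
            t_rl=self.t_rl + other.t_rl,
            t_ap=self.t_ap + other.t_ap,
            t_si=self.t_si + other.t_si,
            pitch=self.pitch + other.pitch,
            roll=self.roll + other.roll,
            yaw=self.yaw + other.yaw,
        )


def _euler_matrix(pitch_deg: float, roll_deg: float, yaw_deg: float) -> np.ndarray:
    """R = R_roll(y-axis) @ R_pitch(x-axis) @ R_yaw(z-axis), fixed axes."""
    a, b, c = np.radians([pitch_deg, roll_deg, yaw_deg])
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    Rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    Ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    Rz = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
    return Ry @ Rx @ Rz


def from_parameters(motion: SegmentMotion) -> RigidTransform:
    """Build the rigid transform ``x -> R (x - p) + p + t`` of a motion."""
    R = _euler_matrix(motion.pitch, motion.roll, motion.yaw)
    p = motion.rotation_point
    t = p + motion.translations - R @ p
    return RigidTransform.from_rotation_translation(R, t)


def _euler_angles(R: np.ndarray) -> tuple[float, float, float]:
    # From R = Ry(roll) Rx(pitch) Rz(yaw):
    #   R[1, 2] = -sin(pitch)
    #   R[1, 0] =  cos(pitch) sin(yaw),   R[1, 1] = cos(pitch) cos(yaw)
    #   R[0, 2] =  sin(roll) cos(pitch),  R[2, 2] = cos(roll) cos(pitch)
    sp = np.clip(-R[1, 2], -1.0, 1.0)
    pitch = np.degrees(np.arcsin(sp))
    if abs(pitch) >= 89.9:
        raise GimbalLockError(
            f"pitch = {pitch:.2f} deg is in the gimbal-lock region (|pitch| >= 89.9); "
            "such a motion is outside the clinical range of orthognathic surgery"
        )
    yaw = np.degrees(np.arctan2(R[1, 0], R[1, 1]))
    roll = np.degrees(np.arctan2(R[0, 2], R[2, 2]))
    return float(pitch), float(roll), float(yaw)


def decompose(transform: RigidTransform, rotation_point) -> SegmentMotion:
    """Clinical 6-DOF readout of ``transform`` about ``rotation_point``.

    Exact inverse of :func:`from_parameters` away from gimbal lock: the
    translation is the displacement of the rotation point expressed on the
    NHP axes, and the angles come from the shared fixed-axes convention.
    """
    p = np.asarray(rotation_point, dtype=float).reshape(3)
    pitch, roll, yaw = _euler_angles(transform.rotation)
    t = transform.apply(p) - p
    return SegmentMotion(
        t_rl=t[0], t_ap=t[1], t_si=t[2],
        pitch=pitch, roll=roll, yaw=yaw,
        rotation_point=p,
    )


def ramus_rotations(transform: RigidTransform, condyle) -> SegmentMotion:
    """Rotation-only readout of a ramus about its condylar head.

    The condylar head is assumed untranslated by surgery, so the
    translational part of the registered transform is discarded and only
    the rotation block is decomposed about the condylar point.  In ramus
    reporting the pitch-axis component is called *autorotation* and the
    yaw-axis component *flare*; *roll* keeps its name.
    """
    p = np.asarray(condyle, dtype=float).reshape(3)
    pitch, roll, yaw = _euler_angles(transform.rotation)
    return SegmentMotion(
        t_rl=0.0, t_ap=0.0, t_si=0.0,
        pitch=pitch, roll=roll, yaw=yaw,
        rotation_point=p,
    )


def transform_error(
    estimate: RigidTransform, truth: RigidTransform, point
) -> tuple[float, float]:
    """(mm displacement at ``point``, total rotation angle in degrees) of
    the residual ``estimate o truth^-1``. Convenience for registration
    accuracy checks."""
    residual = estimate.compose(truth.invert())
    p = np.asarray(point, dtype=float).reshape(3)
    d = float(np.linalg.norm(residual.apply(p) - p))
    return d, residual.rotation_angle_deg()
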
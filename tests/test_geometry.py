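"""Rigid-motion algebra and the clinical 6-DOF parameterization."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from jawmotion.geometry import (
    RigidTransform, LandmarkSet, SegmentMotion, GimbalLockError,
    from_parameters, decompose, ramus_rotations, transform_error,
    compose, invert, apply,
)


def random_motion(rng, t_range=20.0, angle_range=30.0, point_range=40.0):
    t = rng.uniform(-t_range, t_range, 3)
    a = rng.uniform(-angle_range, angle_range, 3)
    p = rng.uniform(-point_range, point_range, 3)
    return SegmentMotion(t_rl=t[0], t_ap=t[1], t_si=t[2],
                         pitch=a[0], roll=a[1], yaw=a[2], rotation_point=p)


def random_transform(rng):
    R = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    t = rng.uniform(-30, 30, 3)
    return RigidTransform.from_rotation_translation(R, t)


class TestRigidTransform:
    def test_identity_inverse(self):
        eye = RigidTransform.identity()
        assert np.allclose(invert(eye).matrix, eye.matrix)

    def test_translations_compose_additively(self):
        a = RigidTransform.translation([1, 2, 3])
        b = RigidTransform.translation([-4, 0, 7])
        assert np.allclose(compose(a, b).translation_vector, [-3, 2, 10])

    def test_group_properties_on_random_transforms(self, rng):
        for _ in range(100):
            a, b, c = (random_transform(rng) for _ in range(3))
            # associativity
            assert np.allclose(compose(compose(a, b), c).matrix,
                               compose(a, compose(b, c)).matrix, atol=1e-10)
            # inverse
            assert np.allclose(compose(a, invert(a)).matrix, np.eye(4), atol=1e-12)

    def test_apply_preserves_pairwise_distances(self, rng):
        pts = rng.uniform(-50, 50, (20, 3))
        d0 = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        for _ in range(100):
            moved = apply(random_transform(rng), pts)
            d1 = np.linalg.norm(moved[:, None] - moved[None], axis=-1)
            assert np.abs(d1 - d0).max() < 1e-9

    def test_rejects_reflection_and_scale(self):
        bad = np.eye(4)
        bad[0, 0] = -1.0
        with pytest.raises(ValueError):
            RigidTransform(bad)
        bad = np.eye(4)
        bad[:3, :3] *= 2.0
        with pytest.raises(ValueError):
            RigidTransform(bad)


class TestParameterization:
    def test_zero_motion_is_identity(self):
        t = from_parameters(SegmentMotion(rotation_point=[5, -3, 2]))
        assert np.allclose(t.matrix, np.eye(4))

    def test_pure_translation_ignores_rotation_point(self):
        for p in ([0, 0, 0], [10, -20, 5]):
            t = from_parameters(SegmentMotion(t_ap=5.0, rotation_point=p))
            assert np.allclose(t.translation_vector, [0, 5, 0])
            assert np.allclose(t.rotation, np.eye(3))

    def test_quarter_turn_yaw(self):
        t = from_parameters(SegmentMotion(yaw=90.0))
        assert np.allclose(t.apply([1.0, 0.0, 0.0]), [0.0, 1.0, 0.0], atol=1e-12)

    def test_euler_convention_matches_scipy(self, rng):
        # R = R_roll(y) @ R_pitch(x) @ R_yaw(z) == intrinsic y-x-z
        for _ in range(50):
            pitch, roll, yaw = rng.uniform(-60, 60, 3)
            ours = from_parameters(SegmentMotion(pitch=pitch, roll=roll, yaw=yaw)).rotation
            ref = Rotation.from_euler("YXZ", [roll, pitch, yaw], degrees=True).as_matrix()
            assert np.allclose(ours, ref, atol=1e-12)

    def test_decompose_identity_any_point(self, rng):
        m = decompose(RigidTransform.identity(), rng.uniform(-30, 30, 3))
        assert np.allclose([m.t_rl, m.t_ap, m.t_si, m.pitch, m.roll, m.yaw], 0.0)

    def test_pure_rotation_about_point_has_zero_translation(self):
        p = [3.0, -7.0, 11.0]
        m = decompose(from_parameters(SegmentMotion(yaw=3.0, rotation_point=p)), p)
        assert np.allclose([m.t_rl, m.t_ap, m.t_si], 0.0, atol=1e-12)
        assert m.yaw == pytest.approx(3.0, abs=1e-12)

    def test_round_trip_on_clinical_range(self):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(1000):
            m = random_motion(rng)
            rec = decompose(from_parameters(m), m.rotation_point)
            err = max(
                abs(rec.t_rl - m.t_rl), abs(rec.t_ap - m.t_ap), abs(rec.t_si - m.t_si),
                abs(rec.pitch - m.pitch), abs(rec.roll - m.roll), abs(rec.yaw - m.yaw),
            )
            worst = max(worst, err)
        assert worst < 1e-9

    def test_gimbal_lock_raises(self):
        t = from_parameters(SegmentMotion(pitch=89.95))
        with pytest.raises(GimbalLockError):
            decompose(t, [0, 0, 0])

    def test_translation_depends_on_rotation_point_iff_rotating(self, rng):
        rotating = from_parameters(SegmentMotion(yaw=10.0, rotation_point=[0, 0, 0]))
        p1, p2 = [0.0, 0.0, 0.0], [20.0, 0.0, 0.0]
        m1, m2 = decompose(rotating, p1), decompose(rotating, p2)
        assert not np.allclose(m1.translations, m2.translations)
        sliding = RigidTransform.translation([1, 2, 3])
        m1, m2 = decompose(sliding, p1), decompose(sliding, p2)
        assert np.allclose(m1.translations, m2.translations)


class TestRamusRotations:
    def test_identity(self):
        m = ramus_rotations(RigidTransform.identity(), [24, -12, 9])
        assert np.allclose([m.pitch, m.roll, m.yaw, m.t_rl, m.t_ap, m.t_si], 0.0)

    def test_pure_pitch_about_condyle(self):
        condyle = [24.0, -12.0, 9.0]
        t = from_parameters(SegmentMotion(pitch=2.0, rotation_point=condyle))
        m = ramus_rotations(t, condyle)
        assert m.pitch == pytest.approx(2.0, abs=1e-12)
        assert m.roll == pytest.approx(0.0, abs=1e-12)
        assert m.yaw == pytest.approx(0.0, abs=1e-12)

    def test_translation_part_is_discarded(self, rng):
        condyle = rng.uniform(-30, 30, 3)
        t = from_parameters(SegmentMotion(t_rl=4, t_ap=-2, t_si=1, pitch=3.0,
                                          rotation_point=condyle))
        m = ramus_rotations(t, condyle)
        assert np.allclose(m.translations, 0.0)
        assert m.pitch == pytest.approx(3.0, abs=1e-12)


class TestLandmarkSet:
    def test_rejects_coincident_condyles(self):
        with pytest.raises(ValueError):
            LandmarkSet([0, 0, 0], [0, 3, -16], [24, -12, 9], [24, -12, 9])

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            LandmarkSet([0, 0, np.nan], [0, 3, -16], [24, -12, 9], [-24, -12, 9])


def test_transform_error_of_exact_match_is_zero(rng):
    t = random_transform(rng)
    mm, deg = transform_error(t, t, [10, 0, 0])
    # arccos loses precision near 1, so the angle is zero only to ~1e-5 deg
    assert mm < 1e-12 and deg < 1e-5
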
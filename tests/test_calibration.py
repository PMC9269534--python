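"""Static-pose calibration: frame transforms, mean vectors, TRIAD basis and
the mount-misalignment recovery property that defines the whole construction."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation as ScipyRotation

from imukin.calibration import (
    MountingRotation,
    SensorSample,
    StaticCapture,
    apply_frame_transform,
    build_basis,
    calibrate,
    calibration_matrix,
    earth_field,
    gravity_reaction,
    mean_vectors,
)
from imukin.exceptions import (
    DegenerateFieldError,
    DegenerateGravityError,
    EmptyInputError,
)
from imukin.pipeline import calibrate_from_streams
from imukin.rotations import rot_axis
from imukin.simulator import MotionProtocol, NoiseModel, simulate_session


def _sample(k, a, w=(0, 0, 0), b=(40, 0, 0), t=None):
    return SensorSample(k=k, t=k / 60.0 if t is None else t, a=a, w=w, b=b)


def _capture(sensor_id, vectors_a, vectors_b=None):
    vectors_b = vectors_b or [(40.0, 0.0, 0.0)] * len(vectors_a)
    samples = [_sample(i, a, b=b) for i, (a, b) in enumerate(zip(vectors_a, vectors_b))]
    return StaticCapture(sensor_id, samples, 60)


class TestFrameTransform:
    def test_identity_leaves_sample_unchanged(self):
        s = _sample(0, (1.0, 2.0, 3.0), w=(4, 5, 6), b=(7, 8, 9))
        out = apply_frame_transform(s, np.eye(3), np.eye(3))
        np.testing.assert_allclose(out.a, s.a)
        np.testing.assert_allclose(out.w, s.w)
        np.testing.assert_allclose(out.b, s.b)

    def test_z_quarter_turn_moves_x_to_y(self):
        s = _sample(0, (1.0, 0.0, 0.0))
        out = apply_frame_transform(s, rot_axis("Z", 90.0), np.eye(3))
        np.testing.assert_allclose(out.a, [0.0, 1.0, 0.0], atol=1e-12)

    def test_norms_preserved_under_random_rotations(self, random_rotations):
        s = _sample(0, (1.0, -2.0, 0.5), w=(3, 0, -1), b=(30, -20, 10))
        for r in random_rotations[:20]:
            out = apply_frame_transform(s, r, np.eye(3))
            for name in ("a", "w", "b"):
                np.testing.assert_allclose(
                    np.linalg.norm(getattr(out, name)),
                    np.linalg.norm(getattr(s, name)),
                    atol=1e-9,
                )


class TestMeanVectors:
    def test_constant_stream(self):
        cap = _capture(1, [(0, 0, 9.81)] * 5)
        a, _ = mean_vectors(cap, np.eye(3))
        np.testing.assert_allclose(a, [0, 0, 9.81])

    def test_two_sample_mean(self):
        cap = _capture(1, [(0, 0, 9.0), (0, 0, 11.0)])
        a, _ = mean_vectors(cap, np.eye(3))
        np.testing.assert_allclose(a, [0, 0, 10.0])

    def test_three_axis_mean(self):
        cap = _capture(1, [(1, 0, 0), (0, 1, 0), (0, 0, 1)])
        a, _ = mean_vectors(cap, np.eye(3))
        np.testing.assert_allclose(a, [1 / 3, 1 / 3, 1 / 3])

    def test_empty_capture_rejected(self):
        with pytest.raises(EmptyInputError):
            StaticCapture(1, [], 60)


class TestBuildBasis:
    def test_hand_computed_example(self):
        basis = build_basis((0, 0, 2.0), (3.0, 0, 0))
        np.testing.assert_allclose(basis.v1, [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(basis.v2, [0, 1, 0], atol=1e-12)
        np.testing.assert_allclose(basis.v3, [-1, 0, 0], atol=1e-12)

    def test_basis_is_proper_rotation_for_random_inputs(self, rng):
        for _ in range(50):
            a = rng.normal(size=3)
            b = rng.normal(size=3)
            if np.linalg.norm(a) < 0.1 or np.linalg.norm(np.cross(a, b)) < 0.1:
                continue
            B = build_basis(a, b).B
            np.testing.assert_allclose(B.T @ B, np.eye(3), atol=1e-9)
            assert abs(np.linalg.det(B) - 1.0) < 1e-9

    def test_parallel_field_rejected(self):
        with pytest.raises(DegenerateFieldError):
            build_basis((0, 0, 9.81), (0, 0, 50.0))

    def test_zero_gravity_rejected(self):
        with pytest.raises(DegenerateGravityError):
            build_basis((0, 0, 0), (40, 0, 0))


class TestCalibrationMatrix:
    def test_self_calibration_is_identity(self):
        basis = build_basis((0, 0, 2.0), (3.0, 0, 0))
        np.testing.assert_allclose(calibration_matrix(basis, basis, 1), np.eye(3), atol=1e-12)

    def test_forearm_is_identity_regardless_of_bases(self):
        b1 = build_basis((0, 0, 2.0), (3.0, 0, 0))
        b2 = build_basis((9.81, 0, 0.0), (30.0, 30.0, 0))
        assert np.array_equal(calibration_matrix(b1, b2, 2), np.eye(3))

    def test_quarter_turn_example_against_brute_force_inverse(self):
        from imukin.calibration import SensorBasis

        rz = rot_axis("Z", 90.0)
        basis_1 = SensorBasis(v1=rz[:, 0], v2=rz[:, 1], v3=rz[:, 2])
        eye = np.eye(3)
        basis_2 = SensorBasis(v1=eye[:, 0], v2=eye[:, 1], v3=eye[:, 2])
        m = calibration_matrix(basis_1, basis_2, 1)
        np.testing.assert_allclose(m, rot_axis("Z", -90.0), atol=1e-12)
        # independent oracle: full 3x3 inversion instead of the transpose trick
        np.testing.assert_allclose(m, np.linalg.inv(rz), atol=1e-12)


class TestCalibratePipeline:
    def test_perfect_mounting_gives_identity(self, static_session):
        sess = static_session
        calib = calibrate_from_streams(sess.arm_stream, sess.forearm_stream, 60, 2.0)
        np.testing.assert_allclose(calib.M[1], np.eye(3), atol=1e-9)
        assert np.array_equal(calib.M[2], np.eye(3))

    def test_known_misalignment_recovered(self):
        """Perturbed arm mount: M1 R1 must map statics back onto gravity/field."""
        E = ScipyRotation.from_euler("zyx", [24.0, -13.0, 40.0], degrees=True).as_matrix()
        sess = simulate_session(
            MotionProtocol(phases=()),
            rate=60,
            noise=NoiseModel.noiseless(),
            t_cal=2.0,
            transition=0.0,
            arm_misalignment=E,
        )
        calib = calibrate_from_streams(sess.arm_stream, sess.forearm_stream, 60, 2.0)
        T = calib.M[1] @ calib.mounts[1].R
        s0 = sess.arm_stream[0]
        np.testing.assert_allclose(T @ s0.a, gravity_reaction(), atol=1e-6)
        np.testing.assert_allclose(T @ s0.b, earth_field(), atol=1e-6)

    def test_sample_order_invariance(self, rng):
        vecs_a = [tuple(np.array([-9.81, 0, 0]) + rng.normal(0, 0.1, 3)) for _ in range(20)]
        vecs_b = [tuple(earth_field() + rng.normal(0, 0.5, 3)) for _ in range(20)]
        perm = rng.permutation(20)
        c1 = calibrate(
            _capture(1, vecs_a, vecs_b),
            _capture(2, [(-9.81, 0, 0)] * 20, [tuple(earth_field())] * 20),
        )
        c2 = calibrate(
            _capture(1, [vecs_a[i] for i in perm], [vecs_b[i] for i in perm]),
            _capture(2, [(-9.81, 0, 0)] * 20, [tuple(earth_field())] * 20),
        )
        np.testing.assert_allclose(c1.M[1], c2.M[1], atol=1e-12)

    def test_single_sample_capture_is_valid(self):
        identity_mounts = (MountingRotation(1, (0.0, 0.0)), MountingRotation(2, (0.0, 0.0)))
        c = calibrate(
            _capture(1, [(-9.81, 0, 0)], [tuple(earth_field())]),
            _capture(2, [(-9.81, 0, 0)], [tuple(earth_field())]),
            identity_mounts,
        )
        np.testing.assert_allclose(c.M[1], np.eye(3), atol=1e-9)

    def test_vertical_error_shrinks_with_sample_count(self):
        """Monte-Carlo: averaging 1000 noisy statics beats averaging 10."""
        wins = 0
        trials = 20
        for seed in range(trials):
            rng = np.random.default_rng(seed)

            def vertical_error(n, rng=rng):
                noisy = gravity_reaction() + rng.normal(0, 0.05, (n, 3))
                v1 = build_basis(noisy.mean(axis=0), earth_field()).v1
                ref = gravity_reaction() / np.linalg.norm(gravity_reaction())
                return np.arccos(np.clip(v1 @ ref, -1, 1))

            if vertical_error(1000) < vertical_error(10):
                wins += 1
        assert wins >= trials * 0.95
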
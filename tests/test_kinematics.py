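"""Joint-angle extraction: axis-projection inverses, relative rotation,
series assembly, and range-of-motion summaries."""

import numpy as np
import pytest

from imukin.exceptions import AlignmentError, EmptyInputError
from imukin.fusion import OrientationTrack
from imukin.kinematics import (
    JointAngleSeries,
    angle_series,
    flexion_extension_angle,
    pronation_supination_angle,
    relative_rotation,
    rom_summary,
)
from imukin.rotations import (
    identity_quat,
    matrix_to_quat,
    quat_conjugate,
    quat_multiply,
    quat_to_matrix,
    rot_axis,
)


def _track(matrices, rate=60, segment_id=1):
    times = np.arange(len(matrices)) / rate
    quats = np.array([matrix_to_quat(m) for m in matrices])
    return OrientationTrack(segment_id=segment_id, times=times, quaternions=quats)


class TestRelativeRotation:
    def test_equal_orientations_give_identity(self, random_rotations):
        q = matrix_to_quat(random_rotations[0])
        np.testing.assert_allclose(relative_rotation(q, q), np.eye(3), atol=1e-9)

    def test_identity_arm_passes_forearm_through(self):
        qf = matrix_to_quat(rot_axis("Z", 72.0))
        np.testing.assert_allclose(
            relative_rotation(identity_quat(), qf), rot_axis("Z", 72.0), atol=1e-9
        )

    def test_matches_quaternion_conjugate_oracle(self, random_rotations):
        for ra, rf in zip(random_rotations[:30], random_rotations[30:60]):
            qa, qf = matrix_to_quat(ra), matrix_to_quat(rf)
            expected = quat_to_matrix(quat_multiply(quat_conjugate(qa), qf))
            np.testing.assert_allclose(relative_rotation(qa, qf), expected, atol=1e-9)


class TestExtractors:
    @pytest.mark.parametrize("delta", [-179.0, -90.0, -10.0, 0.0, 30.0, 90.0, 145.0, 180.0])
    def test_flexion_is_exact_inverse_on_axis(self, delta):
        assert flexion_extension_angle(rot_axis("Z", delta)) == pytest.approx(delta, abs=1e-9)

    @pytest.mark.parametrize("phi", [-170.0, -80.0, 0.0, 45.0, 120.0])
    def test_pronation_upright_is_exact_inverse_on_axis(self, phi):
        assert pronation_supination_angle(rot_axis("X", phi), "upright") == pytest.approx(
            phi, abs=1e-9
        )

    def test_pronation_flexed_mode_pure_y_rotation(self):
        assert pronation_supination_angle(rot_axis("Y", 60.0), "elbow_flexed_90") == pytest.approx(
            60.0, abs=1e-9
        )

    def test_pronation_flexed_mode_with_held_flexion(self):
        # the physical flexed posture: pronation on top of a held 90 deg flexion
        r = rot_axis("Y", -55.0) @ rot_axis("Z", 90.0)
        assert pronation_supination_angle(r, "elbow_flexed_90") == pytest.approx(-55.0, abs=1e-9)
        assert flexion_extension_angle(r) == pytest.approx(90.0, abs=1e-9)

    def test_flexion_robust_to_small_off_axis_content(self):
        """Compare to a brute-force projection oracle on the printed Rz layout."""
        r = rot_axis("Z", 30.0) @ rot_axis("X", 1.0)
        measured = flexion_extension_angle(r)
        grid = np.linspace(29.0, 31.0, 20001)
        costs = [np.linalg.norm((r - rot_axis("Z", d))[:2, :2]) for d in grid]
        oracle = grid[int(np.argmin(costs))]
        assert measured == pytest.approx(30.0, abs=0.1)
        assert measured == pytest.approx(oracle, abs=0.05)

    def test_identity_reads_zero_everywhere(self):
        assert flexion_extension_angle(np.eye(3)) == 0.0
        assert pronation_supination_angle(np.eye(3), "upright") == 0.0
        assert pronation_supination_angle(np.eye(3), "elbow_flexed_90") == 0.0


class TestAngleSeries:
    def test_identity_tracks_give_zero_series(self):
        arm = _track([np.eye(3)] * 10)
        fore = _track([np.eye(3)] * 10, segment_id=2)
        s = angle_series(arm, fore)
        np.testing.assert_allclose(s.flexion_extension, 0.0, atol=1e-9)
        np.testing.assert_allclose(s.pronation_supination, 0.0, atol=1e-9)
        np.testing.assert_allclose(s.off_axis_residual, 0.0, atol=1e-6)

    def test_flexion_ramp_reproduced(self):
        deltas = np.linspace(0.0, 90.0, 60)
        arm = _track([np.eye(3)] * 60)
        fore = _track([rot_axis("Z", d) for d in deltas], segment_id=2)
        s = angle_series(arm, fore)
        np.testing.assert_allclose(s.flexion_extension, deltas, atol=1e-6)

    def test_ground_truth_orientations_reproduce_protocol(self, noiseless_table4_run):
        """Bypassing fusion: truth orientations in, commanded protocol out."""
        from imukin.simulator import _forearm_orientation

        sess, _, _, truth = noiseless_table4_run
        n = len(truth)
        arm = _track([np.eye(3)] * n)
        fore = OrientationTrack(
            segment_id=2,
            times=truth.times,
            quaternions=np.array(
                [
                    matrix_to_quat(_forearm_orientation(d, p))
                    for d, p in zip(truth.flexion_extension, truth.pronation_supination)
                ]
            ),
        )
        arm.times = truth.times
        s = angle_series(arm, fore)
        np.testing.assert_allclose(s.flexion_extension, truth.flexion_extension, atol=1e-6)
        np.testing.assert_allclose(s.pronation_supination, truth.pronation_supination, atol=1e-6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(AlignmentError):
            angle_series(_track([np.eye(3)] * 5), _track([np.eye(3)] * 6, segment_id=2))

    def test_out_of_band_flexion_flagged_not_clipped(self):
        s = JointAngleSeries(
            times=[0.0, 1.0], flexion_extension=[-20.0, 90.0], pronation_supination=[0.0, 0.0]
        )
        assert list(s.out_of_band()) == [True, False]
        assert s.flexion_extension[0] == -20.0


class TestRomSummary:
    def test_constant_series_has_zero_range_and_reps(self):
        s = JointAngleSeries(
            times=np.arange(10) / 60.0,
            flexion_extension=np.full(10, 42.0),
            pronation_supination=np.zeros(10),
        )
        r = rom_summary(s)["flexion_extension"]
        assert r.range == 0.0 and r.repetitions == 0

    def test_triangle_wave_five_repetitions(self):
        t = np.arange(0, 14, 1 / 60.0)
        tri = 90.0 * np.abs(((t / 2.8) % 1.0) * 2 - 1)  # 5 cycles of 0->90->0
        tri = 90.0 - tri
        s = JointAngleSeries(times=t, flexion_extension=tri, pronation_supination=np.zeros_like(t))
        r = rom_summary(s)["flexion_extension"]
        assert r.minimum == pytest.approx(0.0, abs=1e-6)
        assert r.maximum == pytest.approx(90.0, abs=1.0)
        assert r.repetitions == 5

    def test_noisy_triangle_wave_hysteresis_robust(self, rng):
        t = np.arange(0, 14, 1 / 60.0)
        tri = 90.0 - 90.0 * np.abs(((t / 2.8) % 1.0) * 2 - 1)
        noisy = tri + rng.normal(0, 1.0, len(t))
        s = JointAngleSeries(
            times=t, flexion_extension=noisy, pronation_supination=np.zeros_like(t)
        )
        assert rom_summary(s)["flexion_extension"].repetitions == 5

    def test_empty_series_rejected(self):
        s = JointAngleSeries(times=[], flexion_extension=[], pronation_supination=[])
        with pytest.raises(EmptyInputError):
            rom_summary(s)
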
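"""Static-pose sensor-to-segment calibration for a two-sensor upper-limb setup.

The subject stands in the calibration pose (upright, arms at the sides, palms
facing the body) while both sensors record a short static capture.  From the
mean gravity-reaction and magnetic-field vectors each sensor defines an
orthonormal basis (normalized acceleration, its cross product with the field,
and the closing cross product — the classic TRIAD construction).  The forearm
sensor is the reference segment, so its calibration matrix is the identity;
the arm sensor's matrix is the rotation carrying its basis onto the forearm's.
At runtime every raw sample is premultiplied by ``M_i @ R_i`` where ``R_i`` is
the configured mounting rotation and ``M_i`` the static-pose correction.

Anatomical frame convention: X vertical pointing along gravity (down), Y
anteroposterior (front), Z mediolateral (right).  The accelerometer at rest
reads the +1 g reaction opposing gravity, i.e. ``(-9.81, 0, 0)`` in this frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    DegenerateFieldError,
    DegenerateGravityError,
    EmptyInputError,
    InvalidArgumentError,
)
from .rotations import assert_rotation, compose_intrinsic, rot_axis

__all__ = [
    "GRAVITY",
    "CalibrationResult",
    "MountingRotation",
    "SensorBasis",
    "SensorSample",
    "StaticCapture",
    "apply_frame_transform",
    "build_basis",
    "calibrate",
    "calibration_matrix",
    "earth_field",
    "gravity_reaction",
    "mean_vectors",
]

GRAVITY = 9.81  # m/s^2

SUPPORTED_RATES = (30, 60, 120)

#: degeneracy threshold for near-zero gravity or field parallel to gravity
PARALLEL_EPS = 1e-6


def gravity_reaction() -> np.ndarray:
    """Accelerometer reading at rest in the anatomical frame, m/s^2."""
    return np.array([-GRAVITY, 0.0, 0.0])


def earth_field(magnitude_ut: float = 48.0, dip_deg: float = 35.0) -> np.ndarray:
    """Earth magnetic field in the anatomical frame (X down, Y north), in uT."""
    d = np.deg2rad(dip_deg)
    return magnitude_ut * np.array([np.sin(d), np.cos(d), 0.0])


@dataclass
class SensorSample:
    """One time-indexed 9-channel reading from a single sensor.

    ``a`` acceleration in m/s^2, ``w`` angular velocity in deg/s, ``b``
    magnetic field in uT, all as length-3 arrays in the sensor frame (or a
    transformed frame after :func:`apply_frame_transform`).
    """

    k: int
    t: float
    a: np.ndarray
    w: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        for name in ("a", "w", "b"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,) or not np.all(np.isfinite(v)):
                raise InvalidArgumentError(f"sample field {name!r} must be a finite 3-vector")
            setattr(self, name, v)
        if self.k < 0 or not np.isfinite(self.t):
            raise InvalidArgumentError("sample index must be >= 0 and time finite")


@dataclass
class StaticCapture:
    """An ordered static-pose stream from one sensor (1 = arm, 2 = forearm)."""

    sensor_id: int
    samples: list[SensorSample]
    rate: int = 60

    def __post_init__(self):
        if self.sensor_id not in (1, 2):
            raise InvalidArgumentError("sensor_id must be 1 (arm) or 2 (forearm)")
        if self.rate not in SUPPORTED_RATES:
            raise InvalidArgumentError(f"rate must be one of {SUPPORTED_RATES}")
        if len(self.samples) < 1:
            raise EmptyInputError("static capture needs at least one sample")
        times = [s.t for s in self.samples]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise InvalidArgumentError("sample times must be strictly increasing")

    @property
    def n(self) -> int:
        return len(self.samples)


@dataclass
class MountingRotation:
    """Configured donning rotation of a sensor relative to its segment.

    ``R = Rx(delta_odd) @ Ry'(delta_even)`` — an intrinsic X-then-new-Y
    sequence.  The arm sensor ships with a 270 deg first rotation by default;
    the remaining deltas are configuration inputs defaulting to 0.
    """

    sensor_id: int
    delta_angles: tuple[float, float]

    @property
    def R(self) -> np.ndarray:
        d_odd, d_even = self.delta_angles
        return compose_intrinsic(rot_axis("X", d_odd), rot_axis("Y", d_even))

    @classmethod
    def default_pair(cls) -> tuple["MountingRotation", "MountingRotation"]:
        return cls(1, (270.0, 0.0)), cls(2, (0.0, 0.0))


@dataclass
class SensorBasis:
    """Orthonormal right-handed basis derived from a static pose."""

    v1: np.ndarray
    v2: np.ndarray
    v3: np.ndarray

    @property
    def B(self) -> np.ndarray:
        """Basis matrix with v1, v2, v3 as columns (a proper rotation)."""
        return np.column_stack([self.v1, self.v2, self.v3])


@dataclass
class CalibrationResult:
    """Per-sensor calibration matrices, mounting rotations and static means.

    ``M[2]`` is the identity exactly (the forearm is the reference segment).
    ``mean_a``/``mean_b`` are the mount-corrected static means, so the
    forearm's pair doubles as the anatomical reference pair for fusion.
    """

    M: dict[int, np.ndarray]
    mounts: dict[int, MountingRotation]
    mean_a: dict[int, np.ndarray]
    mean_b: dict[int, np.ndarray]

    @property
    def reference_a(self) -> np.ndarray:
        return self.mean_a[2]

    @property
    def reference_b(self) -> np.ndarray:
        return self.mean_b[2]


def apply_frame_transform(sample: SensorSample, M: np.ndarray, R: np.ndarray) -> SensorSample:
    """Premultiply a sample's three vectors by ``M @ R``.

    With ``M = I`` this is the pure mounting correction; with a calibrated
    ``M`` it is the full runtime transform into the anatomical frame.
    """
    T = assert_rotation(M) @ assert_rotation(R)
    return SensorSample(k=sample.k, t=sample.t, a=T @ sample.a, w=T @ sample.w, b=T @ sample.b)


def mean_vectors(capture: StaticCapture, R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mount-corrected mean acceleration and magnetic field over a static capture."""
    if capture.n < 1:
        raise EmptyInputError("cannot average an empty capture")
    R = assert_rotation(R)
    a = np.mean([R @ s.a for s in capture.samples], axis=0)
    b = np.mean([R @ s.b for s in capture.samples], axis=0)
    return a, b


def build_basis(mean_a: np.ndarray, mean_b: np.ndarray, eps: float = PARALLEL_EPS) -> SensorBasis:
    """TRIAD-style orthonormal basis from mean gravity reaction and field.

    v1 along the mean acceleration, v2 along ``v1 x b`` (horizontal, east-ish),
    v3 closing the right-handed set.
    """
    mean_a = np.asarray(mean_a, dtype=float)
    mean_b = np.asarray(mean_b, dtype=float)
    na = np.linalg.norm(mean_a)
    if na <= eps:
        raise DegenerateGravityError("mean acceleration too small to define the vertical")
    v1 = mean_a / na
    cross = np.cross(v1, mean_b)
    nc = np.linalg.norm(cross)
    if nc <= eps:
        raise DegenerateFieldError("magnetic field parallel to gravity: unusable static pose")
    v2 = cross / nc
    v3 = np.cross(v1, v2)
    return SensorBasis(v1=v1, v2=v2, v3=v3)


def calibration_matrix(basis_i: SensorBasis, basis_2: SensorBasis, sensor_id: int) -> np.ndarray:
    """Rotation carrying sensor i's static basis onto the forearm reference basis.

    The forearm (sensor 2) is the reference segment, so its matrix is the
    identity by convention.  For the arm the correction is ``B_2 @ B_i^T``:
    it maps any vector expressed in sensor i's mount-corrected frame onto the
    same physical vector expressed in the reference frame, which is what the
    runtime transform needs under column-vector premultiplication.
    """
    if sensor_id == 2:
        return np.eye(3)
    return assert_rotation(basis_2.B) @ assert_rotation(basis_i.B).T


def calibrate(
    static_arm: StaticCapture,
    static_forearm: StaticCapture,
    mounts: tuple[MountingRotation, MountingRotation] | None = None,
) -> CalibrationResult:
    """Full static-pose calibration pipeline for the arm/forearm pair."""
    if mounts is None:
        mounts = MountingRotation.default_pair()
    mount_map = {m.sensor_id: m for m in mounts}
    if set(mount_map) != {1, 2}:
        raise InvalidArgumentError("mounting rotations must cover sensors 1 and 2")
    if static_arm.sensor_id != 1 or static_forearm.sensor_id != 2:
        raise InvalidArgumentError("captures must be (arm=sensor 1, forearm=sensor 2)")
    if static_arm.rate != static_forearm.rate:
        raise InvalidArgumentError("static captures must share a sampling rate")

    means_a, means_b, bases = {}, {}, {}
    for capture in (static_arm, static_forearm):
        sid = capture.sensor_id
        a, b = mean_vectors(capture, mount_map[sid].R)
        means_a[sid], means_b[sid] = a, b
        try:
            bases[sid] = build_basis(a, b)
        except (DegenerateGravityError, DegenerateFieldError) as exc:
            raise type(exc)(f"sensor {sid}: {exc}") from exc

    M = {sid: calibration_matrix(bases[sid], bases[2], sid) for sid in (1, 2)}
    return CalibrationResult(M=M, mounts=mount_map, mean_a=means_a, mean_b=means_b)
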
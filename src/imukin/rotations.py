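"""Self-contained 3-D rotation algebra.

Conventions used throughout the package:

* rotation matrices are proper orthonormal ``(3, 3)`` float arrays acting on
  column vectors by premultiplication;
* quaternions are Hamilton-convention, scalar-first ``(w, x, y, z)`` arrays,
  kept unit-norm and in canonical form (``w >= 0``; if ``w == 0`` the first
  non-zero component is positive, resolving the double cover);
* Euler angles are *intrinsic* Tait-Bryan sequences, default ``"ZYX"``
  (yaw-pitch-roll as labelled by optical-capture exports);
* every public angle is in degrees, wrapped into ``(-180, 180]``; radians
  appear only inside function bodies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidArgumentError

__all__ = [
    "EulerTriple",
    "EULER_ORDERS",
    "compose_intrinsic",
    "euler_to_matrix",
    "matrix_to_euler",
    "matrix_to_quat",
    "quat_canonical",
    "quat_conjugate",
    "quat_multiply",
    "quat_normalize",
    "quat_to_matrix",
    "rot_axis",
    "rotation_angle_deg",
    "wrap_degrees",
    "is_rotation",
    "assert_rotation",
    "identity_quat",
]

_AXIS_INDEX = {"X": 0, "Y": 1, "Z": 2}

#: the six intrinsic Tait-Bryan sequences supported by the Euler converters
EULER_ORDERS = ("ZYX", "XYZ", "ZXY", "YXZ", "XZY", "YZX")

ORTHONORMALITY_TOL = 1e-9


def wrap_degrees(angle):
    """Wrap an angle (scalar or array, degrees) into ``(-180, 180]``."""
    wrapped = np.mod(angle, 360.0)
    return np.where(wrapped > 180.0, wrapped - 360.0, wrapped)[()]


def rot_axis(axis: str, angle_deg: float) -> np.ndarray:
    """Elemental right-handed rotation matrix about a principal axis.

    ``rot_axis("Z", d)`` has rows ``[cos d, -sin d, 0; sin d, cos d, 0; 0, 0, 1]``
    (sagittal-plane flexion-extension layout); ``rot_axis("X", p)`` is the
    transverse-plane pronation-supination layout.
    """
    if axis not in _AXIS_INDEX:
        raise InvalidArgumentError(f"axis must be one of X, Y, Z, got {axis!r}")
    if not np.isfinite(angle_deg):
        raise InvalidArgumentError(f"rotation angle must be finite, got {angle_deg!r}")
    t = np.deg2rad(float(angle_deg))
    c, s = np.cos(t), np.sin(t)
    i = _AXIS_INDEX[axis]
    j, k = (i + 1) % 3, (i + 2) % 3
    r = np.eye(3)
    r[j, j] = c
    r[k, k] = c
    r[k, j] = s
    r[j, k] = -s
    return r


def is_rotation(r: np.ndarray, tol: float = ORTHONORMALITY_TOL) -> bool:
    r = np.asarray(r, dtype=float)
    if r.shape != (3, 3) or not np.all(np.isfinite(r)):
        return False
    if not np.allclose(r.T @ r, np.eye(3), atol=tol):
        return False
    return bool(abs(np.linalg.det(r) - 1.0) <= tol)


def assert_rotation(r: np.ndarray, tol: float = ORTHONORMALITY_TOL) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if not is_rotation(r, tol):
        raise InvalidArgumentError("matrix is not a proper rotation within tolerance")
    return r


def compose_intrinsic(first: np.ndarray, second: np.ndarray) -> np.ndarray:
    """Compose two rotations, the second about the already-rotated axes.

    Intrinsic composition is plain matrix product ``first @ second``; e.g. a
    mounting sequence "rotate about X, then about the new Y" is
    ``compose_intrinsic(rot_axis("X", d1), rot_axis("Y", d2))``.
    """
    return assert_rotation(first) @ assert_rotation(second)


def rotation_angle_deg(r: np.ndarray) -> float:
    """Geodesic angle of a rotation matrix, degrees in [0, 180]."""
    r = np.asarray(r, dtype=float)
    c = (np.trace(r) - 1.0) / 2.0
    return float(np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0))))


# --------------------------------------------------------------------------
# quaternions (Hamilton, scalar-first)
# --------------------------------------------------------------------------

def identity_quat() -> np.ndarray:
    return np.array([1.0, 0.0, 0.0, 0.0])


def quat_normalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.shape != (4,) or not np.all(np.isfinite(q)):
        raise InvalidArgumentError("quaternion must be a finite length-4 vector")
    n = np.linalg.norm(q)
    if n < 1e-12:
        raise InvalidArgumentError("zero-norm quaternion")
    return q / n


def quat_canonical(q: np.ndarray) -> np.ndarray:
    """Resolve the double cover: w >= 0, ties broken by first non-zero component."""
    q = quat_normalize(q)
    for c in q:
        if abs(c) > 1e-15:
            return q if c > 0 else -q
    return q  # unreachable for unit quaternions


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return np.array([q[0], -q[1], -q[2], -q[3]])


def quat_multiply(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Hamilton product p * q (apply q's rotation first when premultiplying vectors)."""
    pw, px, py, pz = np.asarray(p, dtype=float)
    qw, qx, qy, qz = np.asarray(q, dtype=float)
    return np.array(
        [
            pw * qw - px * qx - py * qy - pz * qz,
            pw * qx + px * qw + py * qz - pz * qy,
            pw * qy - px * qz + py * qw + pz * qx,
            pw * qz + px * qy - py * qx + pz * qw,
        ]
    )


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = quat_normalize(q)
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def matrix_to_quat(r: np.ndarray) -> np.ndarray:
    """Rotation matrix to canonical unit quaternion (Shepperd's method)."""
    r = assert_rotation(r, tol=1e-6)
    t = np.trace(r)
    if t > 0:
        s = np.sqrt(t + 1.0) * 2.0
        q = np.array(
            [0.25 * s, (r[2, 1] - r[1, 2]) / s, (r[0, 2] - r[2, 0]) / s, (r[1, 0] - r[0, 1]) / s]
        )
    else:
        i = int(np.argmax(np.diag(r)))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = np.sqrt(r[i, i] - r[j, j] - r[k, k] + 1.0) * 2.0
        q = np.empty(4)
        q[0] = (r[k, j] - r[j, k]) / s
        q[1 + i] = 0.25 * s
        q[1 + j] = (r[j, i] + r[i, j]) / s
        q[1 + k] = (r[k, i] + r[i, k]) / s
    return quat_canonical(q)


def _quat_from_rotvec(v_rad: np.ndarray) -> np.ndarray:
    """Exponential map: rotation vector (radians) to unit quaternion."""
    v = np.asarray(v_rad, dtype=float)
    angle = np.linalg.norm(v)
    if angle < 1e-12:
        # second-order small-angle expansion keeps the map smooth at zero
        q = np.array([1.0 - angle * angle / 8.0, *(0.5 * v)])
        return q / np.linalg.norm(q)
    axis = v / angle
    half = angle / 2.0
    return np.array([np.cos(half), *(np.sin(half) * axis)])


def _quat_to_rotvec(q: np.ndarray) -> np.ndarray:
    """Logarithm map: unit quaternion to rotation vector (radians)."""
    q = quat_canonical(q)
    w = np.clip(q[0], -1.0, 1.0)
    vec = q[1:]
    s = np.linalg.norm(vec)
    if s < 1e-12:
        return 2.0 * vec  # first-order: q ~ [1, v/2]
    angle = 2.0 * np.arctan2(s, w)
    return angle * vec / s


# --------------------------------------------------------------------------
# Euler angles (intrinsic Tait-Bryan)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EulerTriple:
    """Intrinsic Euler angles in degrees with their axis sequence.

    ``degenerate`` is set by :func:`matrix_to_euler` when the middle angle sits
    in the gimbal band; the third angle is then conventionally zero.
    """

    angles: tuple[float, float, float]
    order: str = "ZYX"
    degenerate: bool = field(default=False, compare=False)

    def __post_init__(self):
        if self.order not in EULER_ORDERS:
            raise InvalidArgumentError(f"unsupported Euler order {self.order!r}")
        if len(self.angles) != 3 or not all(np.isfinite(a) for a in self.angles):
            raise InvalidArgumentError("EulerTriple needs three finite angles")
        object.__setattr__(self, "angles", tuple(float(wrap_degrees(a)) for a in self.angles))


def _cyclic_sign(order: str) -> int:
    return 1 if order in ("XYZ", "YZX", "ZXY") else -1


def euler_to_matrix(e: EulerTriple) -> np.ndarray:
    """Compose the three elemental rotations of an intrinsic sequence."""
    m = np.eye(3)
    for axis, angle in zip(e.order, e.angles):
        m = m @ rot_axis(axis, angle)
    return m


def matrix_to_euler(r: np.ndarray, order: str = "ZYX") -> EulerTriple:
    """Invert :func:`euler_to_matrix` for any supported intrinsic sequence.

    Away from the gimbal band the middle angle lies in the open interval
    (-90, 90) and the round trip is exact to ~1e-6 deg.  Inside the band the
    first and third rotations share an axis; the third is reported as 0 with
    ``degenerate=True``.
    """
    r = assert_rotation(r, tol=1e-6)
    if order not in EULER_ORDERS:
        raise InvalidArgumentError(f"unsupported Euler order {order!r}")
    i, j, k = (_AXIS_INDEX[a] for a in order)
    eps = _cyclic_sign(order)
    s2 = float(np.clip(eps * r[i, k], -1.0, 1.0))
    c2 = float(np.sqrt(max(0.0, 1.0 - s2 * s2)))
    if c2 > 1e-7:
        a1 = np.arctan2(-eps * r[j, k], r[k, k])
        a2 = np.arcsin(s2)
        a3 = np.arctan2(-eps * r[i, j], r[i, i])
        degenerate = False
    else:
        sign = 1.0 if s2 > 0 else -1.0
        a1 = np.arctan2(sign * r[j, i], r[j, j])
        a2 = sign * np.pi / 2.0
        a3 = 0.0
        degenerate = True
    angles = tuple(float(wrap_degrees(np.rad2deg(a))) for a in (a1, a2, a3))
    return EulerTriple(angles=angles, order=order, degenerate=degenerate)
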
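"""Per-sensor orientation estimation during movement.

The estimator is a quaternion error-state Kalman filter: the gyroscope
propagates the attitude through the exact exponential map, and each sample's
accelerometer/magnetometer pair provides an absolute attitude observation via
the same TRIAD basis construction used by the static calibration.  The error
state is a 6-vector (attitude error in the anatomical frame, gyro-bias error
in the sensor frame); the accelerometer's contribution is down-weighted when
the measured specific force deviates from 1 g by more than 10 %, since linear
acceleration then pollutes the gravity direction.

Streams entering :func:`fuse_stream` are expected to already be in the
calibrated (anatomical-at-donning) frame, i.e. transformed sample-by-sample by
``apply_frame_transform`` with the calibrated ``M_i`` and ``R_i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import (
    GRAVITY,
    CalibrationResult,
    SensorSample,
    build_basis,
    earth_field,
    gravity_reaction,
)
from .exceptions import InvalidArgumentError, IrregularSamplingError
from .rotations import (
    _quat_from_rotvec,
    _quat_to_rotvec,
    identity_quat,
    matrix_to_quat,
    quat_canonical,
    quat_conjugate,
    quat_multiply,
    quat_to_matrix,
)

__all__ = [
    "FusionParams",
    "OrientationState",
    "OrientationTrack",
    "fuse_stream",
    "gyro_only_track",
    "integrate_gyro",
    "static_orientation",
]


@dataclass
class FusionParams:
    """Filter tuning knobs.

    ``gyro_noise`` is an angular random-walk density in deg/s/sqrt(Hz);
    ``bias_process`` the bias random-walk rate in deg/s per sqrt(s);
    ``accel_trust``/``mag_trust`` scale the observation confidence (1.0 means
    the TRIAD observation is worth about 2 deg one-sigma on the corresponding
    axes).  ``dt`` is the sample period in seconds.
    """

    gyro_noise: float = 0.2
    accel_trust: float = 1.0
    mag_trust: float = 1.0
    bias_process: float = 0.01
    dt: float = 1.0 / 60.0
    #: base one-sigma of a TRIAD attitude observation, degrees
    obs_sigma: float = 2.0
    #: fractional deviation of |a| from 1 g beyond which accel axes are gated
    accel_gate: float = 0.10
    #: angular rate (deg/s) above which the sample counts as dynamic; linear
    #: acceleration perpendicular to gravity barely changes |a|, so fast
    #: rotation is the better proxy for centripetal pollution
    rate_gate: float = 10.0
    #: angular acceleration (deg/s^2) above which the sample counts as
    #: dynamic — tangential pollution peaks exactly where the rate crosses
    #: zero (movement onsets and turn-arounds), so the rate gate alone
    #: misses it; estimated by smoothed central differences over the stream
    alpha_gate: float = 30.0
    #: observation-sigma inflation applied to the accelerometer axes of a
    #: dynamic sample; large enough to zero the gain (and the bias coupling,
    #: preventing bias wind-up from polluted observations) while keeping the
    #: magnetometer yaw observation active
    gate_inflation: float = 1e3

    def __post_init__(self):
        for name in ("gyro_noise", "accel_trust", "mag_trust", "bias_process", "obs_sigma"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be non-negative")
        if self.dt <= 0:
            raise InvalidArgumentError("dt must be positive")


@dataclass
class OrientationState:
    """Filter state: attitude quaternion, gyro bias (deg/s), 6x6 error covariance."""

    q: np.ndarray = field(default_factory=identity_quat)
    bias: np.ndarray = field(default_factory=lambda: np.zeros(3))
    P: np.ndarray = field(default_factory=lambda: np.diag([np.deg2rad(5.0) ** 2] * 3 + [np.deg2rad(1.0) ** 2] * 3))


@dataclass
class OrientationTrack:
    """Time series of unit quaternions for one body segment."""

    segment_id: int
    times: np.ndarray
    quaternions: np.ndarray  # (n, 4) scalar-first

    def __len__(self) -> int:
        return len(self.times)

    def matrices(self) -> np.ndarray:
        return np.stack([quat_to_matrix(q) for q in self.quaternions])


def static_orientation(
    a: np.ndarray,
    b: np.ndarray,
    ref_a: np.ndarray | None = None,
    ref_b: np.ndarray | None = None,
) -> np.ndarray:
    """Absolute attitude from one accel/mag pair (TRIAD against the reference pair).

    Returns the quaternion of the rotation mapping the measurement frame onto
    the anatomical frame implied by the reference vectors (defaults: gravity
    reaction and the standard earth field).
    """
    ref_a = gravity_reaction() if ref_a is None else np.asarray(ref_a, dtype=float)
    ref_b = earth_field() if ref_b is None else np.asarray(ref_b, dtype=float)
    b_meas = build_basis(a, b)
    b_ref = build_basis(ref_a, ref_b)
    return matrix_to_quat(b_ref.B @ b_meas.B.T)


def integrate_gyro(q: np.ndarray, w_dps: np.ndarray, dt: float) -> np.ndarray:
    """Advance an attitude by a body-frame rate over dt (exact exponential map)."""
    if dt <= 0:
        raise InvalidArgumentError("dt must be positive")
    dq = _quat_from_rotvec(np.deg2rad(np.asarray(w_dps, dtype=float)) * dt)
    return quat_canonical(quat_multiply(q, dq))


def _check_uniform_dt(times: np.ndarray, jitter: float = 0.10) -> float:
    diffs = np.diff(times)
    if len(diffs) == 0:
        return 0.0
    dt = float(np.median(diffs))
    if dt <= 0 or np.any(np.abs(diffs - dt) > jitter * dt):
        raise IrregularSamplingError("timestamps deviate from a uniform grid by more than 10 %")
    return dt


def gyro_only_track(
    stream: list[SensorSample], q0: np.ndarray | None = None, segment_id: int = 0
) -> OrientationTrack:
    """Dead-reckoning baseline: pure gyro integration, no corrections."""
    times = np.array([s.t for s in stream])
    dt = _check_uniform_dt(times)
    q = identity_quat() if q0 is None else quat_canonical(q0)
    quats = [q]
    for prev, s in zip(stream, stream[1:]):
        # trapezoidal rate over the step: second-order accurate in dt
        q = integrate_gyro(q, 0.5 * (prev.w + s.w), dt)
        quats.append(q)
    return OrientationTrack(segment_id=segment_id, times=times, quaternions=np.array(quats))


def fuse_stream(
    stream: list[SensorSample],
    calib: CalibrationResult | None = None,
    params: FusionParams | None = None,
    segment_id: int = 0,
) -> OrientationTrack:
    """Run the error-state filter over a calibrated 9-channel stream.

    Deterministic given the stream and parameters.  The reference vector pair
    for the TRIAD observation is taken from the calibration result (forearm
    static means) when available, so the filter's zero attitude coincides with
    the calibration pose.
    """
    if params is None:
        params = FusionParams()
    if len(stream) == 0:
        raise InvalidArgumentError("cannot fuse an empty stream")
    times = np.array([s.t for s in stream])
    dt = _check_uniform_dt(times) or params.dt

    ref_a = calib.reference_a if calib is not None else None
    ref_b = calib.reference_b if calib is not None else None

    # process noise (radians): attitude random walk from gyro noise density,
    # bias random walk from the bias process rate
    q_theta = np.deg2rad(params.gyro_noise) ** 2 * dt
    q_bias = np.deg2rad(params.bias_process) ** 2 * dt
    Q = np.diag([q_theta] * 3 + [q_bias] * 3)

    # observation noise per anatomical axis: the axis along gravity (X, index
    # 0) is determined by the magnetometer, the two horizontal axes by the
    # accelerometer
    sig = np.deg2rad(params.obs_sigma)
    sig_acc = sig / np.sqrt(max(params.accel_trust, 1e-12))
    sig_mag = sig / np.sqrt(max(params.mag_trust, 1e-12))
    base_obs_var = np.array([sig_mag**2, sig_acc**2, sig_acc**2])

    # per-sample dynamic-motion mask (the filter runs on recorded streams, so
    # the angular-acceleration estimate may use central differences)
    w_arr = np.array([s.w for s in stream])
    alpha = np.gradient(w_arr, dt, axis=0) if len(stream) > 1 else np.zeros_like(w_arr)
    alpha_mag = np.linalg.norm(alpha, axis=1)
    if len(alpha_mag) >= 5:
        alpha_mag = np.convolve(alpha_mag, np.ones(5) / 5.0, mode="same")
    a_dev = np.abs(np.linalg.norm([s.a for s in stream], axis=1) - GRAVITY)
    dynamic_mask = a_dev > params.accel_gate * GRAVITY
    if params.alpha_gate > 0:
        dynamic_mask |= alpha_mag > params.alpha_gate

    state = OrientationState()
    state.q = static_orientation(stream[0].a, stream[0].b, ref_a, ref_b)
    quats = [state.q]

    I6 = np.eye(6)
    for idx, (prev, s) in enumerate(zip(stream, stream[1:]), start=1):
        # --- predict -----------------------------------------------------
        w_hat = s.w - state.bias
        # trapezoidal rate over [prev, s]: second-order accurate in dt
        state.q = integrate_gyro(state.q, 0.5 * (prev.w + s.w) - state.bias, dt)
        R = quat_to_matrix(state.q)
        F = I6.copy()
        F[:3, 3:] = -R * dt
        state.P = F @ state.P @ F.T + Q
        # --- correct -----------------------------------------------------
        try:
            q_obs = static_orientation(s.a, s.b, ref_a, ref_b)
        except Exception:
            quats.append(state.q)
            continue
        obs_var = base_obs_var.copy()
        dynamic = bool(dynamic_mask[idx]) or (
            params.rate_gate > 0 and np.linalg.norm(w_hat) > params.rate_gate
        )
        if dynamic:
            obs_var[1:] *= params.gate_inflation**2
        y = _quat_to_rotvec(quat_multiply(q_obs, quat_conjugate(state.q)))
        S = state.P[:3, :3] + np.diag(obs_var)
        K = state.P[:, :3] @ np.linalg.inv(S)
        dx = K @ y
        state.q = quat_canonical(quat_multiply(_quat_from_rotvec(dx[:3]), state.q))
        state.bias = state.bias + np.rad2deg(dx[3:])
        state.P = state.P - K @ state.P[:3, :]
        state.P = 0.5 * (state.P + state.P.T)
        quats.append(state.q)

    return OrientationTrack(segment_id=segment_id, times=times, quaternions=np.array(quats))
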
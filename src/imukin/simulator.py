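"""Forward simulator for a two-sensor upper-limb capture session.

Stands in for the wearable hardware: given a motion protocol it builds the
forearm's ground-truth orientation trajectory (the arm segment stays fixed),
mounts two virtual sensors with configurable donning rotations, and derives
the exact 9-channel streams they would measure — gyro rates from finite
rotation increments, specific force from the second derivative of the sensor
position on a two-link arm geometry plus the gravity reaction, and the earth
magnetic field rotated into the sensor frame.  A seeded Gaussian noise model
with constant gyro bias makes sessions reproducible bit-for-bit.

Every session starts with ``t_cal`` seconds of the static calibration pose so
the downstream pipeline can self-calibrate from the same file.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import (
    GRAVITY,
    MountingRotation,
    SensorSample,
    StaticCapture,
    SUPPORTED_RATES,
    earth_field,
)
from .exceptions import EmptyInputError, InvalidArgumentError
from .kinematics import JointAngleSeries
from .rotations import _quat_to_rotvec, matrix_to_quat, rot_axis

__all__ = [
    "MotionProtocol",
    "NoiseModel",
    "ProtocolPhase",
    "SyntheticSession",
    "protocol_table4",
    "simulate_session",
    "truth_export",
]

MOVEMENTS = ("flexion_extension", "pronation_supination")
PROFILES = ("cosine", "trapezoid")


@dataclass(frozen=True)
class ProtocolPhase:
    """One block of repeated movement between two target angles."""

    movement: str
    start_angle: float
    end_angle: float
    repetitions: int
    period: float
    velocity_profile: str = "cosine"

    def __post_init__(self):
        if self.movement not in MOVEMENTS:
            raise InvalidArgumentError(f"movement must be one of {MOVEMENTS}")
        if self.velocity_profile not in PROFILES:
            raise InvalidArgumentError(f"velocity_profile must be one of {PROFILES}")
        if self.repetitions < 1:
            raise InvalidArgumentError("repetitions must be >= 1")
        if self.period <= 0:
            raise InvalidArgumentError("period must be positive")

    @property
    def duration(self) -> float:
        return self.repetitions * self.period


@dataclass(frozen=True)
class MotionProtocol:
    phases: tuple[ProtocolPhase, ...]

    @property
    def duration(self) -> float:
        return sum(p.duration for p in self.phases)


def protocol_table4(
    max_flexion: float = 145.0,
    max_pronosup: float = 80.0,
    period: float = 2.8,
) -> MotionProtocol:
    """The standard validation protocol: three blocks of five repetitions.

    Flexion 0 -> 90 deg x5, flexion 0 -> maximum x5, then pronation-supination
    sweeping between -max and +max x5 with the elbow held flexed at 90 deg.
    The maximum amplitudes are subject-dependent; the defaults are
    conventional physiologic values.
    """
    return MotionProtocol(
        phases=(
            ProtocolPhase("flexion_extension", 0.0, 90.0, 5, period),
            ProtocolPhase("flexion_extension", 0.0, max_flexion, 5, period),
            ProtocolPhase("pronation_supination", -max_pronosup, max_pronosup, 5, period),
        )
    )


@dataclass(frozen=True)
class NoiseModel:
    """Seeded Gaussian sensor imperfections (same bias on both sensors)."""

    accel_sigma: float = 0.05  # m/s^2
    gyro_sigma: float = 0.2  # deg/s
    gyro_bias: tuple[float, float, float] = (
        0.5 / np.sqrt(3.0),
        0.5 / np.sqrt(3.0),
        0.5 / np.sqrt(3.0),
    )  # deg/s, |bias| = 0.5
    mag_sigma: float = 0.5  # uT
    seed: int = 0

    def __post_init__(self):
        if min(self.accel_sigma, self.gyro_sigma, self.mag_sigma) < 0:
            raise InvalidArgumentError("noise sigmas must be non-negative")

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(accel_sigma=0.0, gyro_sigma=0.0, gyro_bias=(0.0, 0.0, 0.0), mag_sigma=0.0)


@dataclass
class SyntheticSession:
    """Ground-truth angles plus the raw per-sensor streams they induce."""

    truth: JointAngleSeries
    arm_stream: list[SensorSample]
    forearm_stream: list[SensorSample]
    rate: int
    t_cal: float
    noise: NoiseModel
    mounts: tuple[MountingRotation, MountingRotation]

    @property
    def duration(self) -> float:
        return len(self.truth) / self.rate

    def static_captures(self) -> tuple[StaticCapture, StaticCapture]:
        """The calibration-pose prefix of both streams, as static captures."""
        n_cal = max(1, int(round(self.t_cal * self.rate)))
        return (
            StaticCapture(1, self.arm_stream[:n_cal], self.rate),
            StaticCapture(2, self.forearm_stream[:n_cal], self.rate),
        )


def _trapezoid_stroke(s: float, ramp: float = 0.25) -> float:
    """Position 0 -> 1 over s in [0, 1] with a trapezoidal velocity profile."""
    s = min(max(s, 0.0), 1.0)
    v_max = 1.0 / (1.0 - ramp)  # area under the velocity trapezoid is 1
    if s < ramp:
        return 0.5 * v_max * s * s / ramp
    if s < 1.0 - ramp:
        return 0.5 * v_max * ramp + v_max * (s - ramp)
    u = 1.0 - s
    return 1.0 - 0.5 * v_max * u * u / ramp


def _phase_angle(phase: ProtocolPhase, tau: float) -> float:
    """Commanded angle inside one repetition, tau in [0, period)."""
    r = tau / phase.period
    if phase.movement == "pronation_supination":
        # symmetric oscillation starting from the mid (thumb-up, 0 deg) posture:
        # pronate to +amp, back through 0, supinate to -amp, return
        mid = 0.5 * (phase.start_angle + phase.end_angle)
        amp = 0.5 * (phase.end_angle - phase.start_angle)
        if phase.velocity_profile == "cosine":
            return mid + amp * np.sin(2.0 * np.pi * r)
        # four trapezoidal strokes: 0 -> +1 -> 0 -> -1 -> 0
        q, s = divmod(r * 4.0, 1.0)
        stroke = _trapezoid_stroke(s)
        value = (stroke, 1.0 - stroke, -stroke, stroke - 1.0)[int(q) % 4]
        return mid + amp * value
    # flexion: start -> end -> start per repetition
    if phase.velocity_profile == "cosine":
        frac = 0.5 * (1.0 - np.cos(2.0 * np.pi * r))
    else:
        frac = _trapezoid_stroke(2.0 * r) if r < 0.5 else _trapezoid_stroke(2.0 * (1.0 - r))
    return phase.start_angle + (phase.end_angle - phase.start_angle) * frac


def _smoothstep(x: float) -> float:
    x = min(max(x, 0.0), 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * x))


def _truth_profiles(
    protocol: MotionProtocol, rate: int, t_cal: float, transition: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample the commanded (delta, phi) trajectories on the session time base."""
    segments: list[tuple[float, object]] = [(t_cal, None)] if t_cal > 0 else []
    prev_flexed = False
    for phase in protocol.phases:
        flexed = phase.movement == "pronation_supination"
        if flexed and not prev_flexed and transition > 0:
            segments.append((transition, "transition_up"))
        segments.append((phase.duration, phase))
        prev_flexed = flexed
    total = sum(d for d, _ in segments)
    n = int(round(total * rate))
    if n == 0:
        raise EmptyInputError("protocol and calibration segment are both empty")
    times = np.arange(n) / rate
    delta = np.zeros(n)
    phi = np.zeros(n)
    t0 = 0.0
    for dur, payload in segments:
        sel = (times >= t0 - 1e-12) & (times < t0 + dur - 1e-12)
        local = times[sel] - t0
        if payload is None:
            pass  # static calibration pose
        elif payload == "transition_up":
            delta[sel] = [90.0 * _smoothstep(t / dur) for t in local]
        else:
            phase = payload
            if phase.movement == "flexion_extension":
                delta[sel] = [_phase_angle(phase, t % phase.period) for t in local]
            else:
                delta[sel] = 90.0  # elbow held flexed during pronation-supination
                phi[sel] = [_phase_angle(phase, t % phase.period) for t in local]
        t0 += dur
    return times, delta, phi


def _forearm_orientation(delta: float, phi: float) -> np.ndarray:
    """Segment-to-anatomical rotation of the forearm for commanded angles.

    Pronation while flexed is a space-fixed rotation about anatomical Y applied
    on top of the held flexion; in the upright pose it reduces to a rotation
    about the forearm's long (X) axis.
    """
    if abs(phi) < 1e-12:
        return rot_axis("Z", delta)
    if abs(delta) >= 45.0:
        return rot_axis("Y", phi) @ rot_axis("Z", delta)
    return rot_axis("Z", delta) @ rot_axis("X", phi)


def simulate_session(
    protocol: MotionProtocol,
    rate: int = 60,
    noise: NoiseModel | None = None,
    mounts: tuple[MountingRotation, MountingRotation] | None = None,
    t_cal: float = 2.0,
    transition: float = 1.0,
    arm_length: float = 0.28,
    forearm_length: float = 0.25,
    sensor_fraction: float = 2.0 / 3.0,
    field_magnitude: float = 48.0,
    field_dip: float = 35.0,
    arm_misalignment: np.ndarray | None = None,
) -> SyntheticSession:
    """Generate the raw streams a two-sensor capture of the protocol would produce.

    ``arm_misalignment`` (a rotation matrix) perturbs the arm sensor's actual
    donning relative to its configured mounting rotation — the knob used to
    exercise calibration recovery.  ``sensor_fraction`` places each sensor at
    that fraction of its segment's length from the proximal joint (the lower
    third of the segment by default).
    """
    if rate not in SUPPORTED_RATES:
        raise InvalidArgumentError(f"rate must be one of {SUPPORTED_RATES}")
    noise = NoiseModel() if noise is None else noise
    mounts = MountingRotation.default_pair() if mounts is None else mounts
    mount_map = {m.sensor_id: m for m in mounts}

    times, delta, phi = _truth_profiles(protocol, rate, t_cal, transition)
    n = len(times)
    dt = 1.0 / rate
    g_vec = np.array([GRAVITY, 0.0, 0.0])  # gravity points down = +X
    b_earth = earth_field(field_magnitude, field_dip)

    # actual sensor-to-segment rotations (configured mount, optionally perturbed)
    S = {1: mount_map[1].R, 2: mount_map[2].R}
    if arm_misalignment is not None:
        S[1] = S[1] @ np.asarray(arm_misalignment, dtype=float)

    # segment orientations over time
    C_arm = np.eye(3)
    C_fore = np.stack([_forearm_orientation(d, p) for d, p in zip(delta, phi)])

    # sensor positions (shoulder at origin, anatomical frame)
    elbow = C_arm @ np.array([arm_length, 0.0, 0.0])
    p_arm = np.tile(C_arm @ np.array([sensor_fraction * arm_length, 0.0, 0.0]), (n, 1))
    p_fore = elbow + C_fore @ np.array([sensor_fraction * forearm_length, 0.0, 0.0])

    rng = np.random.default_rng(noise.seed)
    bias = np.asarray(noise.gyro_bias, dtype=float)

    def make_stream(sensor_id: int, C_seg: np.ndarray, pos: np.ndarray) -> list[SensorSample]:
        C_seg_t = C_seg if C_seg.ndim == 3 else np.tile(C_seg, (n, 1, 1))
        C_sens = C_seg_t @ S[sensor_id]
        # body-frame angular rate from exact finite rotation increments
        w_body = np.zeros((n, 3))
        for i in range(n):
            lo, hi = max(i - 1, 0), min(i + 1, n - 1)
            if hi > lo:
                inc = C_seg_t[lo].T @ C_seg_t[hi]
                w_body[i] = np.rad2deg(_quat_to_rotvec(matrix_to_quat(inc))) / ((hi - lo) * dt)
        # linear acceleration by central second difference of the sensor position
        acc = np.zeros((n, 3))
        if n > 2:
            acc[1:-1] = (pos[2:] - 2.0 * pos[1:-1] + pos[:-2]) / dt**2
        f_anat = acc - g_vec  # specific force: reaction convention
        a_s = np.einsum("nij,nj->ni", np.transpose(C_sens, (0, 2, 1)), f_anat)
        b_s = np.einsum("nij,j->ni", np.transpose(C_sens, (0, 2, 1)), b_earth)
        w_s = np.einsum("ij,nj->ni", S[sensor_id].T, w_body)
        if noise.accel_sigma > 0:
            a_s = a_s + rng.normal(0.0, noise.accel_sigma, (n, 3))
        if noise.gyro_sigma > 0:
            w_s = w_s + rng.normal(0.0, noise.gyro_sigma, (n, 3))
        w_s = w_s + bias
        if noise.mag_sigma > 0:
            b_s = b_s + rng.normal(0.0, noise.mag_sigma, (n, 3))
        return [
            SensorSample(k=i, t=float(times[i]), a=a_s[i], w=w_s[i], b=b_s[i]) for i in range(n)
        ]

    arm_stream = make_stream(1, C_arm, p_arm)
    forearm_stream = make_stream(2, C_fore, p_fore)
    truth = JointAngleSeries(
        times=times, flexion_extension=delta, pronation_supination=phi, pose_mode="auto"
    )
    return SyntheticSession(
        truth=truth,
        arm_stream=arm_stream,
        forearm_stream=forearm_stream,
        rate=rate,
        t_cal=t_cal,
        noise=noise,
        mounts=mounts,
    )


def truth_export(session: SyntheticSession) -> JointAngleSeries:
    """The commanded angle series on the session time base (the test oracle)."""
    t = session.truth
    return JointAngleSeries(
        times=t.times.copy(),
        flexion_extension=t.flexion_extension.copy(),
        pronation_supination=t.pronation_supination.copy(),
        pose_mode=t.pose_mode,
    )
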
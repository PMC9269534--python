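"""Joint-angle extraction: elbow flexion-extension and forearm pronation-supination.

Each analytical unit of movement is assigned a rotation axis in the anatomical
frame: flexion-extension is a sagittal-plane rotation about Z, and
pronation-supination a rotation about the forearm's long axis — anatomical X
in the upright pose, anatomical Y once the elbow is flexed to 90 deg.  Angles
are read off the relative rotation (forearm expressed in the arm frame) by
atan2 projections chosen so that each extractor is the exact inverse of the
corresponding elemental rotation matrix, and so that the flexed-mode
pronation extractor also stays exact while the 90 deg flexion is held
(``R_rel = Ry(phi) @ Rz(90)``).

Sign conventions: flexion from the calibration pose is positive; pronation
(palm turning down) is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import AlignmentError, EmptyInputError, InvalidArgumentError
from .fusion import OrientationTrack
from .rotations import quat_to_matrix, rot_axis, rotation_angle_deg

__all__ = [
    "JointAngleSeries",
    "RomStats",
    "angle_series",
    "flexion_extension_angle",
    "pronation_supination_angle",
    "relative_rotation",
    "rom_summary",
]

POSE_MODES = ("upright", "elbow_flexed_90", "auto")

#: flexion band considered physiologic for the elbow; values outside are
#: flagged (never clipped)
FLEXION_BAND = (-10.0, 180.0)

#: |flexion| threshold at which 'auto' mode switches the pronation extractor
#: to the flexed-90 formula
AUTO_FLEXED_THRESHOLD = 45.0


@dataclass
class JointAngleSeries:
    """Clinician-facing kinematic output: per-sample joint angles in degrees."""

    times: np.ndarray
    flexion_extension: np.ndarray
    pronation_supination: np.ndarray
    pose_mode: str = "auto"
    #: per-sample rotation (deg) not explained by the two assigned axes
    off_axis_residual: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.flexion_extension = np.asarray(self.flexion_extension, dtype=float)
        self.pronation_supination = np.asarray(self.pronation_supination, dtype=float)
        if not (len(self.times) == len(self.flexion_extension) == len(self.pronation_supination)):
            raise AlignmentError("angle series channels must have equal length")
        if self.pose_mode not in POSE_MODES:
            raise InvalidArgumentError(f"pose_mode must be one of {POSE_MODES}")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def rate(self) -> float:
        if len(self.times) < 2:
            return 0.0
        return 1.0 / float(np.median(np.diff(self.times)))

    def out_of_band(self) -> np.ndarray:
        """Boolean mask of samples whose flexion leaves the physiologic band."""
        lo, hi = FLEXION_BAND
        return (self.flexion_extension < lo) | (self.flexion_extension > hi)


def relative_rotation(q_arm: np.ndarray, q_forearm: np.ndarray) -> np.ndarray:
    """Forearm orientation expressed in the arm frame: R(q_arm)^T R(q_forearm)."""
    return quat_to_matrix(q_arm).T @ quat_to_matrix(q_forearm)


def flexion_extension_angle(r_rel: np.ndarray) -> float:
    """Sagittal-plane angle about Z, degrees in (-180, 180].

    Projection ``atan2(r21, r11)`` (1-based) — the exact inverse of the
    elemental Rz layout; off-axis content is ignored.
    """
    r_rel = np.asarray(r_rel, dtype=float)
    return float(np.rad2deg(np.arctan2(r_rel[1, 0], r_rel[0, 0])))


def pronation_supination_angle(r_rel: np.ndarray, pose_mode: str) -> float:
    """Forearm axial rotation, degrees in (-180, 180].

    ``upright``: about anatomical X, ``atan2(r32, r22)`` — the inverse of the
    elemental Rx layout.  ``elbow_flexed_90``: about anatomical Y,
    ``atan2(r13, r33)``, which recovers phi exactly both for a pure Ry(phi)
    and for Ry(phi) composed with the held 90 deg flexion.
    """
    r_rel = np.asarray(r_rel, dtype=float)
    if pose_mode == "upright":
        return float(np.rad2deg(np.arctan2(r_rel[2, 1], r_rel[1, 1])))
    if pose_mode == "elbow_flexed_90":
        return float(np.rad2deg(np.arctan2(r_rel[0, 2], r_rel[2, 2])))
    raise InvalidArgumentError("pose_mode must be 'upright' or 'elbow_flexed_90'")


def _modelled_rotation(delta: float, phi: float, flexed: bool) -> np.ndarray:
    if flexed:
        return rot_axis("Y", phi) @ rot_axis("Z", delta)
    return rot_axis("Z", delta) @ rot_axis("X", phi)


def angle_series(
    arm: OrientationTrack,
    forearm: OrientationTrack,
    pose_mode: str = "auto",
) -> JointAngleSeries:
    """Per-sample joint angles from two time-aligned orientation tracks.

    ``auto`` chooses the pronation extractor per sample: the flexed-90 formula
    once |flexion| exceeds 45 deg, the upright one otherwise (both agree and
    read 0 during pure flexion, so the switch is seamless).  Channels are
    unwrapped to remove +-360 deg jumps.  The off-axis residual — the rotation
    left over after removing the two assigned axes — is kept as a per-sample
    diagnostic.
    """
    if len(arm) != len(forearm):
        raise AlignmentError("arm and forearm tracks differ in length")
    if len(arm) and not np.allclose(arm.times, forearm.times, atol=1e-9):
        raise AlignmentError("arm and forearm tracks are not on the same time base")
    if pose_mode not in POSE_MODES:
        raise InvalidArgumentError(f"pose_mode must be one of {POSE_MODES}")

    deltas = np.empty(len(arm))
    phis = np.empty(len(arm))
    residuals = np.empty(len(arm))
    for i, (qa, qf) in enumerate(zip(arm.quaternions, forearm.quaternions)):
        r_rel = relative_rotation(qa, qf)
        delta = flexion_extension_angle(r_rel)
        if pose_mode == "auto":
            flexed = abs(delta) >= AUTO_FLEXED_THRESHOLD
        else:
            flexed = pose_mode == "elbow_flexed_90"
        phi = pronation_supination_angle(r_rel, "elbow_flexed_90" if flexed else "upright")
        deltas[i] = delta
        phis[i] = phi
        residuals[i] = rotation_angle_deg(_modelled_rotation(delta, phi, flexed).T @ r_rel)

    if len(deltas) > 1:
        deltas = np.unwrap(deltas, period=360.0)
        phis = np.unwrap(phis, period=360.0)
    return JointAngleSeries(
        times=arm.times.copy(),
        flexion_extension=deltas,
        pronation_supination=phis,
        pose_mode=pose_mode,
        off_axis_residual=residuals,
    )


@dataclass(frozen=True)
class RomStats:
    """Range-of-motion summary for one movement channel."""

    minimum: float
    maximum: float
    range: float
    repetitions: int


def _count_repetitions(values: np.ndarray, hysteresis_frac: float = 0.15) -> int:
    """Count excursions crossing 50 % of the observed range, with hysteresis.

    A Schmitt trigger with thresholds at mid +- hysteresis_frac * range; one
    repetition per low-to-high transition.  Ranges under 5 deg count as no
    movement at all.
    """
    lo_v, hi_v = float(np.min(values)), float(np.max(values))
    rng = hi_v - lo_v
    if rng < 5.0:
        return 0
    mid = 0.5 * (lo_v + hi_v)
    high = mid + hysteresis_frac * rng
    low = mid - hysteresis_frac * rng
    # start "high" only above the high threshold, so a series starting near
    # the midline still counts its first excursion
    state_high = values[0] > high
    reps = 0
    for v in values[1:]:
        if not state_high and v > high:
            state_high = True
            reps += 1
        elif state_high and v < low:
            state_high = False
    return reps


def rom_summary(series: JointAngleSeries) -> dict[str, RomStats]:
    """Per-channel min/max/range and repetition count."""
    if len(series) == 0:
        raise EmptyInputError("cannot summarise an empty angle series")
    out = {}
    for name, values in (
        ("flexion_extension", series.flexion_extension),
        ("pronation_supination", series.pronation_supination),
    ):
        out[name] = RomStats(
            minimum=float(np.min(values)),
            maximum=float(np.max(values)),
            range=float(np.max(values) - np.min(values)),
            repetitions=_count_repetitions(values),
        )
    return out
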
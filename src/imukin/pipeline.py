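"""End-to-end composition: raw streams -> calibration -> fusion -> joint angles.

This is the programmatic equivalent of the CLI's ``transform`` subcommand and
the path exercised by the round-trip tests: the static calibration-pose prefix
of a session self-calibrates the sensor pair, every sample is transformed into
the anatomical frame, both segments are fused into orientation tracks, and the
joint angles are extracted.
"""

from __future__ import annotations

import numpy as np

from .calibration import (
    CalibrationResult,
    MountingRotation,
    SensorSample,
    StaticCapture,
    apply_frame_transform,
    calibrate,
)
from .fusion import FusionParams, OrientationTrack, fuse_stream
from .kinematics import JointAngleSeries, angle_series

__all__ = ["calibrate_from_streams", "transform_streams"]


def calibrate_from_streams(
    arm_stream: list[SensorSample],
    forearm_stream: list[SensorSample],
    rate: int,
    t_cal: float,
    mounts: tuple[MountingRotation, MountingRotation] | None = None,
) -> CalibrationResult:
    """Calibrate from the static prefix (first ``t_cal`` seconds) of a session."""
    n_cal = max(1, int(round(t_cal * rate)))
    return calibrate(
        StaticCapture(1, arm_stream[:n_cal], rate),
        StaticCapture(2, forearm_stream[:n_cal], rate),
        mounts,
    )


def transform_streams(
    arm_stream: list[SensorSample],
    forearm_stream: list[SensorSample],
    rate: int,
    calib: CalibrationResult,
    params: FusionParams | None = None,
    pose_mode: str = "auto",
) -> tuple[JointAngleSeries, OrientationTrack, OrientationTrack]:
    """Run the movement pipeline on raw streams with an existing calibration."""
    if params is None:
        params = FusionParams(dt=1.0 / rate)
    tracks = {}
    for sid, stream in ((1, arm_stream), (2, forearm_stream)):
        T_m, T_r = calib.M[sid], calib.mounts[sid].R
        corrected = [apply_frame_transform(s, T_m, T_r) for s in stream]
        tracks[sid] = fuse_stream(corrected, calib, params, segment_id=sid)
    series = angle_series(tracks[1], tracks[2], pose_mode=pose_mode)
    return series, tracks[1], tracks[2]
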
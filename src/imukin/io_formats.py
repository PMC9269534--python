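"""Readers and writers for the plain-text capture dialects.

Three dialects are supported:

* the wearable-system per-sensor files — whitespace-separated decimals, 3
  columns (Euler angles), 4 columns (scalar-first quaternions) or 9 columns
  (raw accel/gyro/mag).  These files carry no time column; time is
  reconstructed as ``k / rate``;
* optical-reference exports — a header row, a time column, then per-rigid-body
  ``Y_Yaw_#``, ``X_Pitch_#``, ``Z_Roll_#`` angle columns in degrees (comma- or
  whitespace-separated, auto-detected);
* the kinematic output file — a time column plus one column of degrees per
  analytical unit of movement, written through a 120-line buffer.

All writers use 6 decimal places; all parsers accept any run of spaces/tabs,
tolerate blank lines and trailing whitespace, and use the decimal point
regardless of locale.
"""

from __future__ import annotations

import io
import re
from pathlib import Path

import numpy as np

from .calibration import CalibrationResult, MountingRotation, SensorSample
from .exceptions import (
    IncompleteRigidBodyError,
    MalformedRowError,
    OrderingError,
    ParseError,
)
from .kinematics import JointAngleSeries

__all__ = [
    "IMOCAP_MODES",
    "calibration_from_toml",
    "calibration_to_toml",
    "read_imocap",
    "read_kinematic",
    "read_motive",
    "read_raw_stream",
    "read_session",
    "write_imocap",
    "write_kinematic",
    "write_motive",
    "write_raw_stream",
    "write_session",
]

#: dialect mode -> expected column count
IMOCAP_MODES = {"euler": 3, "quaternion": 4, "raw": 9}

PRECISION = 6


def _parse_rows(path: str | Path, n_cols: int | None) -> np.ndarray:
    """Parse whitespace-separated numeric rows, enforcing a column count."""
    rows = []
    with open(path, "r", encoding="ascii") as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue  # blank line
            if n_cols is None:
                n_cols = len(fields)
            if len(fields) != n_cols:
                raise MalformedRowError(
                    f"{path}: line {lineno}: expected {n_cols} fields, got {len(fields)}",
                    line_number=lineno,
                )
            try:
                rows.append([float(f) for f in fields])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-numeric field ({exc})", lineno)
    return np.array(rows, dtype=float).reshape(-1, n_cols or 0)


def read_imocap(path: str | Path, mode: str | None = None) -> tuple[str, np.ndarray]:
    """Read a per-sensor file; the mode is inferred from the column count if omitted.

    Returns ``(mode, rows)`` with row order preserved; the sample index is the
    row index.
    """
    if mode is not None:
        if mode not in IMOCAP_MODES:
            raise ParseError(f"unknown dialect mode {mode!r}")
        rows = _parse_rows(path, IMOCAP_MODES[mode])
        return mode, rows
    rows = _parse_rows(path, None)
    n_cols = rows.shape[1] if rows.size else 0
    for name, cols in IMOCAP_MODES.items():
        if cols == n_cols:
            return name, rows
    raise MalformedRowError(f"{path}: {n_cols} columns match no known dialect mode")


def write_imocap(path: str | Path, rows: np.ndarray, mode: str) -> None:
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    if rows.size and rows.shape[1] != IMOCAP_MODES[mode]:
        raise MalformedRowError(f"mode {mode!r} requires {IMOCAP_MODES[mode]} columns")
    with open(path, "w", encoding="ascii") as fh:
        for row in rows:
            fh.write(" ".join(f"{v:.{PRECISION}f}" for v in row) + "\n")


def read_raw_stream(path: str | Path, rate: int = 60) -> list[SensorSample]:
    """Raw 9-column file -> samples, with time reconstructed as k / rate."""
    _, rows = read_imocap(path, mode="raw")
    return [
        SensorSample(k=i, t=i / rate, a=row[0:3], w=row[3:6], b=row[6:9])
        for i, row in enumerate(rows)
    ]


def write_raw_stream(path: str | Path, stream: list[SensorSample]) -> None:
    rows = np.array([np.concatenate([s.a, s.w, s.b]) for s in stream]).reshape(-1, 9)
    write_imocap(path, rows, mode="raw")


# --------------------------------------------------------------------------
# optical-reference (Motive-style) export
# --------------------------------------------------------------------------

_MOTIVE_COL = re.compile(r"^([YXZ])_(Yaw|Pitch|Roll)_(\w+)$")


def read_motive(path: str | Path) -> dict[str, dict[str, np.ndarray]]:
    """Parse an optical export into per-rigid-body angle series.

    Returns ``{rigid_body_id: {"times": ..., "yaw": ..., "pitch": ..., "roll": ...}}``
    in degrees.  The separator (comma vs whitespace) is auto-detected from the
    header row.
    """
    with open(path, "r", encoding="ascii") as fh:
        text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise MalformedRowError(f"{path}: empty file, header expected")
    sep = "," if "," in lines[0] else None
    header = [h.strip() for h in lines[0].split(sep)]
    if header[0].lower() != "time":
        raise MalformedRowError(f"{path}: first column must be 'time', got {header[0]!r}")

    bodies: dict[str, dict[str, int]] = {}
    for idx, name in enumerate(header[1:], start=1):
        m = _MOTIVE_COL.match(name)
        if not m:
            raise MalformedRowError(f"{path}: unrecognised column {name!r}")
        bodies.setdefault(m.group(3), {})[m.group(2).lower()] = idx
    for body, cols in bodies.items():
        missing = {"yaw", "pitch", "roll"} - set(cols)
        if missing:
            raise IncompleteRigidBodyError(
                f"{path}: rigid body {body!r} missing column(s) {sorted(missing)}"
            )

    data = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = [f for f in line.split(sep) if f.strip()]
        if len(fields) != len(header):
            raise MalformedRowError(
                f"{path}: line {lineno}: expected {len(header)} fields, got {len(fields)}",
                line_number=lineno,
            )
        try:
            data.append([float(f) for f in fields])
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: non-numeric field ({exc})", lineno)
    table = np.array(data, dtype=float).reshape(-1, len(header))
    times = table[:, 0]
    if np.any(np.diff(times) <= 0):
        raise OrderingError(f"{path}: time column must be strictly increasing")
    return {
        body: {
            "times": times.copy(),
            "yaw": table[:, cols["yaw"]],
            "pitch": table[:, cols["pitch"]],
            "roll": table[:, cols["roll"]],
        }
        for body, cols in bodies.items()
    }


def write_motive(
    path: str | Path, times: np.ndarray, bodies: dict[str, dict[str, np.ndarray]]
) -> None:
    """Write an optical-style export (comma-separated)."""
    header = ["time"]
    for body in bodies:
        header += [f"Y_Yaw_{body}", f"X_Pitch_{body}", f"Z_Roll_{body}"]
    with open(path, "w", encoding="ascii") as fh:
        fh.write(",".join(header) + "\n")
        for i, t in enumerate(times):
            row = [f"{t:.{PRECISION}f}"]
            for body, chans in bodies.items():
                row += [f"{chans[c][i]:.{PRECISION}f}" for c in ("yaw", "pitch", "roll")]
            fh.write(",".join(row) + "\n")


# --------------------------------------------------------------------------
# kinematic output file (buffered session writer)
# --------------------------------------------------------------------------

class _BufferedWriter:
    """Accumulates rows and flushes them to storage in fixed-size blocks.

    Mirrors the capture software's line buffer: content is identical for any
    buffer size; only the flush pattern changes (observable via ``flushes``).
    """

    def __init__(self, fh: io.TextIOBase, buffer_lines: int):
        self.fh = fh
        self.buffer_lines = max(1, int(buffer_lines))
        self.pending: list[str] = []
        self.flushes = 0

    def write_line(self, line: str) -> None:
        self.pending.append(line)
        if len(self.pending) >= self.buffer_lines:
            self._flush()

    def _flush(self) -> None:
        if self.pending:
            self.fh.write("\n".join(self.pending) + "\n")
            self.fh.flush()
            self.pending.clear()
            self.flushes += 1

    def close(self) -> None:
        self._flush()


def write_kinematic(
    series: JointAngleSeries, path: str | Path, buffer_lines: int = 120
) -> int:
    """Write the kinematic file (time + one column per analytical unit).

    Returns the number of buffer flushes performed (the trailing remainder
    flush included), so the buffering behaviour is observable in tests.
    """
    with open(path, "w", encoding="ascii") as fh:
        fh.write("time,flexion_extension,pronation_supination\n")
        writer = _BufferedWriter(fh, buffer_lines)
        for t, d, p in zip(series.times, series.flexion_extension, series.pronation_supination):
            writer.write_line(f"{t:.{PRECISION}f},{d:.{PRECISION}f},{p:.{PRECISION}f}")
        writer.close()
        return writer.flushes


def read_kinematic(path: str | Path) -> JointAngleSeries:
    with open(path, "r", encoding="ascii") as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines or lines[0].split(",")[0] != "time":
        raise MalformedRowError(f"{path}: kinematic header missing")
    header = lines[0].split(",")
    data = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split(",")
        if len(fields) != len(header):
            raise MalformedRowError(
                f"{path}: line {lineno}: expected {len(header)} fields", line_number=lineno
            )
        try:
            data.append([float(f) for f in fields])
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: non-numeric field ({exc})", lineno)
    table = np.array(data, dtype=float).reshape(-1, len(header))
    return JointAngleSeries(
        times=table[:, 0],
        flexion_extension=table[:, 1],
        pronation_supination=table[:, 2],
        pose_mode="auto",
    )


# --------------------------------------------------------------------------
# calibration persistence (TOML)
# --------------------------------------------------------------------------

def _fmt_matrix(m: np.ndarray) -> str:
    rows = ", ".join("[" + ", ".join(f"{v:.12g}" for v in row) + "]" for row in m)
    return f"[{rows}]"


def calibration_to_toml(calib: CalibrationResult, path: str | Path) -> None:
    lines = []
    for sid in (1, 2):
        mount = calib.mounts[sid]
        lines.append(f"[sensor_{sid}]")
        lines.append(f"delta_angles = [{mount.delta_angles[0]}, {mount.delta_angles[1]}]")
        lines.append(f"M = {_fmt_matrix(calib.M[sid])}")
        lines.append(f"mean_a = [{', '.join(f'{v:.12g}' for v in calib.mean_a[sid])}]")
        lines.append(f"mean_b = [{', '.join(f'{v:.12g}' for v in calib.mean_b[sid])}]")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="ascii")


def calibration_from_toml(path: str | Path) -> CalibrationResult:
    import tomllib

    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    M, mounts, mean_a, mean_b = {}, {}, {}, {}
    for sid in (1, 2):
        sec = doc[f"sensor_{sid}"]
        M[sid] = np.array(sec["M"], dtype=float)
        mounts[sid] = MountingRotation(sid, tuple(float(v) for v in sec["delta_angles"]))
        mean_a[sid] = np.array(sec["mean_a"], dtype=float)
        mean_b[sid] = np.array(sec["mean_b"], dtype=float)
    return CalibrationResult(M=M, mounts=mounts, mean_a=mean_a, mean_b=mean_b)


# --------------------------------------------------------------------------
# simulated-session persistence
# --------------------------------------------------------------------------

def write_session(session, out_dir: str | Path) -> Path:
    """Write a simulated session as raw streams + truth CSV + metadata TOML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_raw_stream(out / "arm_raw.txt", session.arm_stream)
    write_raw_stream(out / "forearm_raw.txt", session.forearm_stream)
    write_kinematic(session.truth, out / "truth.csv")
    mounts = {m.sensor_id: m for m in session.mounts}
    meta = [
        f"rate = {session.rate}",
        f"t_cal = {session.t_cal}",
        f"seed = {session.noise.seed}",
        f"mount_1_deltas = [{mounts[1].delta_angles[0]}, {mounts[1].delta_angles[1]}]",
        f"mount_2_deltas = [{mounts[2].delta_angles[0]}, {mounts[2].delta_angles[1]}]",
    ]
    (out / "session.toml").write_text("\n".join(meta) + "\n", encoding="ascii")
    return out


def read_session(session_dir: str | Path):
    """Read back a session directory written by :func:`write_session`.

    Returns ``(arm_stream, forearm_stream, rate, t_cal, mounts)``.
    """
    import tomllib

    d = Path(session_dir)
    with open(d / "session.toml", "rb") as fh:
        meta = tomllib.load(fh)
    rate = int(meta["rate"])
    arm = read_raw_stream(d / "arm_raw.txt", rate)
    forearm = read_raw_stream(d / "forearm_raw.txt", rate)
    mounts = (
        MountingRotation(1, tuple(float(v) for v in meta["mount_1_deltas"])),
        MountingRotation(2, tuple(float(v) for v in meta["mount_2_deltas"])),
    )
    return arm, forearm, rate, float(meta["t_cal"]), mounts
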
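"""Two-system comparison: time alignment and RMSE between angle series.

The wearable-derived series and a reference series (optical export or the
simulator's ground truth) are resampled by linear interpolation onto the grid
of the slower system, the inter-system lag is estimated by maximising the
normalised cross-correlation within a +-max_lag window, and the agreement is
summarised per movement channel as RMSE, bias (mean signed difference) and
range-of-motion difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal

from .exceptions import EmptyInputError, InvalidArgumentError, NoOverlapError
from .kinematics import JointAngleSeries, RomStats, rom_summary

__all__ = ["AlignedPair", "ChannelComparison", "ComparisonReport", "align", "compare", "rmse"]

CHANNELS = ("flexion_extension", "pronation_supination")


@dataclass
class AlignedPair:
    """Two single-channel series on a common grid, with the estimated lag."""

    times: np.ndarray
    series_a: np.ndarray
    series_b: np.ndarray
    lag: float  # seconds; positive = b lags a
    rate: float
    degenerate: bool = False  # flat series: lag fixed at 0


def _estimate_lag(a: np.ndarray, b: np.ndarray, dt: float, max_lag: float) -> tuple[float, bool]:
    a = a - np.mean(a)
    b = b - np.mean(b)
    if np.std(a) < 1e-12 or np.std(b) < 1e-12:
        return 0.0, True
    corr = signal.correlate(a, b, mode="full")
    lags = signal.correlation_lags(len(a), len(b), mode="full")
    window = np.abs(lags * dt) <= max_lag + 1e-12
    corr, lags = corr[window], lags[window]
    # correlate peaks at a negative index when b is a delayed copy of a;
    # flip the sign so positive lag reads "b lags a"
    return float(-lags[np.argmax(corr)] * dt), False


def align(
    a: JointAngleSeries,
    b: JointAngleSeries,
    max_lag: float = 2.0,
    channel: str = "flexion_extension",
) -> AlignedPair:
    """Resample both series to the lower rate and undo the inter-system lag.

    The returned ``lag`` is the shift (seconds) applied to ``b``'s time base;
    a flat (zero-variance) channel cannot carry timing information, so the lag
    is reported as 0 with ``degenerate=True``.
    """
    if channel not in CHANNELS:
        raise InvalidArgumentError(f"channel must be one of {CHANNELS}")
    if len(a) == 0 or len(b) == 0:
        raise EmptyInputError("cannot align an empty series")
    va = np.unwrap(getattr(a, channel), period=360.0)
    vb = np.unwrap(getattr(b, channel), period=360.0)

    rate = min(a.rate or b.rate, b.rate or a.rate)
    if rate <= 0:
        raise EmptyInputError("series too short to define a sampling rate")
    dt = 1.0 / rate

    # resample onto a provisional common grid for lag estimation
    t_lo = max(a.times[0], b.times[0])
    t_hi = min(a.times[-1], b.times[-1])
    if t_hi <= t_lo:
        raise NoOverlapError("series share no common time support")
    grid = np.arange(t_lo, t_hi + dt / 2, dt)
    ga = np.interp(grid, a.times, va)
    gb = np.interp(grid, b.times, vb)
    lag, degenerate = _estimate_lag(ga, gb, dt, max_lag)

    # shift b by the estimated lag and build the final overlap grid
    tb = b.times - lag
    t_lo = max(a.times[0], tb[0])
    t_hi = min(a.times[-1], tb[-1])
    if t_hi <= t_lo:
        raise NoOverlapError("no overlap remains after lag compensation")
    grid = np.arange(t_lo, t_hi + dt / 2, dt)
    return AlignedPair(
        times=grid,
        series_a=np.interp(grid, a.times, va),
        series_b=np.interp(grid, tb, vb),
        lag=lag,
        rate=rate,
        degenerate=degenerate,
    )


def rmse(pair: AlignedPair) -> float:
    """Root mean square difference of an aligned pair, degrees."""
    if len(pair.times) == 0:
        raise EmptyInputError("cannot compute RMSE of an empty pair")
    d = pair.series_a - pair.series_b
    return float(np.sqrt(np.mean(d * d)))


@dataclass(frozen=True)
class ChannelComparison:
    rmse: float
    bias: float
    rom_difference: float
    lag: float
    n: int


@dataclass
class ComparisonReport:
    """Per-movement agreement between a device series and a reference series."""

    channels: dict[str, ChannelComparison]

    def summary(self) -> str:
        lines = ["movement                 rmse_deg   bias_deg   rom_diff_deg   lag_s      n"]
        for name, c in self.channels.items():
            lines.append(
                f"{name:<24} {c.rmse:8.3f} {c.bias:10.3f} {c.rom_difference:14.3f}"
                f" {c.lag:6.3f} {c.n:6d}"
            )
        return "\n".join(lines)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", encoding="ascii") as fh:
            fh.write("movement,rmse_deg,bias_deg,rom_diff_deg,lag_s,n\n")
            for name, c in self.channels.items():
                fh.write(
                    f"{name},{c.rmse:.6f},{c.bias:.6f},{c.rom_difference:.6f},"
                    f"{c.lag:.6f},{c.n}\n"
                )


def compare(
    imu: JointAngleSeries, ref: JointAngleSeries, max_lag: float = 2.0
) -> ComparisonReport:
    """Align and summarise both movement channels of two angle series."""
    rom_imu = rom_summary(imu)
    rom_ref = rom_summary(ref)
    channels = {}
    for channel in CHANNELS:
        pair = align(imu, ref, max_lag=max_lag, channel=channel)
        channels[channel] = ChannelComparison(
            rmse=rmse(pair),
            bias=float(np.mean(pair.series_a - pair.series_b)),
            rom_difference=rom_imu[channel].range - rom_ref[channel].range,
            lag=pair.lag,
            n=len(pair.times),
        )
    return ComparisonReport(channels=channels)
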
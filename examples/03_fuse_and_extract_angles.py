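"""Full pipeline: raw streams -> calibration -> orientation fusion -> angles.

Runs the standard protocol under the default noise model and prints the
recovered range of motion and repetition counts per movement channel.
"""

from imukin import NoiseModel, protocol_table4, rom_summary, simulate_session
from imukin.pipeline import calibrate_from_streams, transform_streams

session = simulate_session(protocol_table4(), rate=60, noise=NoiseModel(seed=42))
calib = calibrate_from_streams(session.arm_stream, session.forearm_stream, 60, session.t_cal)
series, arm_track, forearm_track = transform_streams(
    session.arm_stream, session.forearm_stream, 60, calib
)

print(f"kinematic series: {len(series)} samples, pose mode {series.pose_mode!r}")
for name, stats in rom_summary(series).items():
    print(f"{name}: min {stats.minimum:7.2f}  max {stats.maximum:7.2f}  "
          f"range {stats.range:7.2f} deg  repetitions {stats.repetitions}")
print(f"max off-axis residual: {series.off_axis_residual.max():.2f} deg")
# Flexion should span ~0..145 deg with 5 large repetitions, pronation-
# supination ~ -80..80 deg with 5; the off-axis residual is the per-sample
# rotation the two assigned joint axes cannot explain.
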
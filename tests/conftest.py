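import numpy as np
import pytest

from imukin.pipeline import calibrate_from_streams, transform_streams
from imukin.simulator import (
    MotionProtocol,
    NoiseModel,
    protocol_table4,
    simulate_session,
    truth_export,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def random_rotations(rng):
    """1000 uniformly random rotation matrices (via normalized quaternions)."""
    from imukin.rotations import quat_to_matrix

    q = rng.normal(size=(1000, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    return np.stack([quat_to_matrix(qi) for qi in q])


@pytest.fixture(scope="session")
def static_session():
    """2 s noiseless static calibration-pose session at 60 Hz."""
    return simulate_session(
        MotionProtocol(phases=()),
        rate=60,
        noise=NoiseModel.noiseless(),
        t_cal=2.0,
        transition=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_table4_run():
    """Full noiseless standard-protocol session plus its pipeline output."""
    sess = simulate_session(protocol_table4(), rate=60, noise=NoiseModel.noiseless())
    calib = calibrate_from_streams(sess.arm_stream, sess.forearm_stream, 60, sess.t_cal)
    series, arm_track, forearm_track = transform_streams(
        sess.arm_stream, sess.forearm_stream, 60, calib
    )
    return sess, calib, series, truth_export(sess)


@pytest.fixture(scope="session")
def noisy_table4_run():
    """Same pipeline under the default seeded noise model."""
    sess = simulate_session(protocol_table4(), rate=60, noise=NoiseModel(seed=7))
    calib = calibrate_from_streams(sess.arm_stream, sess.forearm_stream, 60, sess.t_cal)
    series, _, _ = transform_streams(sess.arm_stream, sess.forearm_stream, 60, calib)
    return sess, calib, series, truth_export(sess)
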
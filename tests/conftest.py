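"""Shared fixtures: synthetic walks and paired calibration data.

Session-scoped because the walking simulations and the full pipeline are the
expensive parts; all tests treat the fixtures as read-only.
"""

import numpy as np
import pytest

import pocketgait as pg

# canonical steady-walk study conditions used across the suite
STEP_LENGTH = 0.6
LEG_LENGTH = 0.9
CADENCE = 1.8  # steps/s
DURATION = 30.0
STRIDE_TIME = 2.0 / CADENCE
SPEED = 2 * STEP_LENGTH / STRIDE_TIME

TABLE_ALL = (1.37, 1.02, 0.74)
ZONE_EDGES = (0.2, 0.5, 0.8, 1.1)


@pytest.fixture(scope="session")
def walk_noiseless():
    """Noiseless steady walk, identity orientation, with impact transients."""
    profile = pg.WalkProfile.constant(
        step_length=STEP_LENGTH,
        cadence=CADENCE,
        duration_s=DURATION,
        leg_length=LEG_LENGTH,
        noise_sd=0.0,
        gyro_noise_sd=0.0,
        seed=1,
    )
    return pg.simulate_imu_walk(profile)


@pytest.fixture(scope="session")
def walk_noisy():
    """Same walk with 10° tilt, 0.1 m/s² bias and 0.5 m/s² accelerometer noise."""
    profile = pg.WalkProfile.constant(
        step_length=STEP_LENGTH,
        cadence=CADENCE,
        duration_s=DURATION,
        leg_length=LEG_LENGTH,
        noise_sd=0.5,
        accel_bias=0.1,
        orientation_q=tuple(pg.tilt_quaternion(10.0)),
        seed=0,
    )
    return pg.simulate_imu_walk(profile)


@pytest.fixture(scope="session")
def stride_table_noiseless(walk_noiseless):
    rec, _ = walk_noiseless
    return pg.estimate_gait(rec)


@pytest.fixture(scope="session")
def paired_biased():
    """Paired steps with the published piecewise bias, n=400, noise SD 0.02 m."""
    return pg.simulate_paired_steps(
        400,
        zone_edges=ZONE_EDGES,
        zone_coeffs=TABLE_ALL,
        noise_sd=0.02,
        seed=11,
    )
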
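"""Shared fixtures: one fully analysed synthetic session per scope.

Long (20-min) sessions are session-scoped so the expensive simulation and
spike generation run once; short fixtures are built inline where needed.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hdtheta as ht

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def circle_arena():
    return ht.ArenaSpec("circle")


@pytest.fixture(scope="session")
def traj20(circle_arena):
    """A 20-min foraging session in the 96 cm circular arena."""
    return ht.simulate_trajectory(circle_arena, 1200.0, 50.0, seed=1)


@pytest.fixture(scope="session")
def hd_series(traj20):
    return ht.head_direction_from_leds(traj20)


@pytest.fixture(scope="session")
def angvel(hd_series):
    return ht.angular_velocity(hd_series)


@pytest.fixture(scope="session")
def docc(hd_series):
    return ht.directional_occupancy(hd_series)


@pytest.fixture(scope="session")
def occ25(traj20):
    return ht.spatial_occupancy(traj20, 2.5)


@pytest.fixture(scope="session")
def hd_truth():
    return ht.GroundTruth.hd_cell(preferred_direction_deg=90.0, kappa=4.0,
                                  peak_rate_hz=30.0, baseline_hz=0.5,
                                  cw_ccw_offset_deg=20.0, seed=2)


@pytest.fixture(scope="session")
def hd_train(traj20, hd_truth):
    return ht.generate_hd_spike_train(traj20, hd_truth, seed=2)


@pytest.fixture(scope="session")
def skipping_train():
    """10-min theta-cycle-skipping train at the generator defaults."""
    truth = ht.GroundTruth.theta_skipping_cell(seed=2)
    return ht.generate_theta_skipping_train(600.0, truth, seed=2)


@pytest.fixture(scope="session")
def skipping_fit(skipping_train):
    acorr = ht.autocorrelogram(skipping_train)
    return acorr, ht.fit_skipping_model(acorr)
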
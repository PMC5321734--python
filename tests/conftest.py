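import numpy as np
import pytest

from beltfield import build_belt, simulate_trajectory
from beltfield.ratemaps import compute_occupancy
from beltfield.synth import GroundTruthUnit, simulate_spike_trains


@pytest.fixture(scope="session")
def two_spine_belt():
    return build_belt(200.0, [("spine", 40, 10), ("spine", 140, 10)])


@pytest.fixture(scope="session")
def mixed_belt():
    return build_belt(
        200.0,
        [("spine", 20, 10), ("spine", 120, 10), ("tube", 70, 10), ("tube", 170, 10)],
    )


@pytest.fixture(scope="session")
def trajectory(two_spine_belt):
    return simulate_trajectory(two_spine_belt, n_trials=100, seed=12345)


@pytest.fixture(scope="session")
def occupancy(trajectory):
    return compute_occupancy(trajectory)


@pytest.fixture(scope="session")
def lv_unit():
    return GroundTruthUnit(
        "lv0", "LV", background_hz=1.0, peak_hz=6.0, offset_cm=-5.0,
        anchor_types=("spine",),
    )


@pytest.fixture(scope="session")
def lv_session(two_spine_belt, trajectory, lv_unit):
    spikes, _, _ = simulate_spike_trains(
        two_spine_belt, trajectory, [lv_unit], seed=7
    )
    return spikes["lv0"]
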
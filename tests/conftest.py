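import numpy as np
import pytest

from chairsts import ChairGeometry, chair_angles, marker_angles, simulate_trial


@pytest.fixture(scope="session")
def geom():
    return ChairGeometry()


@pytest.fixture(scope="session")
def noiseless_normal_trial(geom):
    return simulate_trial("normal", geom)


@pytest.fixture(scope="session")
def noiseless_normal_angles(geom, noiseless_normal_trial):
    trial = noiseless_normal_trial
    return chair_angles(trial.distances, geom), marker_angles(trial.markers)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
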
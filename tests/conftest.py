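import numpy as np
import pandas as pd
import pytest

from sulakit.config import GroupDesign, SimConfig, default_config
from sulakit.synthetic import generate_tracks
from sulakit.trajectories import split_trips, step_features


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Two groups, few birds: fast but non-trivial."""
    groups = (
        GroupDesign("BRBO", "F", "JunOct", 4, 3, (0.6, 0.2, 0.2), 180.0, 22.0),
        GroupDesign("BRBO", "M", "JunOct", 4, 3, (0.45, 0.25, 0.3), 150.0, 35.0),
    )
    return SimConfig(groups=groups, seed=11)


@pytest.fixture(scope="session")
def tracks(small_config):
    return generate_tracks(small_config)


@pytest.fixture(scope="session")
def trips(small_config, tracks):
    fixes, _ = tracks
    return split_trips(fixes, small_config.colony_lonlat, small_config.colony_radius_km)


@pytest.fixture(scope="session")
def steps(trips) -> pd.DataFrame:
    return pd.concat([step_features(t) for t in trips], ignore_index=True)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
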
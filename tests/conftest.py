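import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from estuaryuse.synthetic_data import SimConfig, make_shoreline_fixture

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(20030809)


@pytest.fixture(scope="session")
def shoreline():
    return make_shoreline_fixture()


@pytest.fixture
def noise_free_config():
    """SimConfig with every stochastic ingredient silenced."""
    return SimConfig(
        residency_sd_km=0.0,
        tide_coupling_km_per_m=0.0,
        argos_error_sd_km={c: 0.0 for c in "321"} | {"0": 0.0, "A": 0.0, "B": 0.0},
        argos_class_probs={"3": 1.0, "2": 0.0, "1": 0.0, "0": 0.0, "A": 0.0, "B": 0.0},
        seed=7,
    )


def make_fixes(rows):
    """Build a fix table from (whale_id, timestamp, lon, lat, cls) tuples."""
    return pd.DataFrame(
        rows, columns=["whale_id", "timestamp", "lon", "lat", "location_class"]
    ).assign(timestamp=lambda d: pd.to_datetime(d["timestamp"]))
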
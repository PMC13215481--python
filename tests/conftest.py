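import numpy as np
import pandas as pd
import pytest


def make_track(buoy_id, start, lats, lons, ve=0.0, vn=0.0, step_hours=6):
    """Hand-built drifter track: one fix per (lat, lon) at a 6-h cadence."""
    n = len(lats)
    return pd.DataFrame({
        "id": buoy_id,
        "datetime": pd.Timestamp(start) + pd.to_timedelta(np.arange(n) * step_hours, unit="h"),
        "lat": np.asarray(lats, dtype=float),
        "lon": np.asarray(lons, dtype=float),
        "ve": ve, "vn": vn,
    })


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def traits():
    from thalassochory.datasets import load_species_traits
    return load_species_traits()
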
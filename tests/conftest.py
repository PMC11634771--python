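import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from foramshift.census import META_COLUMNS

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_census(rows: list[dict]) -> pd.DataFrame:
    """Build a canonical census frame from row dicts with defaults."""
    defaults = {
        "subsample_id": None, "sample_id": "smp", "latitude": 40.0,
        "longitude": -30.0, "date": "2000-07-15", "depth_upper": 0.0,
        "depth_lower": 100.0, "device": "net", "size_lower": 100.0,
        "size_upper": np.nan, "volume_filtered": 25.0, "count_kind": "concentration",
    }
    out = []
    for i, row in enumerate(rows):
        r = {**defaults, **row}
        if r["subsample_id"] is None:
            r["subsample_id"] = f"s{i}"
        out.append(r)
    df = pd.DataFrame(out)
    df["date"] = pd.to_datetime(df["date"])
    species = [c for c in df.columns if c not in META_COLUMNS]
    df[species] = df[species].fillna(0.0)
    return df


@pytest.fixture
def census_two_stations():
    """Two 4-member net profiles at different stations plus a CPR record."""
    rows = []
    for stn, (lat, lon) in enumerate([(40.0, -30.0), (45.0, -20.0)]):
        for du, dl in [(0, 20), (20, 50), (50, 100), (100, 200)]:
            rows.append({"sample_id": f"st{stn}", "latitude": lat, "longitude": lon,
                         "depth_upper": du, "depth_lower": dl,
                         "A": 5.0 * (stn + 1), "B": 1.0 if du == 20 else 0.0})
    rows.append({"sample_id": "cpr1", "latitude": 50.0, "longitude": -10.0,
                 "depth_upper": 5, "depth_lower": 10, "device": "cpr", "A": 2.0})
    return make_census(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
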
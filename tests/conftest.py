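import numpy as np
import pandas as pd
import pytest

from gridexposure import synthgrid


@pytest.fixture(scope="session")
def registry_3x3():
    registry, adjacency = synthgrid.generate_registry(3, 3, seed=11)
    return registry, adjacency


@pytest.fixture(scope="session")
def registry_5x5():
    registry, adjacency = synthgrid.generate_registry(5, 5, seed=7)
    return registry, adjacency


def make_registry(n_rows, n_cols, customers=100_000, offset=0, seed=0):
    """Registry with fixed customer totals and a single UTC offset."""
    registry, adjacency = synthgrid.generate_registry(
        n_rows, n_cols, customer_range=(customers, customers), seed=seed
    )
    registry = registry.copy()
    registry["utc_offset_hours"] = offset
    return registry, adjacency


def hourly_from_binary(above, customers_total=100_000, threshold=0.001,
                       county_id="00001", start="2018-01-01"):
    """Hourly series whose above-threshold pattern equals a binary sequence."""
    above = np.asarray(above, dtype=bool)
    hours = pd.date_range(start, periods=above.size, freq="h")
    out = np.where(above, int(np.ceil(threshold * customers_total)), 0)
    return pd.DataFrame(
        {
            "county_id": county_id,
            "hour_start": hours,
            "customers_out_max": out.astype(float),
            "customers_out_mean": out.astype(float),
            "n_reports": 6,
            "reported": True,
        }
    )


def single_county_registry(customers_total=100_000, county_id="00001", offset=0):
    return pd.DataFrame(
        {
            "county_id": [county_id],
            "state_id": ["S00"],
            "households": [int(customers_total * 0.8)],
            "businesses": [customers_total - int(customers_total * 0.8)],
            "customers_total": [customers_total],
            "grid_row": [0],
            "grid_col": [0],
            "utc_offset_hours": [offset],
        }
    )
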
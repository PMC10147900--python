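"""Reference tabulations bundled with the package.

The county-day co-occurrence counts below come from a published national
2018–2020 US county-level outage surveillance analysis (1653 continental
counties with three reliable years of data; 1,799,319 county-days).  They
are the machine-readable twin of that study's co-occurrence tabulation and
serve as worked-example inputs for the ratio statistic: the ratio column is
never stored, always recomputed from the counts.
"""

from __future__ import annotations

import pandas as pd

from .climate import build_cooccurrence_table, co_occurrence_ratio  # noqa: F401

# (category, row level, county-days, outage county-days)
_US_COOCCURRENCE_ROWS = [
    ("Total", "total", 1_799_319, 22_793),
    ("None", "none", 1_265_213, 8_637),
    ("Isolated event", "isolated", 492_489, 11_310),
    ("Heavy precipitation", "isolated_type", 267_823, 8_507),
    ("Snowfall", "isolated_type", 25_523, 1_172),
    ("Anomalous heat", "isolated_type", 131_727, 1_090),
    ("Anomalous cold", "isolated_type", 57_924, 344),
    ("Wildfire", "isolated_type", 5_381, 84),
    ("Lightning", "isolated_type", 3_578, 63),
    ("Tropical cyclone", "isolated_type", 533, 50),
    ("Multiple event", "multiple", 41_617, 2_846),
    ("Heavy precipitation-anomalous heat", "multiple_combo", 17_415, 917),
    ("Heavy precipitation-cyclone", "multiple_combo", 2_650, 679),
    ("Heavy precipitation-lightning", "multiple_combo", 8_142, 644),
    ("Snowfall-anomalous cold", "multiple_combo", 7_151, 250),
    ("Heavy precipitation-anomalous cold", "multiple_combo", 1_779, 134),
    ("Heavy precipitation-anomalous heat-cyclone", "multiple_combo", 244, 86),
    ("Heavy precipitation-anomalous heat-lightning", "multiple_combo", 1_197, 78),
    ("Other", "multiple_combo", 3_039, 58),
]


def us_cooccurrence_counts() -> pd.DataFrame:
    """County-day co-occurrence counts of weather events and 8+ hour outages.

    Columns: ``category``, ``rowlevel``, ``n_county_days``,
    ``n_outage_days``.  Combination labels use this package's canonical
    event-type order.
    """
    return pd.DataFrame(
        _US_COOCCURRENCE_ROWS,
        columns=["category", "rowlevel", "n_county_days", "n_outage_days"],
    )


def us_cooccurrence_ratios() -> pd.DataFrame:
    """The counts table with percentages and co-occurrence ratios recomputed.

    Ratios divide each category's outage share by the share among no-event
    county-days; Total and None rows carry no ratio.
    """
    table = us_cooccurrence_counts()
    none = table.loc[table["rowlevel"] == "none"].iloc[0]
    total = table.loc[table["rowlevel"] == "total"].iloc[0]
    table["pct_county_days"] = 100.0 * table["n_county_days"] / total["n_county_days"]
    table["pct_outage_days"] = 100.0 * table["n_outage_days"] / total["n_outage_days"]
    ratios = []
    for _, r in table.iterrows():
        if r["rowlevel"] in ("total", "none"):
            ratios.append(float("nan"))
        else:
            ratios.append(
                co_occurrence_ratio(
                    r["n_outage_days"],
                    r["n_county_days"],
                    none["n_outage_days"],
                    none["n_county_days"],
                )
            )
    table["ratio"] = ratios
    return table
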
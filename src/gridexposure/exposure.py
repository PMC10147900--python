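"""Outage threshold derivation, event detection and exposure metrics.

The 10-minute feed is aggregated to the county-hour (local clock).  A
county-hour is "out" when the share of customers without power reaches or
exceeds a relative threshold — 0.1% of county customers by default, the
90th percentile of county-hour fractions in the source data, with a
data-driven percentile alternative available.  Maximal runs of consecutive
out-hours form outage events; runs of 1+ and 8+ hours are the two duration
classes of interest (8+ hours is the medically relevant class, past the
battery life of much durable medical equipment).

Two metric families are computed:

* relative (SAIFI-like): annual average counts of 1+ / 8+ hour events per
  county, comparable across counties of different size;
* absolute (SAIDI-like): customer-hours without power, total and per
  customer.

Detection uses the within-hour maximum (an outage visible at any reading
counts); customer-hour integration uses the within-hour mean of readings
(each 10-minute reading represents its slot).  Unreported hours break runs:
missingness is never treated as an outage.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.001  # 0.1% of county customers
THRESHOLD_PERCENTILE = 90.0


def estimate_customer_denominator(households: int, businesses: int) -> int:
    """County customers = households + business establishments."""
    if households < 0 or businesses < 0:
        raise ValueError("household and business counts must be >= 0")
    return int(households) + int(businesses)


def aggregate_to_hourly(
    stream: pd.DataFrame,
    registry: pd.DataFrame,
    span: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """County-hour series (local clock) from 10-minute readings.

    Per county-hour: the maximum and the mean of the readings in that hour
    (equal weights on the regular 10-minute grid) and a ``reported`` flag.
    Hours with no reading carry NaN values and ``reported=False``.  When
    ``span`` (local dates, inclusive) is given every county is expanded to
    the full hourly grid of the span; otherwise each county spans its own
    first-to-last reported hour.
    """
    if (stream["customers_out"] < 0).any():
        bad = stream.index[stream["customers_out"] < 0][0]
        raise ValueError(f"negative customers_out at row {bad}")
    offsets = registry.set_index("county_id")["utc_offset_hours"]
    local = pd.to_datetime(stream["timestamp"]) + pd.to_timedelta(
        stream["county_id"].map(offsets).astype(int), unit="h"
    )
    df = pd.DataFrame(
        {
            "county_id": stream["county_id"],
            "hour_start": local.dt.floor("h"),
            "customers_out": stream["customers_out"],
        }
    )
    agg = (
        df.groupby(["county_id", "hour_start"], observed=True)["customers_out"]
        .agg(customers_out_max="max", customers_out_mean="mean", n_reports="size")
        .reset_index()
    )
    if span is not None:
        start = pd.Timestamp(span[0])
        end = pd.Timestamp(span[1]) + pd.Timedelta(hours=23)
        hours = pd.date_range(start, end, freq="h")
        full = pd.MultiIndex.from_product(
            [registry["county_id"], hours], names=["county_id", "hour_start"]
        )
        agg = (
            agg.set_index(["county_id", "hour_start"])
            .reindex(full)
            .reset_index()
        )
    else:
        pieces = []
        for cid, sub in agg.groupby("county_id", observed=True, sort=False):
            hours = pd.date_range(
                sub["hour_start"].min(), sub["hour_start"].max(), freq="h"
            )
            pieces.append(
                sub.set_index("hour_start")
                .reindex(hours)
                .rename_axis("hour_start")
                .assign(county_id=cid)
                .reset_index()
            )
        agg = pd.concat(pieces, ignore_index=True)[
            ["county_id", "hour_start", "customers_out_max", "customers_out_mean", "n_reports"]
        ]
    agg["n_reports"] = agg["n_reports"].fillna(0).astype(int)
    agg["reported"] = agg["n_reports"] > 0
    return agg


def derive_threshold(fractions, percentile: float = THRESHOLD_PERCENTILE) -> float:
    """Data-driven threshold: a percentile of pooled county-hour fractions out.

    Linear interpolation between order statistics (numpy's default quantile
    rule).  The pipeline default is the fixed relative threshold 0.001; this
    operation recovers it empirically from a pooled distribution.
    """
    arr = np.asarray(fractions, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("cannot derive a threshold from an empty distribution")
    return float(np.percentile(arr, percentile, method="linear"))


def detect_outage_events(
    hourly: pd.DataFrame,
    registry: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Maximal runs of consecutive above-threshold county-hours.

    A county-hour qualifies when ``customers_out_max / customers_total >=
    threshold`` (exact fractions, no rounding).  Unreported hours terminate
    runs.  Returns one row per event: local start hour, duration in hours,
    peak customers out, and the event's customer-hours (sum of within-hour
    means over the run).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    totals = registry.set_index("county_id")["customers_total"]
    events = []
    for cid, sub in hourly.groupby("county_id", observed=True, sort=False):
        total = int(totals[cid])
        if total <= 0:
            raise ValueError(f"customers_total must be > 0 for {cid}")
        sub = sub.sort_values("hour_start")
        vals = sub["customers_out_max"].to_numpy(float)
        above = sub["reported"].to_numpy(bool) & (vals / total >= threshold)
        means = np.nan_to_num(sub["customers_out_mean"].to_numpy(float))
        hours = sub["hour_start"].to_numpy()
        for s, e in _runs(above):
            events.append(
                {
                    "county_id": cid,
                    "start_hour": hours[s],
                    "duration_hours": int(e - s),
                    "peak_customers_out": int(np.nanmax(vals[s:e])),
                    "event_customer_hours": float(means[s:e].sum()),
                }
            )
    cols = [
        "county_id",
        "start_hour",
        "duration_hours",
        "peak_customers_out",
        "event_customer_hours",
    ]
    out = pd.DataFrame(events, columns=cols)
    if not out.empty:
        out["start_hour"] = pd.to_datetime(out["start_hour"])
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) index pairs of maximal True runs."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts, ends))


def summarize_events(
    events: pd.DataFrame,
    registry: pd.DataFrame,
    reliable_years: dict[str, list[int]],
    hourly: pd.DataFrame | None = None,
    min_durations: tuple[int, int] = (1, 8),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-county-year event counts and per-county annual averages.

    Events are attributed to the local calendar year containing their start
    hour; only reliable county-years count.  Annual averages divide the
    total over reliable years by the number of reliable years.  When
    ``hourly`` is given, customer-hours totals and hours-per-customer are
    added per county-year.  Counties with no reliable years are excluded
    (logged).

    Returns ``(per_county_year, per_county)``.
    """
    lo, hi = min_durations
    totals = registry.set_index("county_id")["customers_total"]
    skipped = [c for c, ys in reliable_years.items() if not ys]
    if skipped:
        logger.warning("summarize_events: %d counties with zero reliable years", len(skipped))
    rows = []
    ev = events.copy()
    ev["year"] = pd.to_datetime(ev["start_hour"]).dt.year
    by_cy = dict(tuple(ev.groupby(["county_id", "year"], observed=True)))

    ch_by_cy = {}
    if hourly is not None:
        ch = compute_customer_hours(hourly)
        ch_by_cy = ch.to_dict()

    for cid, years in reliable_years.items():
        if not years:
            continue
        total = int(totals.get(cid, 0))
        for year in years:
            sub = by_cy.get((cid, year))
            n1 = int((sub["duration_hours"] >= lo).sum()) if sub is not None else 0
            n8 = int((sub["duration_hours"] >= hi).sum()) if sub is not None else 0
            row = {"county_id": cid, "year": year, "n_events_1h": n1, "n_events_8h": n8}
            if hourly is not None:
                cht = float(ch_by_cy.get((cid, year), 0.0))
                row["customer_hours_total"] = cht
                row["hours_per_customer"] = hours_per_customer(cht, total)
            rows.append(row)
    per_cy = pd.DataFrame(rows)
    if per_cy.empty:
        return per_cy, pd.DataFrame(columns=["county_id", "avg_n_events_1h", "avg_n_events_8h"])
    agg = {"avg_n_events_1h": ("n_events_1h", "mean"), "avg_n_events_8h": ("n_events_8h", "mean")}
    if hourly is not None:
        agg["avg_customer_hours"] = ("customer_hours_total", "mean")
        agg["avg_hours_per_customer"] = ("hours_per_customer", "mean")
    per_county = per_cy.groupby("county_id", observed=True).agg(**agg).reset_index()
    return per_cy, per_county


def compute_customer_hours(hourly: pd.DataFrame) -> pd.Series:
    """Customer-hours without power per county-year (hour x mean customers out)."""
    df = hourly.loc[hourly["reported"]].copy()
    df["year"] = pd.to_datetime(df["hour_start"]).dt.year
    return df.groupby(["county_id", "year"], observed=True)["customers_out_mean"].sum()


def hours_per_customer(customer_hours_total: float, customers_total: int) -> float:
    """SAIDI-like: hours without power experienced by the average customer."""
    if customers_total <= 0:
        raise ValueError("customers_total must be > 0")
    return customer_hours_total / customers_total


def tabulate_start_times(events: pd.DataFrame, min_duration: int = 8) -> pd.DataFrame:
    """Month x local-start-hour count matrix for events of a duration class.

    Rows are months 1..12, columns local hours 0..23; cell (m, h) counts
    events of ``min_duration``+ hours starting at local hour h in month m.
    The grand total equals the number of qualifying events.
    """
    sub = events.loc[events["duration_hours"] >= min_duration]
    mat = pd.DataFrame(
        0, index=pd.RangeIndex(1, 13, name="month"), columns=pd.RangeIndex(0, 24, name="hour")
    )
    if sub.empty:
        return mat
    start = pd.to_datetime(sub["start_hour"])
    counts = pd.crosstab(start.dt.month, start.dt.hour)
    mat = mat.add(counts.reindex(index=mat.index, columns=mat.columns, fill_value=0), fill_value=0)
    return mat.astype(int)
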
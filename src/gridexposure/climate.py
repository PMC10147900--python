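"""Severe weather / climate event classification and outage co-occurrence.

County-days are classified into seven event types from daily weather values
and climatological baselines, typed as none / isolated / multiple, aligned
with the start days of 8+ hour outage events, and summarized as a
co-occurrence table with ratio statistics.

Event definitions (daily, county level):

* anomalous heat  — temperature exceeds 24 °C and the county-week 85th
  percentile of the climatology baseline,
* anomalous cold  — temperature below 0 °C and the county-week 15th
  percentile,
* heavy precipitation — daily precipitation above the county 85th
  percentile (suppressed on snowfall days by default, see
  ``snow_suppresses_precip``),
* snowfall        — snow accumulation of 2.54 cm (1 inch) or more,
* lightning       — any lightning flash within the county,
* tropical cyclone — county within 100 km of a cyclone track center,
* wildfire        — county intersects a wildfire of at least 1 km².

The co-occurrence ratio for event category *i* is the share of category-*i*
county-days on which an 8+ hour outage began, divided by the same share
among county-days with no event at all.  A ratio above 1 means long outages
are over-represented on such days.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical event-type order used for flag columns and combination labels.
EVENT_TYPES = ["precip", "snow", "heat", "cold", "wildfire", "lightning", "cyclone"]

#: Display names for isolated single-event categories.
ISOLATED_LABELS = {
    "precip": "Heavy precipitation",
    "snow": "Snowfall",
    "heat": "Anomalous heat",
    "cold": "Anomalous cold",
    "wildfire": "Wildfire",
    "lightning": "Lightning",
    "cyclone": "Tropical cyclone",
}

#: Lower-case names used inside hyphenated combination labels.
COMBO_NAMES = {
    "precip": "heavy precipitation",
    "snow": "snowfall",
    "heat": "anomalous heat",
    "cold": "anomalous cold",
    "wildfire": "wildfire",
    "lightning": "lightning",
    "cyclone": "cyclone",
}

# Fixed physical thresholds.
HEAT_TEMP_C = 24.0
COLD_TEMP_C = 0.0
SNOW_CM = 2.54
CYCLONE_KM = 100.0
WILDFIRE_KM2 = 1.0


class UndefinedRatioError(ValueError):
    """Raised when a co-occurrence ratio has a zero denominator."""


def combination_label(types: tuple[str, ...] | list[str]) -> str:
    """Canonical hyphenated label for a set of co-occurring event types.

    Types are ordered canonically (``EVENT_TYPES``); the first word is
    capitalized, subsequent components are lower case, e.g.
    ``('precip', 'cyclone', 'heat')`` -> ``'Heavy precipitation-anomalous
    heat-cyclone'``.
    """
    ordered = [t for t in EVENT_TYPES if t in set(types)]
    if not ordered:
        raise ValueError("combination_label needs at least one event type")
    if len(ordered) == 1:
        return ISOLATED_LABELS[ordered[0]]
    parts = [COMBO_NAMES[t] for t in ordered]
    label = "-".join(parts)
    return label[0].upper() + label[1:]


def classify_county_days(
    weather: pd.DataFrame,
    baselines: pd.DataFrame,
    snow_suppresses_precip: bool = True,
) -> pd.DataFrame:
    """Classify county-days into the seven event flags and a category.

    Parameters
    ----------
    weather
        One row per county-day with columns ``county_id``, ``date``,
        ``temp_c``, ``precip_mm``, ``snowfall_cm``, ``lightning_flash``,
        ``cyclone_distance_km``, ``wildfire_area_km2``.  The daily
        temperature statistic (mean/max) is whatever the table carries; the
        rules are applied to it as-is.
    baselines
        Climatology with columns ``county_id``, ``week`` (ISO week 1..53),
        ``temp_p85_c``, ``temp_p15_c``, ``precip_p85_mm``.
    snow_suppresses_precip
        When True (default), the heavy-precipitation flag is forced off on
        snowfall days, so snowfall and heavy precipitation are separate
        categories rather than double counted.

    Returns
    -------
    DataFrame with the seven flag columns (0/1 in canonical order), the flag
    count ``n_events``, ``level`` in {none, isolated, multiple} and a display
    ``category`` label.  County-days without a matching baseline row are
    excluded (logged).
    """
    w = weather.copy()
    w["date"] = pd.to_datetime(w["date"])
    week = w["date"].dt.isocalendar().week.astype(int)
    w["week"] = week

    base = baselines.copy()
    if (base["temp_p15_c"] > base["temp_p85_c"]).any():
        raise ValueError("baseline has temp_p15_c > temp_p85_c")
    merged = w.merge(base, on=["county_id", "week"], how="left", validate="m:1")
    missing = merged["temp_p85_c"].isna() | merged["precip_p85_mm"].isna()
    if missing.any():
        logger.warning(
            "classify_county_days: %d county-days without baseline excluded",
            int(missing.sum()),
        )
        merged = merged.loc[~missing].copy()

    t = merged["temp_c"].to_numpy(float)
    flags = pd.DataFrame(index=merged.index)
    flags["heat"] = (t > HEAT_TEMP_C) & (t > merged["temp_p85_c"].to_numpy(float))
    flags["cold"] = (t < COLD_TEMP_C) & (t < merged["temp_p15_c"].to_numpy(float))
    flags["snow"] = merged["snowfall_cm"].to_numpy(float) >= SNOW_CM
    precip = merged["precip_mm"].to_numpy(float) > merged["precip_p85_mm"].to_numpy(float)
    if snow_suppresses_precip:
        precip = precip & ~flags["snow"].to_numpy()
    flags["precip"] = precip
    flags["lightning"] = merged["lightning_flash"].astype(bool)
    flags["cyclone"] = merged["cyclone_distance_km"].to_numpy(float) <= CYCLONE_KM
    flags["wildfire"] = merged["wildfire_area_km2"].to_numpy(float) >= WILDFIRE_KM2

    out = merged[["county_id", "date"]].copy()
    for name in EVENT_TYPES:
        out[name] = flags[name].astype(np.int8)
    n = out[EVENT_TYPES].sum(axis=1)
    out["n_events"] = n.astype(int)
    out["level"] = np.select([n == 0, n == 1], ["none", "isolated"], default="multiple")
    out["category"] = _category_labels(out)
    return out.reset_index(drop=True)


def _category_labels(classes: pd.DataFrame) -> pd.Series:
    """Vectorized display label per row from the flag columns."""
    bits = classes[EVENT_TYPES].to_numpy(bool)
    # encode flag pattern -> label, computed once per distinct pattern
    codes = bits.dot(1 << np.arange(len(EVENT_TYPES)))
    labels = {}
    for code in np.unique(codes):
        if code == 0:
            labels[code] = "None"
        else:
            types = [t for k, t in enumerate(EVENT_TYPES) if code >> k & 1]
            labels[code] = combination_label(types)
    return pd.Series(codes, index=classes.index).map(labels)


def align_outage_days(events: pd.DataFrame, classes: pd.DataFrame) -> pd.DataFrame:
    """Mark county-days on which an 8+ hour outage event began.

    ``events`` is an event table with ``county_id``, ``start_hour`` (local
    clock) and ``duration_hours``; only events lasting 8+ hours count.
    Several same-day starts in one county mark the day once.  Events whose
    county-day is not present in ``classes`` are logged and ignored.
    """
    out = classes.copy()
    out["date"] = pd.to_datetime(out["date"])
    long_events = events.loc[events["duration_hours"] >= 8]
    start_days = pd.DataFrame(
        {
            "county_id": long_events["county_id"],
            "date": pd.to_datetime(long_events["start_hour"]).dt.normalize(),
        }
    ).drop_duplicates()
    keyed = set(zip(out["county_id"], out["date"]))
    known = [
        (c, d) in keyed for c, d in zip(start_days["county_id"], start_days["date"])
    ]
    n_unknown = len(known) - int(np.sum(known))
    if n_unknown:
        logger.warning(
            "align_outage_days: %d outage start days outside the calendar", n_unknown
        )
    marked = set(
        zip(start_days.loc[known, "county_id"], start_days.loc[known, "date"])
    )
    out["outage_start"] = [
        (c, d) in marked for c, d in zip(out["county_id"], out["date"])
    ]
    return out


def co_occurrence_ratio(
    n_outage_i: int, n_days_i: int, n_outage_none: int, n_days_none: int
) -> float:
    """Co-occurrence ratio of an event category against no-event days.

    ``(n_outage_i / n_days_i) / (n_outage_none / n_days_none)``.  Raises
    :class:`UndefinedRatioError` when any denominator is zero (distinct from
    a ratio of 0, which is a valid value).
    """
    if n_days_i <= 0 or n_days_none <= 0 or n_outage_none <= 0:
        raise UndefinedRatioError(
            "co-occurrence ratio undefined: zero denominator "
            f"(n_days_i={n_days_i}, n_days_none={n_days_none}, "
            f"n_outage_none={n_outage_none})"
        )
    return (n_outage_i / n_days_i) / (n_outage_none / n_days_none)


def build_cooccurrence_table(classes: pd.DataFrame, other_rank: int = 7) -> pd.DataFrame:
    """County-day co-occurrence table over an aligned, classified calendar.

    Rows: Total, None, Isolated (with one row per event type), Multiple
    (with the ``other_rank`` most common combinations by outage county-days
    plus an aggregated Other row).  Columns carry county-day and outage
    county-day counts, their within-table percentages, and the co-occurrence
    ratio against the None row.
    """
    if "outage_start" not in classes.columns:
        raise ValueError("classes must be aligned first (missing outage_start)")
    total_days = len(classes)
    total_out = int(classes["outage_start"].sum())
    none_days = int((classes["level"] == "none").sum())
    none_out = int(classes.loc[classes["level"] == "none", "outage_start"].sum())

    rows: list[dict] = [
        _row("Total", "total", total_days, total_out),
        _row("None", "none", none_days, none_out),
    ]

    iso = classes.loc[classes["level"] == "isolated"]
    rows.append(_row("Isolated event", "isolated", len(iso), int(iso["outage_start"].sum())))
    for t in EVENT_TYPES:
        sub = iso.loc[iso[t] == 1]
        rows.append(
            _row(ISOLATED_LABELS[t], "isolated_type", len(sub), int(sub["outage_start"].sum()))
        )

    multi = classes.loc[classes["level"] == "multiple"]
    rows.append(_row("Multiple event", "multiple", len(multi), int(multi["outage_start"].sum())))
    combo = (
        multi.groupby("category", observed=True)
        .agg(n_days=("outage_start", "size"), n_out=("outage_start", "sum"))
        .sort_values(["n_out", "n_days"], ascending=False)
    )
    top = combo.head(other_rank)
    for label, r in top.iterrows():
        rows.append(_row(label, "multiple_combo", int(r["n_days"]), int(r["n_out"])))
    rest = combo.iloc[len(top):]
    rows.append(_row("Other", "multiple_combo", int(rest["n_days"].sum()), int(rest["n_out"].sum())))

    table = pd.DataFrame(rows)
    table["pct_county_days"] = 100.0 * table["n_county_days"] / total_days if total_days else np.nan
    table["pct_outage_days"] = (
        100.0 * table["n_outage_days"] / total_out if total_out else np.nan
    )
    ratios = []
    for _, r in table.iterrows():
        if r["rowlevel"] in ("total", "none"):
            ratios.append(np.nan)
            continue
        try:
            ratios.append(
                co_occurrence_ratio(r["n_outage_days"], r["n_county_days"], none_out, none_days)
            )
        except UndefinedRatioError:
            ratios.append(np.nan)
    table["ratio"] = ratios
    return table


def _row(category: str, level: str, n_days: int, n_out: int) -> dict:
    return {
        "category": category,
        "rowlevel": level,
        "n_county_days": n_days,
        "n_outage_days": n_out,
    }


def monthly_event_composition(classes: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Monthly category mix of outage county-days, isolated vs multiple.

    For county-days on which an 8+ hour outage began, counts and within-month
    proportions per category, separately for isolated and multiple levels.
    Months with no outage county-days in a panel are simply absent.
    """
    if "outage_start" not in classes.columns:
        raise ValueError("classes must be aligned first (missing outage_start)")
    out: dict[str, pd.DataFrame] = {}
    hit = classes.loc[classes["outage_start"]]
    for level in ("isolated", "multiple"):
        sub = hit.loc[hit["level"] == level].copy()
        if sub.empty:
            out[level] = pd.DataFrame(columns=["month", "category", "count", "proportion"])
            continue
        sub["month"] = pd.to_datetime(sub["date"]).dt.month
        counts = (
            sub.groupby(["month", "category"], observed=True)
            .size()
            .rename("count")
            .reset_index()
        )
        totals = counts.groupby("month")["count"].transform("sum")
        counts["proportion"] = counts["count"] / totals
        out[level] = counts
    return out
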
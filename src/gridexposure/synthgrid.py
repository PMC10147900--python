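"""Synthetic county grids, outage feeds, weather calendars and vulnerability surfaces.

A lattice "world" of counties stands in for real geography: adjacency is
explicit, every planted signal (outage events, feed gaps, weather coupling,
vulnerability clusters) is recorded in a :class:`GroundTruth` object, and
regeneration from the same seed is bit-for-bit reproducible.  One master
seed feeds a hierarchy of per-purpose, per-county substreams
(``numpy.random.SeedSequence``) so individual pieces can be regenerated
independently.

The outage feed emulates a commercial 10-minute county outage product:

* a sub-threshold noise floor (uniform counts below 0.05% of customers) so
  percentile-based threshold derivation sees a realistic distribution,
* planted events whose fraction of customers out is at or above the 0.1%
  detection threshold for their whole duration,
* an evening onset peak (default mean 18:00 local, roughly 15:00-20:00),
* missingness: i.i.d. dropped 10-minute slots, or contiguous block gaps of
  the feed itself,
* optional coupling to a daily weather calendar: the probability that a
  long (8+ hour) event starts on a county-day is multiplied by the relative
  risk of each event type active that day.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from math import ceil

import numpy as np
import pandas as pd

from .climate import EVENT_TYPES

SLOTS_PER_DAY = 144  # 10-minute resolution
SLOTS_PER_HOUR = 6

DEFAULT_DURATIONS = {
    "p_long": 0.3,            # share of events drawn from the long (8+ h) range
    "short_hours": (1, 7),    # inclusive integer-hour range for short events
    "long_hours": (8, 24),
}
DEFAULT_ONSET = {"mean_hour": 18.0, "sd_hours": 1.5}
DEFAULT_BASE_RATES = {
    "precip": 0.15,
    "snow": 0.04,
    "heat": 0.08,
    "cold": 0.04,
    "wildfire": 0.01,
    "lightning": 0.02,
    "cyclone": 0.005,
}

# Weather value ranges used to realize flags as physical values.  The
# climatology baselines are flat so that the classification rules reduce to
# the intended flag with probability one.
_BASE_TEMP_P85 = 22.0
_BASE_TEMP_P15 = -2.0
_BASE_PRECIP_P85 = 20.0

# Loosely realistic (mean at svi=0, slope per unit svi, sd) for the 16
# census-derived vulnerability components, in percent of population.
SVI_COMPONENTS = {
    "below_150_poverty": (12.0, 25.0, 6.0),
    "unemployed": (4.0, 6.0, 2.0),
    "housing_cost_burden": (20.0, 15.0, 6.0),
    "no_high_school_diploma": (8.0, 15.0, 5.0),
    "no_health_insurance": (6.0, 12.0, 4.0),
    "age_65_plus": (16.0, 6.0, 4.0),
    "age_17_under": (21.0, 4.0, 3.0),
    "disability": (13.0, 8.0, 4.0),
    "single_parent": (6.0, 8.0, 3.0),
    "limited_english": (2.0, 8.0, 3.0),
    "racial_ethnic_minority": (15.0, 30.0, 10.0),
    "multi_unit_structures": (8.0, 10.0, 5.0),
    "mobile_homes": (6.0, 16.0, 5.0),
    "crowding": (2.0, 5.0, 2.0),
    "no_vehicle": (5.0, 7.0, 3.0),
    "group_quarters": (2.0, 3.0, 1.5),
}


@dataclass
class GroundTruth:
    """Record of everything the generator planted, for parameter recovery."""

    planted_events: list[dict] = field(default_factory=list)
    event_rate_per_county_day: float = 0.0
    weather_relative_risks: dict = field(default_factory=dict)
    reporting_gap_fraction: float = 0.0
    vulnerability_cluster_counties: list[str] = field(default_factory=list)
    seed: int = 0
    n_merged_events: int = 0

    def __post_init__(self) -> None:
        for ev in self.planted_events:
            if ev["duration_hours"] <= 0:
                raise ValueError("planted event with non-positive duration")
            if "peak_fraction_out" not in ev:
                raise ValueError("planted event without recorded peak_fraction_out")
        if any(v < 0 for v in self.weather_relative_risks.values()):
            raise ValueError("weather relative risks must be >= 0")

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))

    def events_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.planted_events)
        if not df.empty:
            df["start_time"] = pd.to_datetime(df["start_time"])
        return df


def generate_registry(
    n_rows: int,
    n_cols: int,
    customer_range: tuple[int, int] = (5_000, 200_000),
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, dict[str, list[str]]]]:
    """Counties on an ``n_rows`` x ``n_cols`` lattice plus contiguity lists.

    Customer totals are drawn uniformly from ``customer_range`` and split
    into households and businesses.  UTC offsets vary by column band (west
    of the lattice is further from UTC), fixed per county with no
    daylight-saving modeling.

    Returns the registry table and ``{"rook": .., "queen": ..}`` adjacency
    mappings (county_id -> neighbor ids).
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("lattice dimensions must be >= 1")
    lo, hi = customer_range
    if lo <= 0 or hi < lo:
        raise ValueError("customer_range must be a positive interval")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    n = n_rows * n_cols
    rows, cols = np.divmod(np.arange(n), n_cols)
    total = rng.integers(lo, hi + 1, size=n)
    hh_share = rng.uniform(0.75, 0.9, size=n)
    households = np.floor(total * hh_share).astype(int)
    businesses = total - households
    # 4 longitude bands spanning offsets -5 .. -8
    offset = -5 - np.minimum((cols * 4) // max(n_cols, 1), 3)
    registry = pd.DataFrame(
        {
            "county_id": [f"{i + 1:05d}" for i in range(n)],
            "state_id": [f"S{(r // 4) * 16 + (c // 4):02d}" for r, c in zip(rows, cols)],
            "households": households,
            "businesses": businesses,
            "customers_total": total,
            "grid_row": rows,
            "grid_col": cols,
            "utc_offset_hours": offset,
        }
    )
    adjacency = {
        scheme: lattice_adjacency(registry, scheme) for scheme in ("rook", "queen")
    }
    return registry, adjacency


def lattice_adjacency(registry: pd.DataFrame, scheme: str = "queen") -> dict[str, list[str]]:
    """Contiguity lists on the lattice; rook = edge-sharing, queen = +diagonals."""
    if scheme not in ("rook", "queen"):
        raise ValueError(f"unknown contiguity scheme: {scheme}")
    pos = {
        (int(r), int(c)): cid
        for cid, r, c in zip(
            registry["county_id"], registry["grid_row"], registry["grid_col"]
        )
    }
    if len(pos) != len(registry):
        raise ValueError("lattice coordinates must be unique per county")
    steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if scheme == "queen":
        steps += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    adj: dict[str, list[str]] = {}
    for (r, c), cid in pos.items():
        adj[cid] = sorted(
            pos[(r + dr, c + dc)] for dr, dc in steps if (r + dr, c + dc) in pos
        )
    return adj


def _normalize_span(span: tuple[str, str]) -> pd.DatetimeIndex:
    start, end = pd.Timestamp(span[0]), pd.Timestamp(span[1])
    if end < start:
        raise ValueError("span end before start")
    return pd.date_range(start, end, freq="D")


def generate_outage_streams(
    registry: pd.DataFrame,
    span: tuple[str, str] = ("2018-01-01", "2018-12-31"),
    daily_event_rate: float = 0.05,
    duration_distribution: dict | None = None,
    onset_distribution: dict | None = None,
    gap_fraction: float = 0.0,
    seed: int = 0,
    calendar_flags: pd.DataFrame | None = None,
    relative_risks: dict[str, float] | None = None,
    county_rate_multiplier: dict[str, float] | None = None,
    county_coverage: dict[str, float] | None = None,
    county_gap_fraction: dict[str, float] | None = None,
    noise_floor_frac: float = 0.0005,
    event_fraction_range: tuple[float, float] = (0.002, 0.05),
    block_gaps: bool = False,
    return_streams: bool = True,
) -> tuple[pd.DataFrame | None, GroundTruth]:
    """10-minute outage feeds for every county plus the planted ground truth.

    Event starts are Bernoulli per county-day: short events (duration below
    8 h) at rate ``daily_event_rate * (1 - p_long)``, long (8+ h) events at
    rate ``daily_event_rate * p_long`` multiplied — when ``calendar_flags``
    and ``relative_risks`` are given — by the relative risk of every event
    type flagged on that county-day.  Onset hours follow a discretized
    normal distribution on the local clock; durations are integer hours
    drawn uniformly from the short or long range.  Overlapping or touching
    events within a county are merged and the merge recorded.

    Timestamps in the emitted stream are UTC; event times in the truth
    record are local clock (the registry's fixed offset maps between them).
    With ``return_streams=False`` only the :class:`GroundTruth` is built
    (identical to the one returned with streams, by substream separation).
    """
    if not 0 <= gap_fraction < 1:
        raise ValueError("gap_fraction must be in [0, 1)")
    if daily_event_rate < 0:
        raise ValueError("daily_event_rate must be >= 0")
    durations = {**DEFAULT_DURATIONS, **(duration_distribution or {})}
    onset = {**DEFAULT_ONSET, **(onset_distribution or {})}
    if durations["long_hours"][0] < 8:
        raise ValueError("long-event durations must be >= 8 hours")
    relative_risks = dict(relative_risks or {})
    if any(v < 0 for v in relative_risks.values()):
        raise ValueError("relative risks must be >= 0")

    days = _normalize_span(span)
    n_days = len(days)
    n_slots = n_days * SLOTS_PER_DAY
    times_local = days[0] + pd.to_timedelta(np.arange(n_slots) * 10, unit="min")

    flag_lookup: dict[str, np.ndarray] | None = None
    if calendar_flags is not None and relative_risks:
        flag_lookup = _daily_rr(calendar_flags, days, relative_risks)

    ss = np.random.SeedSequence([seed, 202])
    county_seeds = ss.spawn(len(registry))
    truth_events: list[dict] = []
    n_merged = 0
    frames: list[pd.DataFrame] = []

    for entry, cs in zip(registry.itertuples(index=False), county_seeds):
        cid = entry.county_id
        total = int(entry.customers_total)
        ss_events, ss_noise, ss_gaps = cs.spawn(3)
        rng_e = np.random.default_rng(ss_events)

        mult = (county_rate_multiplier or {}).get(cid, 1.0)
        p_long = daily_event_rate * durations["p_long"] * mult
        p_short = daily_event_rate * (1.0 - durations["p_long"]) * mult
        rr_day = np.ones(n_days)
        if flag_lookup is not None and cid in flag_lookup:
            rr_day = flag_lookup[cid]
        long_start = rng_e.random(n_days) < np.clip(p_long * rr_day, 0.0, 1.0)
        short_start = rng_e.random(n_days) < min(p_short, 1.0)

        events = []  # (start_slot, end_slot, peak_frac, kind)
        for day_idx in np.flatnonzero(long_start | short_start):
            for kind, hit in (("long", long_start[day_idx]), ("short", short_start[day_idx])):
                if not hit:
                    continue
                hour = int(round(rng_e.normal(onset["mean_hour"], onset["sd_hours"]))) % 24
                lo, hi = durations[f"{kind}_hours"]
                dur_h = int(rng_e.integers(lo, hi + 1))
                peak = float(rng_e.uniform(*event_fraction_range))
                s = day_idx * SLOTS_PER_DAY + hour * SLOTS_PER_HOUR
                events.append((s, s + dur_h * SLOTS_PER_HOUR, peak, kind))

        merged, merges = _merge_events(events)
        n_merged += merges
        for s, e, peak, kind in merged:
            truth_events.append(
                {
                    "county_id": cid,
                    "start_time": str(times_local[s]) if s < n_slots else str(
                        days[0] + pd.Timedelta(minutes=10 * s)
                    ),
                    "duration_hours": (min(e, n_slots) - s) / SLOTS_PER_HOUR,
                    "peak_fraction_out": peak,
                    "kind": kind,
                }
            )

        if not return_streams:
            continue

        noise_max = int(np.floor(noise_floor_frac * total))
        rng_n = np.random.default_rng(ss_noise)
        out = rng_n.integers(0, noise_max + 1, size=n_slots).astype(np.int64)
        for s, e, peak, _ in merged:
            val = max(ceil(peak * total), ceil(0.001 * total))
            out[s : min(e, n_slots)] = val

        gap_c = (county_gap_fraction or {}).get(cid, gap_fraction)
        rng_g = np.random.default_rng(ss_gaps)
        keep = _gap_mask(rng_g, n_slots, gap_c, block_gaps)

        coverage = (county_coverage or {}).get(cid, 1.0)
        tracked = int(round(coverage * total))
        offset = pd.Timedelta(hours=int(entry.utc_offset_hours))
        frames.append(
            pd.DataFrame(
                {
                    "county_id": cid,
                    "timestamp": times_local[keep] - offset,
                    "customers_out": out[keep],
                    "customers_tracked": tracked,
                }
            )
        )

    truth = GroundTruth(
        planted_events=truth_events,
        event_rate_per_county_day=daily_event_rate,
        weather_relative_risks=relative_risks,
        reporting_gap_fraction=gap_fraction,
        seed=seed,
        n_merged_events=n_merged,
    )
    if not return_streams:
        return None, truth
    if frames:
        stream = pd.concat(frames, ignore_index=True)
    else:
        stream = pd.DataFrame(
            columns=["county_id", "timestamp", "customers_out", "customers_tracked"]
        )
    return stream, truth


def _merge_events(events: list[tuple]) -> tuple[list[tuple], int]:
    """Merge overlapping or touching [start, end) slot intervals per county."""
    if not events:
        return [], 0
    events = sorted(events, key=lambda t: t[0])
    merged = [list(events[0])]
    n_merges = 0
    for s, e, peak, kind in events[1:]:
        last = merged[-1]
        if s <= last[1]:  # overlap or touching -> one contiguous run
            last[1] = max(last[1], e)
            last[2] = max(last[2], peak)
            if (last[1] - last[0]) >= 8 * SLOTS_PER_HOUR:
                last[3] = "long"
            n_merges += 1
        else:
            merged.append([s, e, peak, kind])
    return [tuple(m) for m in merged], n_merges


def _gap_mask(rng, n_slots: int, gap_fraction: float, block_gaps: bool) -> np.ndarray:
    """Boolean keep-mask over slots; True = the feed reported that slot."""
    if gap_fraction <= 0:
        return np.ones(n_slots, dtype=bool)
    if not block_gaps:
        return rng.random(n_slots) >= gap_fraction
    keep = np.ones(n_slots, dtype=bool)
    target = int(gap_fraction * n_slots)
    removed = 0
    while removed < target:
        start = int(rng.integers(0, n_slots))
        length = int(rng.geometric(1.0 / 18.0))  # mean 3 h of dead feed
        stop = min(start + length, n_slots)
        removed += int(keep[start:stop].sum())
        keep[start:stop] = False
    return keep


def _daily_rr(
    calendar_flags: pd.DataFrame, days: pd.DatetimeIndex, rr: dict[str, float]
) -> dict[str, np.ndarray]:
    """Per-county daily relative-risk multipliers from a flag calendar."""
    cal = calendar_flags.copy()
    cal["date"] = pd.to_datetime(cal["date"])
    day_pos = {d: i for i, d in enumerate(days)}
    out: dict[str, np.ndarray] = {}
    for cid, sub in cal.groupby("county_id", observed=True, sort=False):
        mult = np.ones(len(days))
        idx = sub["date"].map(day_pos)
        ok = idx.notna()
        positions = idx[ok].astype(int).to_numpy()
        for t, r in rr.items():
            if t in sub.columns and r != 1.0:
                flagged = sub.loc[ok, t].to_numpy() > 0
                mult[positions[flagged]] *= r
        out[str(cid)] = mult
    return out


def generate_weather_calendar(
    registry: pd.DataFrame,
    span: tuple[str, str] = ("2018-01-01", "2018-12-31"),
    base_rates: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Daily weather values, climatology baselines and the implied flags.

    Flags are drawn Bernoulli per county-day at ``base_rates`` (heat and
    cold compete for the single daily temperature, so they are drawn from
    one categorical and never co-occur; heavy precipitation is suppressed on
    snowfall days, matching the classifier's default precedence).  Physical
    values are then realized so that the classification rules reproduce the
    drawn flags exactly: the returned flag table is the ground truth for
    classification tests.

    Returns ``(weather, baselines, flags)``.
    """
    rates = {**DEFAULT_BASE_RATES, **(base_rates or {})}
    unknown = set(rates) - set(EVENT_TYPES)
    if unknown:
        raise ValueError(f"unknown event types in base_rates: {sorted(unknown)}")
    if any(not 0 <= v <= 1 for v in rates.values()):
        raise ValueError("base rates must be in [0, 1]")
    if rates["heat"] + rates["cold"] > 1:
        raise ValueError("heat + cold rates cannot exceed 1")

    days = _normalize_span(span)
    n_days = len(days)
    ss = np.random.SeedSequence([seed, 303])
    county_seeds = ss.spawn(len(registry))

    weeks = days.isocalendar().week.astype(int).to_numpy()
    weather_frames, flag_frames, base_rows = [], [], []
    for entry, cs in zip(registry.itertuples(index=False), county_seeds):
        cid = entry.county_id
        rng = np.random.default_rng(cs)
        u = rng.random(n_days)
        heat = u < rates["heat"]
        cold = (u >= rates["heat"]) & (u < rates["heat"] + rates["cold"])
        snow = rng.random(n_days) < rates["snow"]
        precip_raw = rng.random(n_days) < rates["precip"]
        precip = precip_raw & ~snow
        lightning = rng.random(n_days) < rates["lightning"]
        cyclone = rng.random(n_days) < rates["cyclone"]
        wildfire = rng.random(n_days) < rates["wildfire"]

        temp = rng.uniform(3.0, 18.0, n_days)
        temp[heat] = rng.uniform(25.0, 35.0, int(heat.sum()))
        temp[cold] = rng.uniform(-12.0, -3.0, int(cold.sum()))
        precip_mm = rng.uniform(0.0, 15.0, n_days)
        precip_mm[precip_raw] = rng.uniform(25.0, 60.0, int(precip_raw.sum()))
        snowfall = np.zeros(n_days)
        snowfall[snow] = rng.uniform(3.0, 30.0, int(snow.sum()))
        cyc_km = rng.uniform(150.0, 2000.0, n_days)
        cyc_km[cyclone] = rng.uniform(5.0, 95.0, int(cyclone.sum()))
        fire = np.zeros(n_days)
        fire[wildfire] = rng.uniform(1.5, 50.0, int(wildfire.sum()))

        weather_frames.append(
            pd.DataFrame(
                {
                    "county_id": cid,
                    "date": days,
                    "temp_c": temp,
                    "precip_mm": precip_mm,
                    "snowfall_cm": snowfall,
                    "lightning_flash": lightning.astype(np.int8),
                    "cyclone_distance_km": cyc_km,
                    "wildfire_area_km2": fire,
                }
            )
        )
        flag_frames.append(
            pd.DataFrame(
                {
                    "county_id": cid,
                    "date": days,
                    "heat": heat.astype(np.int8),
                    "cold": cold.astype(np.int8),
                    "precip": precip.astype(np.int8),
                    "snow": snow.astype(np.int8),
                    "lightning": lightning.astype(np.int8),
                    "cyclone": cyclone.astype(np.int8),
                    "wildfire": wildfire.astype(np.int8),
                }
            )
        )
        for wk in np.unique(weeks):
            base_rows.append(
                {
                    "county_id": cid,
                    "week": int(wk),
                    "temp_p85_c": _BASE_TEMP_P85,
                    "temp_p15_c": _BASE_TEMP_P15,
                    "precip_p85_mm": _BASE_PRECIP_P85,
                }
            )

    weather = pd.concat(weather_frames, ignore_index=True)
    flags = pd.concat(flag_frames, ignore_index=True)
    baselines = pd.DataFrame(base_rows)
    return weather, baselines, flags


def generate_vulnerability_surface(
    registry: pd.DataFrame,
    cluster_spec: dict | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """SVI index + 16 components and DME prevalence, with an optional planted cluster.

    ``cluster_spec`` keys: ``region`` = (row_lo, row_hi, col_lo, col_hi)
    inclusive lattice bounds, ``svi_shift`` (added to the SVI of counties in
    the region, clipped to [0, 1]), ``dme_shift`` (added per 1000 Medicare
    enrollees) and ``outage_rate_multiplier`` (returned in the truth dict
    for the outage generator).  Returns the vulnerability table and a truth
    dict with the planted cluster membership and the per-county outage rate
    multiplier map.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    n = len(registry)
    svi = rng.uniform(0.0, 1.0, n)
    dme = rng.gamma(shape=9.0, scale=6.5, size=n)

    in_region = np.zeros(n, dtype=bool)
    multiplier = 1.0
    if cluster_spec is not None:
        r0, r1, c0, c1 = cluster_spec["region"]
        rows = registry["grid_row"].to_numpy()
        cols = registry["grid_col"].to_numpy()
        if r0 < 0 or c0 < 0 or r1 >= rows.max() + 1 or c1 >= cols.max() + 1:
            raise ValueError("cluster region outside the lattice")
        in_region = (rows >= r0) & (rows <= r1) & (cols >= c0) & (cols <= c1)
        svi = np.clip(svi + cluster_spec.get("svi_shift", 0.0) * in_region, 0.0, 1.0)
        dme = dme + cluster_spec.get("dme_shift", 0.0) * in_region
        multiplier = float(cluster_spec.get("outage_rate_multiplier", 1.0))
        if (
            cluster_spec.get("svi_shift", 0.0) == 0
            and cluster_spec.get("dme_shift", 0.0) == 0
            and multiplier == 1.0
        ):
            in_region[:] = False  # nothing planted, so nothing to recover
    dme = np.clip(dme, 0.0, 1000.0)

    table = pd.DataFrame({"county_id": registry["county_id"], "svi": svi})
    for name, (base, slope, sd) in SVI_COMPONENTS.items():
        table[name] = np.clip(rng.normal(base + slope * svi, sd), 0.0, 100.0)
    table["dme_per_1000"] = dme

    cluster_ids = registry.loc[in_region, "county_id"].tolist()
    truth = {
        "vulnerability_cluster_counties": cluster_ids,
        "outage_rate_multiplier": {cid: multiplier for cid in cluster_ids},
    }
    return table, truth


def simulate_outage_counts(
    registry: pd.DataFrame,
    base_annual_rate: float = 2.0,
    rate_multiplier: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.Series:
    """Annual 8+ hour outage counts per county, Poisson at the county level.

    A county-level shortcut for spatial-clustering simulations where the
    quantity of interest is the per-county annual event count rather than
    the 10-minute feed itself.
    """
    if base_annual_rate < 0:
        raise ValueError("base_annual_rate must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 505]))
    mult = registry["county_id"].map(rate_multiplier or {}).fillna(1.0).to_numpy()
    counts = rng.poisson(base_annual_rate * mult)
    return pd.Series(counts, index=registry["county_id"].to_numpy(), name="n_events_8h")
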
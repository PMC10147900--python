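"""Reliability screening of county outage feeds and study-tier assignment.

A county-year is *reliable* when the feed reported in at least 50% of the
expected 10-minute slots of that (local) calendar year AND the customers it
tracked covered at least 50% of the county's total customers.  Counties are
then tiered by how many reliable years they have (1+, 2+, all years of the
span); each analysis stage of the pipeline consumes the tier it needs.

Both thresholds are inclusive at exactly 0.5.  The coverage numerator is
the maximum simultaneous customers the feed tracked (a conservative proxy);
when the stream carries no ``customers_tracked`` column, coverage is
treated as complete.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass

import numpy as np
import pandas as pd

SLOTS_PER_DAY = 144

REPORTING_THRESHOLD = 0.5
COVERAGE_THRESHOLD = 0.5


def expected_slots(year: int) -> int:
    """Expected 10-minute slots in a calendar year (leap-aware)."""
    return (366 if calendar.isleap(year) else 365) * SLOTS_PER_DAY


def assess_reliability(
    stream: pd.DataFrame, registry_entry, year: int
) -> dict:
    """Reliability assessment of one county's feed for one local calendar year.

    ``registry_entry`` is a mapping/Series with ``county_id``,
    ``customers_total`` and ``utc_offset_hours``.  Stream timestamps are
    UTC; the county's fixed offset maps them onto the local clock before
    slot counting.
    """
    total = int(registry_entry["customers_total"])
    if total <= 0:
        raise ValueError(
            f"invalid denominator: customers_total={total} for "
            f"{registry_entry['county_id']}"
        )
    ts = pd.to_datetime(stream["timestamp"]) + pd.Timedelta(
        hours=int(registry_entry["utc_offset_hours"])
    )
    in_year = ts.dt.year == year
    slots = ts[in_year].dt.floor("10min")
    reporting = slots.nunique() / expected_slots(year)

    if "customers_tracked" in stream.columns and in_year.any():
        tracked = float(stream.loc[in_year, "customers_tracked"].max())
        coverage = min(tracked / total, 1.0)
    else:
        coverage = 1.0 if in_year.any() else 0.0
    return {
        "county_id": registry_entry["county_id"],
        "year": int(year),
        "reporting_fraction": float(min(reporting, 1.0)),
        "coverage_fraction": float(coverage),
        "reliable": bool(
            reporting >= REPORTING_THRESHOLD and coverage >= COVERAGE_THRESHOLD
        ),
    }


def assess_all(
    streams: pd.DataFrame, registry: pd.DataFrame, years: list[int]
) -> pd.DataFrame:
    """Assessment table over every county in the registry and every year.

    Counties with no readings at all in a year get reporting_fraction 0 for
    that year (and are therefore unreliable in it).
    """
    reg = registry.set_index("county_id")
    rows = []
    grouped = dict(tuple(streams.groupby("county_id", observed=True)))
    empty = streams.iloc[0:0]
    for cid, entry in reg.iterrows():
        sub = grouped.get(cid, empty)
        e = {"county_id": cid, **entry.to_dict()}
        for year in years:
            rows.append(assess_reliability(sub, e, year))
    return pd.DataFrame(rows)


@dataclass
class StudyTiers:
    """Per-county reliable-year counts and nested tier memberships."""

    table: pd.DataFrame  # county_id, years_reliable, tier booleans
    span_years: int

    @property
    def tier_1plus(self) -> set[str]:
        return set(self.table.loc[self.table["tier_1plus"], "county_id"])

    @property
    def tier_2plus(self) -> set[str]:
        return set(self.table.loc[self.table["tier_2plus"], "county_id"])

    @property
    def tier_full(self) -> set[str]:
        return set(self.table.loc[self.table["tier_full"], "county_id"])

    def members(self, tier: str) -> set[str]:
        key = {"1plus": "tier_1plus", "2plus": "tier_2plus", "3y": "tier_full",
               "full": "tier_full"}[tier]
        return set(self.table.loc[self.table[key], "county_id"])

    def reliable_years(self) -> dict[str, list[int]]:
        return self._reliable_years

    def __post_init__(self) -> None:
        # Nesting full ⊆ 2+ ⊆ 1+ (the full tier only nests under 2+ when the
        # span itself has at least 2 years).
        assert self.tier_2plus <= self.tier_1plus
        if self.span_years >= 2:
            assert self.tier_full <= self.tier_2plus


def assign_tiers(assessments: pd.DataFrame, span_years: int | None = None) -> StudyTiers:
    """Tier counties by reliable-year count; 0-reliable-year counties drop out.

    ``span_years`` defaults to the number of distinct years assessed; the
    full tier requires every span year to be reliable.
    """
    dup = assessments.duplicated(subset=["county_id", "year"])
    if dup.any():
        raise ValueError("duplicate county-year assessments")
    if span_years is None:
        span_years = assessments["year"].nunique()
    assessments = assessments.assign(reliable=assessments["reliable"].astype(bool))
    per_county = (
        assessments.groupby("county_id", observed=True)["reliable"]
        .sum()
        .astype(int)
        .rename("years_reliable")
        .reset_index()
    )
    per_county = per_county.loc[per_county["years_reliable"] > 0].copy()
    per_county["tier_1plus"] = per_county["years_reliable"] >= 1
    per_county["tier_2plus"] = per_county["years_reliable"] >= 2
    per_county["tier_full"] = per_county["years_reliable"] >= span_years
    tiers = StudyTiers(per_county.reset_index(drop=True), span_years)
    rel = assessments.loc[assessments["reliable"]]
    tiers._reliable_years = {
        cid: sorted(sub["year"].tolist())
        for cid, sub in rel.groupby("county_id", observed=True)
    }
    return tiers
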
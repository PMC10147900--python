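"""Configuration, validated table I/O and end-to-end pipeline orchestration.

Stages: simulate -> screen -> detect -> cooccur -> cluster -> report.  Every
stage is a pure function of (inputs, config, seed); re-running with the same
config byte-reproduces every output.  All artifacts are plain CSV (UTF-8,
ISO-8601 timestamps, canonical column order) plus a JSON truth record and a
JSON run manifest (config hash, seed, versions, row counts).
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, climate, exposure, reliability, synthgrid, vulnerability

logger = logging.getLogger(__name__)

TIERS = ("1plus", "2plus", "3y")


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    n_rows: int = 6
    n_cols: int = 6
    span_start: str = "2018-01-01"
    span_end: str = "2020-12-31"
    seed: int = 0
    threshold: float = exposure.DEFAULT_THRESHOLD
    min_durations: tuple[int, int] = (1, 8)
    other_rank: int = 7
    permutations: int = 999
    alpha: float = 0.05
    tier_cooccur: str = "3y"
    tier_vulnerability: str = "2plus"
    daily_event_rate: float = 0.05
    gap_fraction: float = 0.0
    base_rates: dict = field(default_factory=dict)
    coupling: dict = field(default_factory=dict)
    cluster_spec: dict | None = None
    contiguity: str = "queen"

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        for name in ("tier_cooccur", "tier_vulnerability"):
            if getattr(self, name) not in TIERS:
                raise ValueError(f"{name} must be one of {TIERS}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        self.min_durations = tuple(self.min_durations)

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            return cls(**tomllib.load(fh))

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @property
    def years(self) -> list[int]:
        return list(
            range(pd.Timestamp(self.span_start).year, pd.Timestamp(self.span_end).year + 1)
        )


# ---------------------------------------------------------------------------
# validated table I/O

def _nonneg(col):
    def check(df):
        bad = df.index[df[col] < 0]
        if len(bad):
            raise ValueError(f"negative {col} at row {bad[0]}")
    return check


def _binary(cols):
    def check(df):
        for c in cols:
            bad = df.index[~df[c].isin([0, 1])]
            if len(bad):
                raise ValueError(f"non-binary {c} at row {bad[0]}")
    return check


def _unit_interval(col):
    def check(df):
        bad = df.index[(df[col] < 0) | (df[col] > 1)]
        if len(bad):
            raise ValueError(f"{col} outside [0, 1] at row {bad[0]}")
    return check


SCHEMAS: dict[str, dict] = {
    "registry": {
        "required": [
            "county_id", "state_id", "households", "businesses",
            "customers_total", "grid_row", "grid_col", "utc_offset_hours",
        ],
        "strings": ["county_id", "state_id"],
        "checks": [_nonneg("households"), _nonneg("businesses")],
    },
    "stream": {
        "required": ["county_id", "timestamp", "customers_out"],
        "optional": ["customers_tracked"],
        "strings": ["county_id"],
        "datetimes": ["timestamp"],
        "checks": [_nonneg("customers_out")],
    },
    "weather": {
        "required": [
            "county_id", "date", "temp_c", "precip_mm", "snowfall_cm",
            "lightning_flash", "cyclone_distance_km", "wildfire_area_km2",
        ],
        "strings": ["county_id"],
        "datetimes": ["date"],
        "checks": [_binary(["lightning_flash"]), _nonneg("precip_mm")],
    },
    "flags": {
        "required": ["county_id", "date"] + ["heat", "cold", "precip", "snow",
                                             "lightning", "cyclone", "wildfire"],
        "strings": ["county_id"],
        "datetimes": ["date"],
        "checks": [_binary(["heat", "cold", "precip", "snow", "lightning",
                            "cyclone", "wildfire"])],
    },
    "baselines": {
        "required": ["county_id", "week", "temp_p85_c", "temp_p15_c", "precip_p85_mm"],
        "strings": ["county_id"],
        "checks": [],
    },
    "vulnerability": {
        "required": ["county_id", "svi"] + list(synthgrid.SVI_COMPONENTS) + ["dme_per_1000"],
        "strings": ["county_id"],
        "checks": [_unit_interval("svi")],
    },
    "assessment": {
        "required": ["county_id", "year", "reporting_fraction",
                     "coverage_fraction", "reliable"],
        "strings": ["county_id"],
        "checks": [_unit_interval("reporting_fraction"), _unit_interval("coverage_fraction")],
    },
    "tiers": {
        "required": ["county_id", "years_reliable", "tier_1plus", "tier_2plus", "tier_full"],
        "strings": ["county_id"],
        "checks": [],
    },
    "events": {
        "required": ["county_id", "start_hour", "duration_hours",
                     "peak_customers_out", "event_customer_hours"],
        "strings": ["county_id"],
        "datetimes": ["start_hour"],
        "checks": [_nonneg("duration_hours")],
    },
    "summary": {
        "required": ["county_id", "year", "n_events_1h", "n_events_8h"],
        "optional": ["customer_hours_total", "hours_per_customer"],
        "strings": ["county_id"],
        "checks": [_nonneg("n_events_1h"), _nonneg("n_events_8h")],
    },
    "cooccurrence": {
        "required": ["category", "rowlevel", "n_county_days", "n_outage_days",
                     "pct_county_days", "pct_outage_days", "ratio"],
        "strings": ["category", "rowlevel"],
        "checks": [_nonneg("n_county_days")],
    },
    "lisa": {
        "required": ["county_id", "local_stat", "pseudo_p",
                     "fdr_significant", "cluster_label"],
        "optional": ["lag", "quadrant"],
        "strings": ["county_id", "cluster_label"],
        "checks": [_unit_interval("pseudo_p")],
    },
}


def read_table(name: str, path) -> pd.DataFrame:
    """Read and validate a named CSV schema; fail with the offending row."""
    schema = SCHEMAS[name]
    df = pd.read_csv(path, dtype={c: str for c in schema.get("strings", [])})
    missing = [c for c in schema["required"] if c not in df.columns]
    if missing:
        raise ValueError(f"{name} table at {path} missing columns {missing}")
    known = set(schema["required"]) | set(schema.get("optional", []))
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        logger.warning("%s table: ignoring unknown columns %s", name, unknown)
    for c in schema.get("datetimes", []):
        df[c] = pd.to_datetime(df[c])
    for check in schema["checks"]:
        check(df)
    return df


def write_table(df: pd.DataFrame, name: str, path) -> None:
    """Write a named table in canonical column order (UTF-8, ISO-8601)."""
    schema = SCHEMAS[name]
    cols = [c for c in schema["required"] if c in df.columns]
    cols += [c for c in schema.get("optional", []) if c in df.columns]
    missing = [c for c in schema["required"] if c not in df.columns]
    if missing:
        raise ValueError(f"cannot write {name}: missing columns {missing}")
    df[cols].to_csv(path, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# pipeline

def run_pipeline(config: PipelineConfig) -> dict:
    """Run simulate -> screen -> detect -> cooccur -> cluster -> report.

    Returns the run manifest (also written to ``manifest.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    span = (config.span_start, config.span_end)
    counts: dict[str, int] = {}

    # --- simulate ---------------------------------------------------------
    registry, adjacency = synthgrid.generate_registry(
        config.n_rows, config.n_cols, seed=config.seed
    )
    weather, baselines, flags = synthgrid.generate_weather_calendar(
        registry, span, base_rates=config.base_rates or None, seed=config.seed
    )
    vuln, vuln_truth = synthgrid.generate_vulnerability_surface(
        registry, cluster_spec=config.cluster_spec, seed=config.seed
    )
    stream, truth = synthgrid.generate_outage_streams(
        registry,
        span,
        daily_event_rate=config.daily_event_rate,
        gap_fraction=config.gap_fraction,
        seed=config.seed,
        calendar_flags=flags if config.coupling else None,
        relative_risks=config.coupling or None,
        county_rate_multiplier=vuln_truth["outage_rate_multiplier"] or None,
    )
    truth.vulnerability_cluster_counties = vuln_truth["vulnerability_cluster_counties"]
    write_table(registry, "registry", out / "registry.csv")
    write_table(stream, "stream", out / "stream.csv")
    write_table(weather, "weather", out / "weather.csv")
    write_table(flags, "flags", out / "flags.csv")
    write_table(baselines, "baselines", out / "baselines.csv")
    write_table(vuln, "vulnerability", out / "vulnerability.csv")
    truth.to_json(out / "truth.json")
    counts["counties"] = len(registry)
    counts["stream_rows"] = len(stream)
    logger.info("simulate: %d counties, %d stream rows", len(registry), len(stream))

    # --- screen -----------------------------------------------------------
    assessments = reliability.assess_all(stream, registry, config.years)
    tiers = reliability.assign_tiers(assessments, span_years=len(config.years))
    write_table(assessments, "assessment", out / "assessment.csv")
    write_table(tiers.table, "tiers", out / "tiers.csv")
    counts["counties_reliable_1plus"] = len(tiers.tier_1plus)
    logger.info(
        "screen: %d/%d counties with 1+ reliable years",
        len(tiers.tier_1plus), len(registry),
    )

    # --- detect -----------------------------------------------------------
    hourly = exposure.aggregate_to_hourly(stream, registry, span=span)
    events = exposure.detect_outage_events(hourly, registry, config.threshold)
    per_cy, per_county = exposure.summarize_events(
        events, registry, tiers.reliable_years(), hourly=hourly,
        min_durations=config.min_durations,
    )
    write_table(events, "events", out / "events.csv")
    write_table(per_cy, "summary", out / "summary.csv")
    per_county.to_csv(out / "summary_county.csv", index=False)
    start_matrix = exposure.tabulate_start_times(events, config.min_durations[1])
    start_matrix.to_csv(out / "start_times.csv")
    counts["events"] = len(events)
    logger.info("detect: %d events in %d reliable county-years", len(events), len(per_cy))

    # --- cooccur ----------------------------------------------------------
    tier_ids = tiers.members(config.tier_cooccur)
    if not tier_ids:
        raise ValueError(
            f"cooccur stage: tier {config.tier_cooccur!r} has no counties "
            f"(span {config.span_start}..{config.span_end})"
        )
    classes = climate.classify_county_days(weather, baselines)
    classes = classes.loc[classes["county_id"].isin(tier_ids)]
    aligned = climate.align_outage_days(
        events.loc[events["county_id"].isin(tier_ids)], classes
    )
    table = climate.build_cooccurrence_table(aligned, other_rank=config.other_rank)
    write_table(table, "cooccurrence", out / "cooccurrence.csv")
    composition = climate.monthly_event_composition(aligned)
    for level, comp in composition.items():
        comp.to_csv(out / f"composition_{level}.csv", index=False)
    counts["county_days"] = len(aligned)
    logger.info(
        "cooccur: %d county-days in tier %s, %d outage county-days",
        len(aligned), config.tier_cooccur, int(aligned["outage_start"].sum()),
    )

    # --- cluster ----------------------------------------------------------
    tier_v = tiers.members(config.tier_vulnerability)
    if not tier_v:
        raise ValueError(
            f"cluster stage: tier {config.tier_vulnerability!r} has no counties "
            f"(span {config.span_start}..{config.span_end})"
        )
    adj = {
        i: [j for j in nbrs if j in tier_v]
        for i, nbrs in adjacency[config.contiguity].items()
        if i in tier_v
    }
    w = vulnerability.build_spatial_weights(adj)
    avg8 = per_county.set_index("county_id")["avg_n_events_8h"]
    y = avg8.reindex(w.ids).fillna(0.0).to_numpy()
    lisa_out = {}
    for metric, col in (("svi", "svi"), ("dme", "dme_per_1000")):
        x = vuln.set_index("county_id")[col].reindex(w.ids).to_numpy()
        lisa = vulnerability.bivariate_local_moran(
            x, y, w, n_permutations=config.permutations, seed=config.seed
        )
        lisa = vulnerability.fdr_classify_clusters(lisa, alpha=config.alpha)
        write_table(lisa, "lisa", out / f"lisa_{metric}.csv")
        lisa_out[metric] = lisa
        counts[f"high_high_{metric}"] = int(
            (lisa["cluster_label"] == "high-high").sum()
        )
    hh = set(lisa_out["svi"].loc[lisa_out["svi"]["cluster_label"] == "high-high",
                                 "county_id"])
    if hh and len(hh) < len(vuln):
        contrasts = vulnerability.compare_svi_components(
            vuln, hh, list(synthgrid.SVI_COMPONENTS)
        )
        contrasts.to_csv(out / "svi_component_contrasts.csv", index=False)
    logger.info("cluster: %d high-high SVI counties", counts["high_high_svi"])

    # --- report -----------------------------------------------------------
    manifest = report(config, out, counts)
    return manifest


def report(config: PipelineConfig, out: Path, counts: dict) -> dict:
    """Regenerate ratio summaries from stored intermediates + run manifest."""
    table = read_table("cooccurrence", out / "cooccurrence.csv")
    none = table.loc[table["rowlevel"] == "none"].iloc[0]
    recomputed = []
    for _, r in table.iterrows():
        if r["rowlevel"] in ("total", "none"):
            recomputed.append(float("nan"))
        else:
            try:
                recomputed.append(
                    climate.co_occurrence_ratio(
                        r["n_outage_days"], r["n_county_days"],
                        none["n_outage_days"], none["n_county_days"],
                    )
                )
            except climate.UndefinedRatioError:
                recomputed.append(float("nan"))
    table["ratio"] = recomputed
    write_table(table, "cooccurrence", out / "cooccurrence_report.csv")

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": asdict(config),
        "config_hash": config.digest(),
        "seed": config.seed,
        "row_counts": counts,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
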
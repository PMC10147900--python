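"""Exposure metrics: hourly aggregation, detection vs run-enumeration oracle,
threshold behavior, customer-hours integration, planted-event recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gridexposure import exposure, synthgrid

from conftest import hourly_from_binary, make_registry, single_county_registry


def enumerate_runs(above):
    """Brute-force maximal-run enumeration over a binary sequence."""
    runs, start = [], None
    for i, a in enumerate(above):
        if a and start is None:
            start = i
        elif not a and start is not None:
            runs.append((start, i - start))
            start = None
    if start is not None:
        runs.append((start, len(above) - start))
    return runs


class TestDenominator:
    @pytest.mark.parametrize(
        "hh,biz,total", [(80_000, 20_000, 100_000), (0, 0, 0), (123, 0, 123)]
    )
    def test_sum(self, hh, biz, total):
        assert exposure.estimate_customer_denominator(hh, biz) == total

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            exposure.estimate_customer_denominator(-1, 5)


class TestHourlyAggregation:
    def _stream(self, values, start="2018-01-01 00:00"):
        ts = pd.date_range(start, periods=len(values), freq="10min")
        return pd.DataFrame(
            {"county_id": "00001", "timestamp": ts, "customers_out": values}
        )

    def test_constant_hour(self):
        hourly = exposure.aggregate_to_hourly(
            self._stream([120] * 6), single_county_registry()
        )
        assert hourly["customers_out_max"].iloc[0] == 120
        assert hourly["customers_out_mean"].iloc[0] == 120

    def test_single_spike_mean_is_equal_weight(self):
        hourly = exposure.aggregate_to_hourly(
            self._stream([0, 0, 0, 600, 0, 0]), single_county_registry()
        )
        assert hourly["customers_out_max"].iloc[0] == 600
        assert hourly["customers_out_mean"].iloc[0] == pytest.approx(100.0)

    def test_empty_hour_flagged_unreported(self):
        stream = self._stream([50] * 6)
        later = stream.copy()
        later["timestamp"] = later["timestamp"] + pd.Timedelta(hours=2)
        hourly = exposure.aggregate_to_hourly(
            pd.concat([stream, later]), single_county_registry()
        )
        assert hourly["reported"].tolist() == [True, False, True]
        assert np.isnan(hourly["customers_out_max"].iloc[1])

    def test_negative_reading_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            exposure.aggregate_to_hourly(
                self._stream([5, -1, 2]), single_county_registry()
            )

    def test_local_clock_offset_applied(self):
        reg = single_county_registry(offset=-6)
        hourly = exposure.aggregate_to_hourly(self._stream([10] * 6), reg)
        assert hourly["hour_start"].iloc[0] == pd.Timestamp("2017-12-31 18:00")


class TestThreshold:
    def test_constant_series(self):
        assert exposure.derive_threshold([0.0005] * 20) == 0.0005

    def test_percentile_matches_sorted_list_oracle(self):
        vals = [0.0001] * 9 + [0.01]
        # linear interpolation on sorted order statistics at rank 0.9*(n-1)
        srt = sorted(vals)
        pos = 0.9 * (len(srt) - 1)
        lo = int(np.floor(pos))
        oracle = srt[lo] + (pos - lo) * (srt[lo + 1] - srt[lo])
        assert exposure.derive_threshold(vals) == pytest.approx(oracle)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            exposure.derive_threshold([])

    def test_default_study_threshold(self):
        assert exposure.DEFAULT_THRESHOLD == 0.001


class TestDetection:
    def test_hundred_of_hundred_thousand_qualifies(self):
        hourly = hourly_from_binary([0, 1, 1, 0])
        hourly.loc[hourly["customers_out_max"] > 0, "customers_out_max"] = 100
        events = exposure.detect_outage_events(
            hourly, single_county_registry(100_000), 0.001
        )
        assert len(events) == 1
        assert events["duration_hours"].iloc[0] == 2

    def test_999_of_a_million_does_not_qualify(self):
        reg = single_county_registry(1_000_000)
        hours = pd.date_range("2018-01-01", periods=4, freq="h")
        hourly = pd.DataFrame(
            {
                "county_id": "00001",
                "hour_start": hours,
                "customers_out_max": [0, 999, 1000, 0],
                "customers_out_mean": [0, 999, 1000, 0],
                "n_reports": 6,
                "reported": True,
            }
        )
        events = exposure.detect_outage_events(hourly, reg, 0.001)
        assert len(events) == 1
        assert events["duration_hours"].iloc[0] == 1  # only the 1000-out hour

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_run_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        above = rng.random(300) < 0.3
        events = exposure.detect_outage_events(
            hourly_from_binary(above), single_county_registry(), 0.001
        )
        runs = enumerate_runs(above)
        assert len(events) == len(runs)
        assert events["duration_hours"].tolist() == [d for _, d in runs]

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.booleans(), min_size=1, max_size=120))
    def test_oracle_equivalence_property(self, above):
        events = exposure.detect_outage_events(
            hourly_from_binary(above), single_county_registry(), 0.001
        )
        assert events["duration_hours"].tolist() == [
            d for _, d in enumerate_runs(above)
        ]

    def test_unreported_hour_breaks_run(self):
        hourly = hourly_from_binary([1, 1, 1, 1])
        hourly.loc[1, "reported"] = False
        events = exposure.detect_outage_events(
            hourly, single_county_registry(), 0.001
        )
        assert events["duration_hours"].tolist() == [1, 2]

    def test_threshold_monotonicity_on_plateau_events(self):
        """For plateau-shaped outage events (noise floor below, event level
        above), raising the threshold never increases event counts or any
        event's duration."""
        registry, _ = make_registry(3, 3, customers=80_000, seed=6)
        stream, _ = synthgrid.generate_outage_streams(
            registry, ("2018-01-01", "2018-06-30"), 0.1, seed=7
        )
        hourly = exposure.aggregate_to_hourly(stream, registry)
        prev = None
        for thr in (0.001, 0.005, 0.02, 0.04):
            ev = exposure.detect_outage_events(hourly, registry, thr)
            n1 = int((ev["duration_hours"] >= 1).sum())
            n8 = int((ev["duration_hours"] >= 8).sum())
            tot = int(ev["duration_hours"].sum())
            if prev is not None:
                assert n1 <= prev[0] and n8 <= prev[1] and tot <= prev[2]
            prev = (n1, n8, tot)

    def test_threshold_monotonicity_of_total_hours_any_series(self):
        """On arbitrary series the total above-threshold time is monotone in
        the threshold even when runs split."""
        rng = np.random.default_rng(3)
        hours = pd.date_range("2018-01-01", periods=400, freq="h")
        out = rng.integers(0, 400, size=400)
        hourly = pd.DataFrame(
            {
                "county_id": "00001",
                "hour_start": hours,
                "customers_out_max": out.astype(float),
                "customers_out_mean": out.astype(float),
                "n_reports": 6,
                "reported": True,
            }
        )
        reg = single_county_registry()
        prev = None
        for thr in (0.0005, 0.001, 0.002, 0.003):
            ev = exposure.detect_outage_events(hourly, reg, thr)
            tot = int(ev["duration_hours"].sum())
            if prev is not None:
                assert tot <= prev
            prev = tot


class TestCustomerHours:
    def test_sum_of_hourly_means(self):
        hourly = hourly_from_binary([1, 1, 0])
        hourly["customers_out_mean"] = [100.0, 200.0, 0.0]
        total = exposure.compute_customer_hours(hourly)
        assert total.iloc[0] == 300.0

    def test_per_customer(self):
        assert exposure.hours_per_customer(1_000_000, 10_000) == 100.0
        with pytest.raises(ValueError):
            exposure.hours_per_customer(10, 0)

    def test_rectangle_integration_oracle(self):
        """Constant c customers out for H hours of 10-minute readings
        integrates to exactly c*H customer-hours."""
        c, H = 750, 12
        ts = pd.date_range("2018-01-01", periods=H * 6, freq="10min")
        stream = pd.DataFrame(
            {"county_id": "00001", "timestamp": ts, "customers_out": c}
        )
        hourly = exposure.aggregate_to_hourly(stream, single_county_registry())
        assert exposure.compute_customer_hours(hourly).iloc[0] == c * H

    def test_event_hours_conserved_under_total(self):
        registry, _ = make_registry(2, 2, seed=2)
        stream, _ = synthgrid.generate_outage_streams(
            registry, ("2018-01-01", "2018-03-31"), 0.1, seed=3
        )
        hourly = exposure.aggregate_to_hourly(stream, registry)
        events = exposure.detect_outage_events(hourly, registry, 0.001)
        totals = exposure.compute_customer_hours(hourly)
        for cid, sub in events.groupby("county_id"):
            assert sub["event_customer_hours"].sum() <= totals[cid].sum() + 1e-9


class TestSummaries:
    def test_duration_classes_and_annual_average(self):
        events = pd.DataFrame(
            {
                "county_id": ["A"] * 6,
                "start_hour": pd.to_datetime(
                    ["2018-02-01", "2018-03-01", "2018-07-01",
                     "2019-02-01", "2019-03-01", "2019-04-01"]
                ),
                "duration_hours": [1, 9, 3, 1, 1, 2],
                "peak_customers_out": 100,
                "event_customer_hours": 100.0,
            }
        )
        registry = single_county_registry(county_id="A")
        per_cy, per_county = exposure.summarize_events(
            events, registry, {"A": [2018, 2019]}
        )
        assert per_cy.set_index("year")["n_events_1h"].to_dict() == {2018: 3, 2019: 3}
        assert per_cy.set_index("year")["n_events_8h"].to_dict() == {2018: 1, 2019: 0}
        assert per_county["avg_n_events_1h"].iloc[0] == 3.0
        assert per_county["avg_n_events_8h"].iloc[0] == 0.5

    def test_two_year_totals_average(self):
        events = pd.DataFrame(
            {
                "county_id": ["A"] * 6,
                "start_hour": pd.to_datetime(
                    ["2018-01-01"] * 4 + ["2019-01-01"] * 2
                ),
                "duration_hours": [2] * 6,
                "peak_customers_out": 100,
                "event_customer_hours": 10.0,
            }
        )
        registry = single_county_registry(county_id="A")
        _, per_county = exposure.summarize_events(
            events, registry, {"A": [2018, 2019]}
        )
        assert per_county["avg_n_events_1h"].iloc[0] == 3.0  # (4 + 2) / 2

    def test_zero_reliable_years_excluded(self):
        events = pd.DataFrame(
            {
                "county_id": ["A"],
                "start_hour": [pd.Timestamp("2018-01-01")],
                "duration_hours": [2],
                "peak_customers_out": [100],
                "event_customer_hours": [10.0],
            }
        )
        registry = single_county_registry(county_id="A")
        per_cy, per_county = exposure.summarize_events(events, registry, {"A": []})
        assert per_cy.empty and per_county.empty


class TestStartTimes:
    def test_single_event_single_cell(self):
        events = pd.DataFrame(
            {
                "county_id": ["A"],
                "start_hour": [pd.Timestamp("2018-06-15 18:00")],
                "duration_hours": [10],
            }
        )
        mat = exposure.tabulate_start_times(events)
        assert mat.loc[6, 18] == 1
        assert mat.to_numpy().sum() == 1

    def test_empty_events_zero_matrix(self):
        mat = exposure.tabulate_start_times(
            pd.DataFrame(columns=["county_id", "start_hour", "duration_hours"])
        )
        assert mat.shape == (12, 24)
        assert mat.to_numpy().sum() == 0

    def test_onset_mode_recovered_from_generator(self):
        registry, _ = make_registry(4, 4, seed=8)
        _, truth = synthgrid.generate_outage_streams(
            registry, ("2018-01-01", "2018-12-31"), 0.3, seed=12,
            return_streams=False,
        )
        ev = truth.events_frame()
        ev = ev.rename(columns={"start_time": "start_hour"})
        mat = exposure.tabulate_start_times(ev, min_duration=8)
        hour_totals = mat.sum(axis=0)
        assert hour_totals.idxmax() == 18
        assert mat.to_numpy().sum() == (ev["duration_hours"] >= 8).sum()


class TestPlantedRecovery:
    def test_exact_recovery_without_gaps(self):
        """Zero reporting gaps + sub-threshold noise: detected events match
        the planted truth in count, start hour and duration exactly."""
        registry, _ = make_registry(3, 3, customers=50_000, offset=-5, seed=10)
        stream, truth = synthgrid.generate_outage_streams(
            registry, ("2018-01-01", "2018-06-30"), 0.08, seed=44
        )
        hourly = exposure.aggregate_to_hourly(stream, registry)
        detected = exposure.detect_outage_events(hourly, registry, 0.001)
        planted = truth.events_frame().sort_values(["county_id", "start_time"])
        detected = detected.sort_values(["county_id", "start_hour"])
        assert len(detected) == len(planted)
        assert detected["start_hour"].tolist() == planted["start_time"].tolist()
        assert detected["duration_hours"].tolist() == planted["duration_hours"].tolist()

    def test_block_gaps_never_lengthen_events(self):
        registry, _ = make_registry(2, 2, customers=50_000, seed=10)
        stream, truth = synthgrid.generate_outage_streams(
            registry, ("2018-01-01", "2018-03-31"), 0.1,
            gap_fraction=0.2, block_gaps=True, seed=45,
        )
        hourly = exposure.aggregate_to_hourly(stream, registry)
        detected = exposure.detect_outage_events(hourly, registry, 0.001)
        planted = truth.events_frame()
        for ev in detected.itertuples():
            mine = planted.loc[planted["county_id"] == ev.county_id]
            covering = mine.loc[
                (mine["start_time"] <= ev.start_hour)
                & (
                    mine["start_time"]
                    + pd.to_timedelta(mine["duration_hours"], unit="h")
                    > ev.start_hour
                )
            ]
            assert len(covering) == 1
            assert ev.duration_hours <= covering["duration_hours"].iloc[0]
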
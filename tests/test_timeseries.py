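"""Containers, CSV round-trips, deduplication, lag alignment and IQR."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aircausal import (
    EnvSeries,
    VisitSeries,
    compute_iqr,
    deduplicate_visits,
    lag_align,
    read_env_csv,
    read_visits_csv,
)
from aircausal.timeseries import TimeSeriesError


def _env(days, **columns):
    idx = pd.DatetimeIndex(pd.to_datetime(days))
    return EnvSeries(pd.DataFrame(columns, index=idx))


def _visits(days, counts):
    idx = pd.DatetimeIndex(pd.to_datetime(days))
    return VisitSeries(pd.Series(counts, index=idx))


class TestCsvRoundTrip:
    def test_env_round_trip_preserves_values(self, tmp_path):
        days = ["2014-01-01", "2014-01-02", "2014-01-03"]
        env = _env(days, so2=[1.5, 2.25, 3.125], no2=[0.1, 0.2, 0.3])
        path = tmp_path / "env.csv"
        env.to_csv(path)
        back = read_env_csv(path)
        assert back.data.equals(env.data)

    def test_visits_round_trip(self, tmp_path):
        visits = _visits(["2014-01-01", "2014-01-02"], [3, 7])
        path = tmp_path / "v.csv"
        visits.to_csv(path)
        assert read_visits_csv(path).counts.equals(visits.counts)

    def test_invalid_date_reports_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("date,so2\n2014-01-01,1.0\n2014-02-30,2.0\n")
        with pytest.raises(TimeSeriesError, match="2014-02-30"):
            read_env_csv(path)

    def test_duplicated_date_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("date,so2\n2014-01-01,1.0\n2014-01-01,2.0\n")
        with pytest.raises(TimeSeriesError, match="duplicated"):
            read_env_csv(path)

    def test_missing_cell_reports_position(self, tmp_path):
        path = tmp_path / "gap.csv"
        path.write_text("date,so2,no2\n2014-01-01,1.0,2.0\n2014-01-02,,3.0\n")
        with pytest.raises(TimeSeriesError, match="so2"):
            read_env_csv(path)

    def test_calendar_gap_is_listed_not_fatal(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("date,so2\n2014-01-01,1.0\n2014-01-03,2.0\n")
        env = read_env_csv(path)
        assert env.gaps() == [pd.Timestamp("2014-01-02")]


class TestDeduplicateVisits:
    @staticmethod
    def _records(patient_days):
        rows = [
            {"patient_id": pid, "visit_date": pd.Timestamp(2014, 1, day), "age": 5.0, "sex": "M"}
            for pid, days in patient_days.items()
            for day in days
        ]
        return pd.DataFrame(rows)

    def test_window_rule_hand_trace(self):
        records = self._records({"A": [1, 1, 3, 10]})
        kept = deduplicate_visits(records, followup_window_days=7)
        assert list(kept["visit_date"].dt.day) == [1, 10]

    def test_zero_window_removes_same_day_only(self):
        records = self._records({"A": [1, 1, 2]})
        kept = deduplicate_visits(records, followup_window_days=0)
        assert list(kept["visit_date"].dt.day) == [1, 2]

    def test_patients_deduplicated_independently(self):
        records = self._records({"A": [1, 3], "B": [1, 3]})
        kept = deduplicate_visits(records, followup_window_days=7)
        assert (kept["visit_date"].dt.day == 1).sum() == 2
        assert len(kept) == 2

    def test_idempotent(self):
        records = self._records({"A": [1, 1, 3, 10, 12, 25], "B": [2, 5, 9]})
        once = deduplicate_visits(records, 7)
        twice = deduplicate_visits(once, 7)
        pd.testing.assert_frame_equal(once, twice)

    def test_negative_window_rejected(self):
        with pytest.raises(TimeSeriesError):
            deduplicate_visits(self._records({"A": [1]}), -1)


class TestLagAlign:
    def test_lag0_is_date_intersection(self):
        days = pd.date_range("2014-01-01", periods=5, freq="D")
        env = _env(days, x=np.arange(5.0))
        visits = _visits(days[1:], [1, 2, 3, 4])
        table = lag_align(env, visits, 0)
        assert list(table.index) == list(days[1:])
        assert list(table["x"]) == [1.0, 2.0, 3.0, 4.0]

    def test_row_count_shrinks_by_lag(self):
        days = pd.date_range("2014-01-01", periods=10, freq="D")
        env = _env(days, x=np.arange(10.0))
        visits = _visits(days, np.ones(10, dtype=int))
        assert len(lag_align(env, visits, 6)) == 4

    def test_exposure_column_is_shifted(self):
        days = pd.date_range("2014-01-01", periods=10, freq="D")
        env = _env(days, x=np.arange(1.0, 11.0))
        visits = _visits(days, np.full(10, 2))
        table = lag_align(env, visits, 3)
        assert list(table["x"]) == [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]

    def test_lagged_column_consistent_with_lag0_shift(self, small_sim):
        _, env, visits = small_sim
        t0 = lag_align(env, visits, 0)
        t3 = lag_align(env, visits, 3)
        np.testing.assert_allclose(
            t3["so2"].to_numpy(), t0["so2"].to_numpy()[:-3]
        )

    def test_gap_splits_alignment_segments(self):
        days = list(pd.date_range("2014-01-01", periods=4, freq="D")) + list(
            pd.date_range("2014-02-01", periods=4, freq="D")
        )
        env = _env(days, x=np.arange(8.0))
        visits = _visits(days, np.ones(8, dtype=int))
        table = lag_align(env, visits, 2)
        # two segments of 4 days each contribute 2 rows apiece; no row pairs
        # an exposure across the gap
        assert len(table) == 4
        assert list(table["x"]) == [0.0, 1.0, 4.0, 5.0]

    def test_empty_overlap_and_excess_lag_rejected(self):
        env = _env(pd.date_range("2014-01-01", periods=3), x=[1.0, 2.0, 3.0])
        far = _visits(pd.date_range("2015-01-01", periods=3), [1, 1, 1])
        with pytest.raises(TimeSeriesError):
            lag_align(env, far, 0)
        near = _visits(pd.date_range("2014-01-01", periods=3), [1, 1, 1])
        with pytest.raises(TimeSeriesError):
            lag_align(env, near, 3)


class TestIqr:
    def test_uniform_grid_closed_form(self):
        assert compute_iqr(np.arange(1.0, 101.0)) == pytest.approx(49.5)

    def test_constant_vector_is_zero(self):
        assert compute_iqr([5.0, 5.0, 5.0, 5.0]) == 0.0

    def test_too_few_values_rejected(self):
        with pytest.raises(TimeSeriesError):
            compute_iqr([1.0, 2.0, 3.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        values=st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False), min_size=4, max_size=40
        ),
        a=st.floats(min_value=-100, max_value=100, allow_nan=False),
        b=st.floats(min_value=-1e3, max_value=1e3, allow_nan=False),
    )
    def test_affine_equivariance(self, values, a, b):
        base = compute_iqr(values)
        scaled = compute_iqr([a * v + b for v in values])
        assert scaled == pytest.approx(abs(a) * base, rel=1e-7, abs=1e-3)


def test_visit_series_rejects_negative_and_fractional_counts():
    days = pd.date_range("2014-01-01", periods=2)
    with pytest.raises(TimeSeriesError):
        VisitSeries(pd.Series([1, -1], index=days))
    with pytest.raises(TimeSeriesError):
        VisitSeries(pd.Series([1.0, 2.5], index=days))
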
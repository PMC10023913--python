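"""Date-indexed containers, visit deduplication, lag alignment and IQR.

The analysis pairs a matrix of daily environmental measurements (meteorology
and air pollutants) with a daily count of hospital visits.  Exposure on day
``t - k`` is paired with the outcome on day ``t`` ("lag k"), the standard
epidemiologic convention in which the exposure precedes the outcome.

Everything here is thin plumbing over :mod:`pandas`: the containers validate
the invariants the downstream statistics rely on (strictly increasing dates,
non-negative integer counts) and the alignment logic is careful never to pair
days across a gap in the calendar.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EnvSeries",
    "VisitSeries",
    "read_env_csv",
    "read_visits_csv",
    "read_patient_csv",
    "write_patient_csv",
    "deduplicate_visits",
    "lag_align",
    "compute_iqr",
    "TimeSeriesError",
]


class TimeSeriesError(ValueError):
    """Malformed series, file or alignment request."""


def _check_dates(index: pd.DatetimeIndex, context: str) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()][0]
        raise TimeSeriesError(f"{context}: duplicated date {dup.date()}")
    if not index.is_monotonic_increasing:
        raise TimeSeriesError(f"{context}: dates must be strictly increasing")


def _calendar_gaps(index: pd.DatetimeIndex) -> list[pd.Timestamp]:
    if len(index) == 0:
        return []
    full = pd.date_range(index[0], index[-1], freq="D")
    return list(full.difference(index))


@dataclass
class EnvSeries:
    """Daily environmental variables: one row per calendar day.

    Parameters
    ----------
    data
        DataFrame indexed by a ``DatetimeIndex`` of daily dates, one float
        column per environmental variable.
    units
        Optional map from variable name to unit string (``μg/m³``, ``hPa`` ...).
        Variables without an entry carry an empty unit tag.
    """

    data: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.data.index, pd.DatetimeIndex):
            self.data = self.data.copy()
            self.data.index = pd.DatetimeIndex(self.data.index)
        _check_dates(self.data.index, "EnvSeries")
        if self.data.columns.has_duplicates:
            raise TimeSeriesError("EnvSeries: duplicated variable names")

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.data.index

    def gaps(self) -> list[pd.Timestamp]:
        """Calendar days missing between the first and last date."""
        return _calendar_gaps(self.data.index)

    def unit_of(self, variable: str) -> str:
        return self.units.get(variable, "")

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "date", out.index.strftime("%Y-%m-%d"))
        out.to_csv(path, index=False)


@dataclass
class VisitSeries:
    """Daily visit counts (non-negative integers) on a date index."""

    counts: pd.Series

    def __post_init__(self) -> None:
        if not isinstance(self.counts.index, pd.DatetimeIndex):
            self.counts = self.counts.copy()
            self.counts.index = pd.DatetimeIndex(self.counts.index)
        _check_dates(self.counts.index, "VisitSeries")
        values = np.asarray(self.counts.values)
        if np.any(values < 0):
            raise TimeSeriesError("VisitSeries: counts must be non-negative")
        if not np.allclose(values, np.round(values)):
            raise TimeSeriesError("VisitSeries: counts must be integral")
        self.counts = self.counts.astype(np.int64)
        self.counts.name = "visits"

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.counts.index

    def gaps(self) -> list[pd.Timestamp]:
        return _calendar_gaps(self.counts.index)

    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path) -> None:
        out = pd.DataFrame(
            {"date": self.counts.index.strftime("%Y-%m-%d"), "visits": self.counts.values}
        )
        out.to_csv(path, index=False)


def _parse_dates(raw: pd.Series, path) -> pd.DatetimeIndex:
    parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.values)[0])
        # +2: one for the header line, one for 1-based numbering
        raise TimeSeriesError(
            f"{path}: unparseable date {raw.iloc[row]!r} on line {row + 2}"
        )
    return pd.DatetimeIndex(parsed)


def read_env_csv(path, units: dict[str, str] | None = None) -> EnvSeries:
    """Load an environmental series from CSV (``date`` column + one per variable)."""
    frame = pd.read_csv(path)
    if "date" not in frame.columns:
        raise TimeSeriesError(f"{path}: missing required 'date' column")
    index = _parse_dates(frame["date"], path)
    data = frame.drop(columns=["date"]).astype(float)
    data.index = index
    missing = data.isna()
    if missing.any().any():
        r, c = np.argwhere(missing.values)[0]
        raise TimeSeriesError(
            f"{path}: missing value at row {int(r) + 2}, column {data.columns[c]!r}"
        )
    return EnvSeries(data, units=dict(units or {}))


def read_visits_csv(path) -> VisitSeries:
    frame = pd.read_csv(path)
    for col in ("date", "visits"):
        if col not in frame.columns:
            raise TimeSeriesError(f"{path}: missing required {col!r} column")
    index = _parse_dates(frame["date"], path)
    counts = pd.Series(frame["visits"].values, index=index, name="visits")
    return VisitSeries(counts)


PATIENT_COLUMNS = ["patient_id", "visit_date", "age", "sex"]


def read_patient_csv(path) -> pd.DataFrame:
    """Load patient-level visit records (patient_id, visit_date, age, sex)."""
    frame = pd.read_csv(path)
    for col in PATIENT_COLUMNS:
        if col not in frame.columns:
            raise TimeSeriesError(f"{path}: missing required {col!r} column")
    frame = frame[PATIENT_COLUMNS].copy()
    frame["visit_date"] = pd.DatetimeIndex(_parse_dates(frame["visit_date"], path))
    bad_sex = ~frame["sex"].isin(["M", "F"])
    if bad_sex.any():
        raise TimeSeriesError(f"{path}: sex must be 'M' or 'F'")
    return frame


def write_patient_csv(records: pd.DataFrame, path) -> None:
    out = records.copy()
    out["visit_date"] = pd.DatetimeIndex(out["visit_date"]).strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def deduplicate_visits(records: pd.DataFrame, followup_window_days: int = 7) -> pd.DataFrame:
    """Collapse repeat and follow-up visits to index visits per patient.

    Per patient: visits on the same day collapse to one record, and any visit
    falling within ``followup_window_days`` days after the last retained index
    visit is dropped as a scheduled follow-up.  The first visit after the
    window closes starts a new index visit.  With a window of 0 only same-day
    duplicates are removed.  Chronological order is preserved.
    """
    if followup_window_days < 0:
        raise TimeSeriesError("followup_window_days must be non-negative")
    if records.empty:
        return records.copy()
    frame = records.reset_index(drop=True).copy()
    frame["visit_date"] = pd.DatetimeIndex(frame["visit_date"])
    frame = frame.sort_values(["visit_date", "patient_id"], kind="stable")
    keep_idx: list[int] = []
    for _, grp in frame.groupby("patient_id", sort=False):
        grp = grp.drop_duplicates(subset="visit_date", keep="first")
        last_index_day: pd.Timestamp | None = None
        for idx, day in zip(grp.index, grp["visit_date"]):
            if (
                last_index_day is None
                or (day - last_index_day).days > followup_window_days
            ):
                keep_idx.append(idx)
                last_index_day = day
    kept = frame.loc[keep_idx]
    return kept.sort_values(["visit_date", "patient_id"], kind="stable").reset_index(drop=True)


def _contiguous_runs(index: pd.DatetimeIndex) -> list[pd.DatetimeIndex]:
    if len(index) == 0:
        return []
    day = pd.Timedelta(days=1)
    breaks = np.flatnonzero(np.diff(index.values) != day.to_timedelta64()) + 1
    pieces = np.split(np.arange(len(index)), breaks)
    return [index[p] for p in pieces]


def lag_align(env: EnvSeries, visits: VisitSeries, lag: int) -> pd.DataFrame:
    """Pair the outcome on day ``t`` with every exposure on day ``t - lag``.

    Returns a DataFrame indexed by the outcome day with a ``visits`` column
    and one column per environmental variable holding its value ``lag`` days
    earlier.  Gaps in the shared calendar split the series into contiguous
    segments that are aligned independently, so no row ever pairs days that
    are not exactly ``lag`` apart.
    """
    if lag < 0:
        raise TimeSeriesError("lag must be non-negative")
    overlap = env.dates.intersection(visits.dates)
    if len(overlap) == 0:
        raise TimeSeriesError("lag_align: no overlapping dates")
    span = max(len(run) for run in _contiguous_runs(overlap))
    if lag >= span:
        raise TimeSeriesError(
            f"lag_align: lag {lag} exceeds longest contiguous overlap ({span} days)"
        )
    pieces = []
    for run in _contiguous_runs(overlap):
        if lag >= len(run):
            continue
        outcome_days = run[lag:]
        exposure_days = run[: len(run) - lag]
        block = env.data.loc[exposure_days].copy()
        block.index = outcome_days
        block.insert(0, "visits", visits.counts.loc[outcome_days].values)
        pieces.append(block)
    return pd.concat(pieces)


def compute_iqr(values: Sequence[float] | np.ndarray) -> float:
    """Interquartile range Q3 − Q1, linear interpolation between order statistics."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 4:
        raise TimeSeriesError("compute_iqr requires at least 4 finite values")
    q1, q3 = np.percentile(arr, [25.0, 75.0])
    return float(q3 - q1)
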
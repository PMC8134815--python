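"""Daily-case time series I/O and smoothing.

Reads and writes the wide CSV dialect used by the OWID/JHU surveillance
exports (a ``date`` column followed by one column per country/region)
and computes the trailing 7-day moving average conventionally overlaid
on daily new-case curves.

The in-memory currency is :class:`CaseSeries`: a contiguous daily grid
of raw counts plus an optional smoothed companion of identical length.
Raw counts may contain missing values (reporting gaps) and negative
entries (retroactive corrections); smoothing clamps negatives to zero
and skips missing days so the smoothed curve stays non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CaseSeries", "load_case_series", "moving_average", "write_case_series"]


@dataclass(frozen=True)
class CaseSeries:
    """A daily new-case series for one region.

    Parameters
    ----------
    region
        Column label the series was read from (or will be written to).
    dates
        Contiguous daily ``DatetimeIndex``; exactly one entry per day.
    raw
        Daily new-case counts (persons/day). ``NaN`` marks missing
        reports; negative values are retroactive corrections and are
        kept as-is.
    smoothed
        Optional moving-average companion, same length as ``raw``.
    """

    region: str
    dates: pd.DatetimeIndex
    raw: np.ndarray
    smoothed: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.region:
            raise ValueError("region label must be a non-empty string")
        dates = pd.DatetimeIndex(self.dates)
        raw = np.asarray(self.raw, dtype=float)
        if len(dates) != len(raw):
            raise ValueError(f"dates ({len(dates)}) and raw ({len(raw)}) differ in length")
        if len(dates) == 0:
            raise ValueError("series must contain at least one day")
        deltas = np.diff(dates.values.astype("datetime64[D]").astype(int))
        if len(deltas) and not np.all(deltas == 1):
            raise ValueError("dates must be strictly increasing with a step of one day")
        if self.smoothed is not None:
            smoothed = np.asarray(self.smoothed, dtype=float)
            if len(smoothed) != len(raw):
                raise ValueError("smoothed must have the same length as raw")
            object.__setattr__(self, "smoothed", smoothed)
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "raw", raw)

    def __len__(self) -> int:
        return len(self.raw)

    def to_frame(self) -> pd.DataFrame:
        """Return a DataFrame view (columns: date, raw, optionally smoothed)."""
        data = {"date": self.dates, self.region: self.raw}
        frame = pd.DataFrame(data)
        if self.smoothed is not None:
            frame[f"{self.region}_smoothed"] = self.smoothed
        return frame


def load_case_series(path: str | Path, region: str) -> CaseSeries:
    """Load one region's daily new cases from a wide surveillance CSV.

    The file must have a date-like first column (ISO-8601) and one
    column per region. The match on ``region`` is case-insensitive but
    otherwise exact. Calendar gaps are filled with missing values so
    the returned series is daily-contiguous; blank cells become ``NaN``.

    Raises
    ------
    ValueError
        If the file is empty, a date cannot be parsed (the offending
        row number is reported), or the region is unknown (available
        columns are listed).
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty") from None
    if frame.shape[1] < 2 or frame.shape[0] == 0:
        raise ValueError(f"{path}: expected a date column plus at least one region column and one data row")

    date_col = frame.columns[0]
    regions = list(frame.columns[1:])
    matches = [c for c in regions if c.lower() == region.lower()]
    if not matches:
        raise ValueError(f"unknown region {region!r}; available columns: {', '.join(regions)}")
    column = matches[0]

    dates = []
    for row_number, text in enumerate(frame[date_col], start=2):  # header is row 1
        try:
            dates.append(pd.Timestamp(text))
        except (ValueError, TypeError):
            raise ValueError(f"{path}: unparseable date {text!r} on row {row_number}") from None
    index = pd.DatetimeIndex(dates)

    values = pd.to_numeric(frame[column].replace("", np.nan), errors="coerce")
    series = pd.Series(values.to_numpy(dtype=float), index=index).sort_index()
    # fill calendar gaps with NaN to enforce daily contiguity
    full = pd.date_range(series.index[0], series.index[-1], freq="D")
    series = series.reindex(full)
    return CaseSeries(region=column, dates=full, raw=series.to_numpy())


def moving_average(series: CaseSeries, window: int = 7) -> CaseSeries:
    """Attach a trailing moving average to a series.

    ``smoothed[t]`` is the mean of the raw values over the ``window``
    days ending at ``t`` (shorter windows at the start of the series,
    so no future information is used). Missing raw days are skipped;
    a window with no observed day yields a missing smoothed value.
    Negative raw entries (surveillance corrections) are clamped to zero
    before averaging, so the smoothed curve is non-negative.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    raw = series.raw
    if np.all(np.isnan(raw)):
        raise ValueError("cannot smooth a series with no observed values")
    clamped = np.where(np.isnan(raw), np.nan, np.maximum(raw, 0.0))
    smoothed = (
        pd.Series(clamped)
        .rolling(window=window, min_periods=1)
        .mean()
        .to_numpy()
    )
    return replace(series, smoothed=smoothed)


def write_case_series(series: CaseSeries, path: str | Path) -> None:
    """Write a series back to the wide CSV dialect (one region column).

    Round-trip contract: ``load_case_series`` on the written file
    reproduces ``dates`` and ``raw`` exactly, with missing values
    preserved as blank cells. The smoothed companion is not written;
    it is derived data.
    """
    path = Path(path)
    frame = pd.DataFrame(
        {
            "date": series.dates.strftime("%Y-%m-%d"),
            series.region: [_format_count(v) for v in series.raw],
        }
    )
    try:
        frame.to_csv(path, index=False)
    except OSError as exc:
        raise ValueError(f"cannot write to {path}: {exc}") from exc


def _format_count(value: float) -> str:
    if np.isnan(value):
        return ""
    if float(value).is_integer():
        return str(int(value))
    return repr(float(value))
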
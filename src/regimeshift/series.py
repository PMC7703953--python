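"""Univariate time-series container used throughout the package.

A :class:`TimeSeries` is an ordered set of ``(time, value)`` observations
for one variable.  Times are integers (calendar years, or any integer
index); gaps in the time index encode missing values explicitly, so the
container itself never stores NaNs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TimeSeries", "read_timeseries_csv", "write_timeseries_csv"]


@dataclass(frozen=True)
class TimeSeries:
    """Ordered (time, value) observations for one variable.

    Parameters
    ----------
    times
        Strictly increasing integer time stamps (e.g. calendar years).
    values
        Finite observation values, one per time stamp, in data units.
    label
        Short name of the variable (used in outputs and plots).
    units
        Data units, free text (e.g. ``"°C"``, ``"cod per haul"``).
    """

    times: np.ndarray
    values: np.ndarray
    label: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=np.int64)
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1:
            raise ValueError("times and values must be one-dimensional")
        if len(times) != len(values):
            raise ValueError(
                f"times ({len(times)}) and values ({len(values)}) differ in length"
            )
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(values)):
            bad = times[~np.isfinite(values)]
            raise ValueError(f"non-finite value at time {bad[0]}")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def has_gaps(self) -> bool:
        """True if consecutive time stamps differ by more than one step."""
        return len(self) > 1 and bool(np.any(np.diff(self.times) > 1))

    def slice_times(self, start: int, end: int) -> "TimeSeries":
        """Sub-series with ``start <= time <= end`` (inclusive)."""
        mask = (self.times >= start) & (self.times <= end)
        return replace(self, times=self.times[mask], values=self.values[mask])

    def with_label(self, label: str, units: str | None = None) -> "TimeSeries":
        return replace(self, label=label, units=self.units if units is None else units)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "value": self.values})


def read_timeseries_csv(path: str | Path, label: str = "", units: str = "") -> TimeSeries:
    """Read a two-column (time, value) CSV with a header row.

    Raises
    ------
    ValueError
        If the file has fewer than two columns or duplicate times.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time, value), got {df.shape[1]}")
    tcol, vcol = df.columns[:2]
    times = pd.to_numeric(df[tcol], errors="raise").astype(np.int64)
    dup = times[times.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate time {dup.iloc[0]}")
    values = pd.to_numeric(df[vcol], errors="raise").astype(float)
    order = np.argsort(times.to_numpy())
    return TimeSeries(
        times.to_numpy()[order], values.to_numpy()[order],
        label=label or str(vcol), units=units,
    )


def write_timeseries_csv(series: TimeSeries, path: str | Path) -> None:
    """Write a series as a two-column (time, value) CSV; round-trips exactly."""
    # repr gives the shortest digit string that parses back to the same float
    lines = ["time,value"]
    lines += [f"{t},{float(v)!r}" for t, v in zip(series.times, series.values)]
    Path(path).write_text("\n".join(lines) + "\n")
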
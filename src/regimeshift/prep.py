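"""Reading and deriving the study's analysis inputs.

The six study inputs are plain CSVs: annual series (winter NAO index,
juvenile cod catch per haul, *C. finmarchicus* abundance, fishing
mortality F, spawning stock biomass) and one monthly series (Flødevigen
sea-surface temperature).  This module validates them and derives the
analysis series: per-month annual SST series, the March-August pooled
plankton series, and F and SSB expressed relative to their limit
reference points.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .series import TimeSeries, read_timeseries_csv

__all__ = [
    "ReferencePoints",
    "MonthlyRecord",
    "read_series",
    "monthly_series",
    "pool_months",
    "relative_to_reference",
    "SERIES_DEFAULTS",
]


@dataclass(frozen=True)
class ReferencePoints:
    """North Sea cod reference points.

    f_lim is the limit instantaneous fishing mortality, b_lim the limit
    spawning stock biomass in tonnes, and f_msy the fishing mortality at
    maximum sustainable yield (informational).
    """

    f_lim: float = 0.54
    b_lim: float = 107_000.0
    f_msy: float = 0.31

    def __post_init__(self) -> None:
        if not (self.f_lim > 0 and self.b_lim > 0 and self.f_msy > 0):
            raise ValueError("reference points must be positive")


@dataclass(frozen=True)
class MonthlyRecord:
    year: int
    month: int
    value: float

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValueError(f"month must be in 1..12, got {self.month}")


#: Per-series analysis defaults: minimum regime length M in years.  The
#: fishing-mortality series uses a shorter minimum (6 yr) than the
#: ecological series (10 yr).
SERIES_DEFAULTS: dict[str, dict] = {
    "nao": {"min_len": 10},
    "cod": {"min_len": 10},
    "zooplankton": {"min_len": 10},
    "sst_month": {"min_len": 10},
    "fishing": {"min_len": 6},
    "ssb": {"min_len": 10},
}


def read_series(
    path: str | Path, schema: str = "annual", label: str = "", units: str = ""
):
    """Read a study CSV.

    schema="annual" expects (time, value) columns and returns a
    :class:`TimeSeries`; schema="monthly" expects (year, month, value) and
    returns a list of :class:`MonthlyRecord`.  Duplicate (year[, month])
    keys raise a ``ValueError`` naming the offender.
    """
    if schema == "annual":
        return read_timeseries_csv(path, label=label, units=units)
    if schema != "monthly":
        raise ValueError(f"schema must be 'annual' or 'monthly', got {schema!r}")
    df = pd.read_csv(path)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: monthly schema needs (year, month, value) columns")
    ycol, mcol, vcol = df.columns[:3]
    years = pd.to_numeric(df[ycol], errors="raise").astype(int)
    months = pd.to_numeric(df[mcol], errors="raise").astype(int)
    values = pd.to_numeric(df[vcol], errors="raise").astype(float)
    keys = list(zip(years, months))
    seen: set = set()
    for k in keys:
        if k in seen:
            raise ValueError(f"{path}: duplicate (year, month) = {k}")
        seen.add(k)
    return [MonthlyRecord(int(y), int(m), float(v)) for y, m, v in zip(years, months, values)]


def _monthly_frame(records: list[MonthlyRecord]) -> pd.DataFrame:
    if not records:
        raise ValueError("no monthly records provided")
    return pd.DataFrame(
        {
            "year": [r.year for r in records],
            "month": [r.month for r in records],
            "value": [r.value for r in records],
        }
    )


def monthly_series(
    records: list[MonthlyRecord], month: int, label: str = "", units: str = ""
) -> TimeSeries:
    """Annual series for one calendar month.

    Sub-monthly records are averaged within each (year, month); years with
    no record for the month become gaps in the time index.
    """
    if not 1 <= month <= 12:
        raise ValueError(f"month must be in 1..12, got {month}")
    df = _monthly_frame(records)
    sub = df[df["month"] == month].groupby("year")["value"].mean().sort_index()
    return TimeSeries(
        sub.index.to_numpy(), sub.to_numpy(),
        label=label or f"month {month}", units=units,
    )


def pool_months(
    records: list[MonthlyRecord],
    first_month: int = 3,
    last_month: int = 8,
    stat: str = "mean",
    label: str = "",
    units: str = "",
) -> TimeSeries:
    """Annual series pooled over a window of months (default March-August).

    Per year, monthly means inside the window are combined with ``stat``
    ("mean" by default; "sum" for total abundance).  Years with no data in
    the window are gaps.
    """
    if first_month > last_month:
        raise ValueError("first_month must be <= last_month")
    if stat not in ("mean", "sum"):
        raise ValueError("stat must be 'mean' or 'sum'")
    df = _monthly_frame(records)
    window = df[(df["month"] >= first_month) & (df["month"] <= last_month)]
    if window.empty:
        raise ValueError(
            f"no records in months {first_month}..{last_month}"
        )
    per_month = window.groupby(["year", "month"])["value"].mean()
    agg = getattr(per_month.groupby(level="year"), stat)().sort_index()
    return TimeSeries(
        agg.index.to_numpy(), agg.to_numpy(),
        label=label or f"pooled months {first_month}-{last_month} ({stat})",
        units=units,
    )


def relative_to_reference(series: TimeSeries, ref: float) -> TimeSeries:
    """Express a series relative to a positive reference point (ratio)."""
    if not ref > 0:
        raise ValueError(f"reference point must be positive, got {ref}")
    label = f"{series.label} / {ref:g}" if series.label else f"value / {ref:g}"
    return TimeSeries(series.times, series.values / ref, label=label, units="ratio")
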
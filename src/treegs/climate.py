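"""Canadian Fire Weather Index Drought Code (DC) and monthly drought anomalies.

The DC tracks moisture depletion in deep, compact organic layers; higher values
mean drier conditions.  The daily update (Van Wagner 1987) is implemented
directly:

    V  = max(0, 0.36 * (T + 2.8) + Lf(month))          potential evapotranspiration
    if P > 2.8 mm:                                     rain routine
        r_eff = 0.83 * P - 1.27
        Q     = 800 * exp(-DC / 400)
        DC    = max(0, 400 * ln(800 / (Q + 3.937 * r_eff)))
    DC_new = max(0, DC + 0.5 * V)

with the standard northern-hemisphere monthly day-length factors Lf.  Monthly DC
is the mean of daily values over a fire season (April 1 - October 31 by default,
restarted each spring from a fixed value).  Monthly anomalies are centred and
scaled against a baseline period per calendar month, which is how drought
summers are made comparable across years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DAY_LENGTH_FACTORS",
    "ClimateSeries",
    "MonthlyIndexTable",
    "drought_code_step",
    "monthly_dc",
    "scale_monthly",
]

# Van Wagner (1987) monthly day-length factors, northern hemisphere, Jan..Dec.
DAY_LENGTH_FACTORS = (-1.6, -1.6, -1.6, 0.9, 3.8, 5.8, 6.4, 5.0, 2.4, 0.4, -1.6, -1.6)

RAIN_THRESHOLD_MM = 2.8


@dataclass
class ClimateSeries:
    """Contiguous daily weather records: date, mean temperature (degC), precip (mm)."""

    data: pd.DataFrame  # columns: date (datetime64), tmean, precip

    def __post_init__(self) -> None:
        df = self.data
        required = {"date", "tmean", "precip"}
        if not required.issubset(df.columns):
            raise ValueError(f"climate series needs columns {sorted(required)}")
        df = df.copy()
        df["date"] = pd.to_datetime(df["date"])
        if not df["date"].is_monotonic_increasing or df["date"].duplicated().any():
            raise ValueError("dates must be strictly increasing")
        gaps = df["date"].diff().dropna()
        missing = gaps[gaps != pd.Timedelta(days=1)]
        if len(missing):
            where = df["date"][missing.index].dt.date.tolist()
            raise ValueError(f"gap in daily dates before: {where}")
        if (df["precip"] < 0).any():
            raise ValueError("negative precipitation")
        self.data = df.reset_index(drop=True)

    def write_csv(self, path) -> None:
        out = self.data.copy()
        out["date"] = out["date"].dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def read_csv(cls, path) -> "ClimateSeries":
        return cls(pd.read_csv(path, parse_dates=["date"]))


@dataclass
class MonthlyIndexTable:
    """(year, month) -> raw monthly DC and, after scaling, its anomaly."""

    data: pd.DataFrame  # columns: year, month, dc_raw [, dc_scaled]
    baseline: tuple[int, int] | None = None

    def monthly(self, year: int, month: int, column: str = "dc_raw") -> float:
        df = self.data
        row = df[(df["year"] == year) & (df["month"] == month)]
        if row.empty:
            raise KeyError(f"no DC value for {year}-{month:02d}")
        return float(row[column].iloc[0])

    def write_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.6f")


def drought_code_step(dc_prev: float, tmean: float, precip: float, month: int) -> float:
    """One daily Drought Code update; pure function of yesterday's DC and today's weather."""
    if not 1 <= month <= 12:
        raise ValueError(f"month must be in 1..12, got {month}")
    if dc_prev < 0:
        raise ValueError("dc_prev must be non-negative")
    dc = float(dc_prev)
    if precip > RAIN_THRESHOLD_MM:
        r_eff = 0.83 * precip - 1.27
        q = 800.0 * np.exp(-dc / 400.0) + 3.937 * r_eff
        dc = max(0.0, 400.0 * np.log(800.0 / q))
    v = max(0.0, 0.36 * (tmean + 2.8) + DAY_LENGTH_FACTORS[month - 1])
    return max(0.0, dc + 0.5 * v)


def monthly_dc(
    series: ClimateSeries,
    dc_start: float = 15.0,
    season: tuple[str, str] = ("04-01", "10-31"),
    overwinter_reset: float | None = None,
) -> MonthlyIndexTable:
    """Iterate the daily DC over each fire season and average by month.

    Each spring the code restarts at ``overwinter_reset`` (defaults to
    ``dc_start``); days outside the season carry no DC and contribute no monthly
    value.
    """
    reset = dc_start if overwinter_reset is None else overwinter_reset
    df = series.data
    start_md = tuple(int(x) for x in season[0].split("-"))
    end_md = tuple(int(x) for x in season[1].split("-"))
    years = df["date"].dt.year
    months = df["date"].dt.month
    days = df["date"].dt.day
    md = list(zip(months, days))
    in_season = np.array([start_md <= x <= end_md for x in md])

    records: list[tuple[int, int, float]] = []
    dc = reset
    prev_year = None
    daily = np.full(len(df), np.nan)
    for i in range(len(df)):
        if not in_season[i]:
            continue
        y = int(years.iloc[i])
        if y != prev_year:
            dc = reset
            prev_year = y
        dc = drought_code_step(dc, float(df["tmean"].iloc[i]), float(df["precip"].iloc[i]), int(months.iloc[i]))
        daily[i] = dc
    tab = pd.DataFrame({"year": years, "month": months, "dc": daily}).dropna()
    agg = tab.groupby(["year", "month"], as_index=False)["dc"].mean()
    agg = agg.rename(columns={"dc": "dc_raw"})
    records = agg
    return MonthlyIndexTable(records.reset_index(drop=True))


def scale_monthly(raw: MonthlyIndexTable, baseline: tuple[int, int]) -> MonthlyIndexTable:
    """Centre and scale monthly DC per calendar month against a baseline year range."""
    lo, hi = baseline
    df = raw.data.copy()
    base = df[(df["year"] >= lo) & (df["year"] <= hi)]
    if base.empty:
        raise ValueError(f"no data inside baseline {lo}-{hi}")
    stats = base.groupby("month")["dc_raw"].agg(["mean", "std", "count"])
    bad = stats[stats["count"] < 2]
    if len(bad):
        raise ValueError(f"baseline has < 2 years for months {list(bad.index)}")
    zero = stats[stats["std"] == 0]
    if len(zero):
        raise ValueError(f"zero baseline standard deviation for months {list(zero.index)}")
    df["dc_scaled"] = (
        df["dc_raw"] - df["month"].map(stats["mean"])
    ) / df["month"].map(stats["std"])
    return MonthlyIndexTable(df, baseline=baseline)
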
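"""Age grids and calendar/date helpers.

All internal arithmetic is done in exact days; durations convert to years
by division with ``DAYS_PER_YEAR`` = 365.25.  Dates are represented as
integer days since the Unix epoch (``numpy.datetime64[D]`` cast to int),
so day counting is exact and vectorizable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25


def to_day(date) -> int:
    """Convert a date-like (string, datetime, date) to integer epoch days."""
    return int(np.datetime64(pd.Timestamp(date).date(), "D").astype(int))


def to_days(dates) -> np.ndarray:
    """Vectorized :func:`to_day`."""
    return pd.to_datetime(pd.Series(dates)).values.astype("datetime64[D]").astype(int)


def from_day(day: int | np.ndarray):
    """Inverse of :func:`to_day`: epoch days back to ``datetime64[D]``."""
    return np.asarray(day).astype("datetime64[D]")


def years_to_days(years: float) -> int:
    return int(round(years * DAYS_PER_YEAR))


@dataclass(frozen=True)
class AgeGrid:
    """Ordered partition of [0, inf) into age bands.

    Parameters
    ----------
    day_breaks
        Strictly increasing lower bounds in exact days of age, starting at 0.
        The last band is open-ended.
    labels
        One label per band.
    """

    day_breaks: tuple[int, ...]
    labels: tuple[str, ...]
    year_breaks: tuple[float, ...] | None = None  # exact years, when built from years

    def __post_init__(self):
        br = np.asarray(self.day_breaks)
        if br[0] != 0 or np.any(np.diff(br) <= 0):
            raise ValueError("age day_breaks must start at 0 and be strictly increasing")
        if len(self.labels) != len(self.day_breaks):
            raise ValueError("need one label per band")

    @property
    def n_bands(self) -> int:
        return len(self.labels)

    def band_of(self, age_days) -> np.ndarray:
        """Index of the band containing each age (in days)."""
        return np.searchsorted(self.day_breaks, np.asarray(age_days), side="right") - 1

    def band_starts_years(self) -> np.ndarray:
        if self.year_breaks is not None:
            return np.asarray(self.year_breaks, dtype=float)
        return np.asarray(self.day_breaks) / DAYS_PER_YEAR

    @classmethod
    def from_year_breaks(cls, year_breaks: Sequence[float], labels: Iterable[str] | None = None) -> "AgeGrid":
        days = tuple(years_to_days(y) for y in year_breaks)
        if labels is None:
            ys = list(year_breaks)
            labels = []
            for i, y in enumerate(ys):
                if i + 1 < len(ys):
                    hi = ys[i + 1]
                    labels.append(f"{y:g}-{hi - 1:g}y" if hi - y > 1 else f"{y:g}y")
                else:
                    labels.append(f"{y:g}+y")
        return cls(days, tuple(labels), tuple(float(y) for y in year_breaks))

    @classmethod
    def analysis(cls) -> "AgeGrid":
        """The seven surveillance analysis bands.

        0-28 d is implemented as [0, 29) days and 29-365 d as [29, 366) so the
        printed labels' inclusive upper bounds hold; year-denominated bands
        start at round(365.25 * years) days.
        """
        return cls(
            (0, 29, 366, years_to_days(5), years_to_days(15), years_to_days(55), years_to_days(75)),
            ("0-28d", "29-365d", "1-4y", "5-14y", "15-54y", "55-74y", "75+y"),
        )

    @classmethod
    def lifetable(cls, open_age: int = 85) -> "AgeGrid":
        """Standard abridged grid: <1, 1-4, then 5-year bands to ``open_age``+."""
        years = [0, 1] + list(range(5, open_age + 1, 5))
        labels = ["<1y", "1-4y"] + [f"{a}-{a + 4}y" for a in range(5, open_age, 5)] + [f"{open_age}+y"]
        return cls(tuple(years_to_days(y) for y in years), tuple(labels), tuple(float(y) for y in years))


ANALYSIS_GRID = AgeGrid.analysis()
LIFETABLE_GRID = AgeGrid.lifetable()


@dataclass(frozen=True)
class PeriodBreaks:
    """Partition of the study window into calendar analysis periods."""

    start_days: tuple[int, ...]  # period start dates (epoch days), ascending
    end_day: int                 # exclusive end of the last period
    labels: tuple[str, ...]

    @classmethod
    def from_years(cls, years: Sequence[int], end_year: int) -> "PeriodBreaks":
        starts = tuple(to_day(f"{y}-01-01") for y in years)
        labels = []
        ys = list(years) + [end_year]
        for lo, hi in zip(ys[:-1], ys[1:]):
            labels.append(f"{lo}-{str(hi - 1)[2:]}")
        return cls(starts, to_day(f"{end_year}-01-01"), tuple(labels))

    @classmethod
    def default(cls) -> "PeriodBreaks":
        """Four 4-year analysis periods, 2003-2018."""
        return cls.from_years([2003, 2007, 2011, 2015], 2019)

    @property
    def window(self) -> tuple[int, int]:
        return self.start_days[0], self.end_day

    def period_of(self, day) -> np.ndarray:
        return np.searchsorted(self.start_days, np.asarray(day), side="right") - 1

    def boundaries(self) -> np.ndarray:
        return np.asarray(self.start_days[1:])


def month_starts(day_lo: int, day_hi: int) -> np.ndarray:
    """Epoch days of the first of each month intersecting [day_lo, day_hi)."""
    lo = from_day(day_lo).astype("datetime64[M]")
    hi = (from_day(day_hi - 1).astype("datetime64[M]") + 1).astype("datetime64[M]")
    return np.arange(lo, hi + 1).astype("datetime64[D]").astype(int)


def year_month(day) -> tuple[np.ndarray, np.ndarray]:
    """Calendar (year, month) of epoch days."""
    d = from_day(day)
    m = d.astype("datetime64[M]").astype(int)
    return m // 12 + 1970, m % 12 + 1
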
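"""Episode-based person-time: risk intervals and Lexis splitting.

The atomic input is a *residency episode*: one individual's continuous spell
of residence in one location, bounded by birth / in-migration / enumeration
at the start and death / out-migration / study end at the end.  Episodes are
converted to risk intervals (entry enters risk at the latest of birth,
in-migration and study start; exit leaves at the earliest of death,
out-migration and study end), then split on a Lexis grid of age band x sex x
calendar period (optionally x calendar month and x location).

Conventions
-----------
Dates are integer epoch days; an interval [entry, exit) is half-open, so an
episode ending in death on date *d* contributes exposure up to but not
including *d*, and the death is attributed to the cell containing the last
exposed day.  Durations convert to years via /365.25.

Two risk-time rules are supported:

``standard``
    Out-migration -> in-migration gaps are excluded from risk time
    (avoids survivor bias: only survivors of the gap are observed to return).
``madimah``
    Gaps shorter than 180 days between an out-migration and the next
    in-migration are counted as risk time (appended as ``included-gap``
    intervals attributed to the previous residence location), which
    increases person-years and lowers rate estimates.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .ages import AgeGrid, PeriodBreaks, DAYS_PER_YEAR, month_starts, to_days, year_month

logger = logging.getLogger(__name__)

MADIMAH_GAP_DAYS = 180

START_REASONS = {"birth", "in-migration", "enumeration"}
END_REASONS = {"death", "out-migration", "study-end", "ongoing"}


class DataIntegrityError(ValueError):
    """Input episode/individual tables violate the surveillance contract."""


def _episode_days(episodes: pd.DataFrame, window: tuple[int, int]) -> pd.DataFrame:
    ep = episodes.copy()
    ep["start_day"] = to_days(ep["start_date"])
    end = pd.to_datetime(pd.Series(ep["end_date"].values))
    end_day = np.where(end.isna(), window[1], end.values.astype("datetime64[D]").astype("float64"))
    # non-terminal episodes (study-end / ongoing) run to the exclusive window end
    open_ended = ep["end_reason"].isin(["study-end", "ongoing"]).values | end.isna().values
    ep["exit_day_raw"] = np.where(open_ended, window[1], end_day).astype(int)
    return ep


def build_risk_intervals(
    episodes: pd.DataFrame,
    study_window: tuple[int, int],
    rule: str = "standard",
    individuals: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Convert residency episodes to risk intervals under a risk-time rule.

    Parameters
    ----------
    episodes
        Columns ``individual_id, location_id, start_date, start_reason,
        end_date, end_reason``.  Episodes of one individual must be disjoint.
    study_window
        ``(start_day, end_day)`` in epoch days, end exclusive.
    rule
        ``"standard"`` or ``"madimah"`` (see module docstring).
    individuals
        Optional table with ``individual_id, dod``; used to detect deaths
        dated outside any episode.

    Returns
    -------
    DataFrame with columns ``individual_id, location_id, entry_day,
    exit_day, event, provenance``; one row per interval, ``entry < exit``.
    """
    if rule not in {"standard", "madimah"}:
        raise ValueError(f"unknown risk-time rule {rule!r}")
    bad_reasons = set(episodes["end_reason"].dropna()) - END_REASONS
    if bad_reasons:
        raise DataIntegrityError(f"unknown end_reason values: {sorted(bad_reasons)}")

    ep = _episode_days(episodes, study_window).sort_values(
        ["individual_id", "start_day"], kind="mergesort"
    )
    if (ep["exit_day_raw"] < ep["start_day"]).any():
        bad = ep.loc[ep["exit_day_raw"] < ep["start_day"], "individual_id"].iloc[0]
        raise DataIntegrityError(f"episode ends before it starts for individual {bad!r}")

    same = ep["individual_id"].values[1:] == ep["individual_id"].values[:-1]
    overlap = same & (ep["start_day"].values[1:] < ep["exit_day_raw"].values[:-1])
    if overlap.any():
        bad = ep["individual_id"].values[1:][overlap][0]
        raise DataIntegrityError(f"overlapping episodes for individual {bad!r}")

    entry = np.maximum(ep["start_day"].values, study_window[0])
    exit_ = np.minimum(ep["exit_day_raw"].values, study_window[1])
    # death counts as an event only if the episode's own end was the death
    # and it was not clipped away by the window
    event = (ep["end_reason"].values == "death") & (exit_ == ep["exit_day_raw"].values)

    out = pd.DataFrame(
        {
            "individual_id": ep["individual_id"].values,
            "location_id": ep["location_id"].values,
            "entry_day": entry,
            "exit_day": exit_,
            "event": event,
            "provenance": "residence",
        }
    )

    if individuals is not None and "dod" in individuals:
        dod = pd.to_datetime(individuals.set_index("individual_id")["dod"])
        dod = dod.dropna().values.astype("datetime64[D]").astype(int)
        died = individuals.loc[pd.notna(individuals["dod"]), "individual_id"]
        covered = set(ep.loc[ep["end_reason"] == "death", "individual_id"])
        outside = [i for i, d in zip(died, dod) if i not in covered and study_window[0] <= d < study_window[1]]
        if outside:
            raise DataIntegrityError(
                f"death date outside all episodes for individuals {outside[:5]}"
            )

    if rule == "madimah":
        prev_end = ep["exit_day_raw"].values[:-1]
        gap_ok = (
            same
            & (ep["end_reason"].values[:-1] == "out-migration")
            & (ep["start_reason"].values[1:] == "in-migration")
        )
        gap_len = ep["start_day"].values[1:] - prev_end
        inc = gap_ok & (gap_len > 0) & (gap_len < MADIMAH_GAP_DAYS)
        if inc.any():
            g_entry = np.maximum(prev_end[inc], study_window[0])
            g_exit = np.minimum(ep["start_day"].values[1:][inc], study_window[1])
            keep = g_entry < g_exit
            gaps = pd.DataFrame(
                {
                    "individual_id": ep["individual_id"].values[1:][inc][keep],
                    "location_id": ep["location_id"].values[:-1][inc][keep],
                    "entry_day": g_entry[keep],
                    "exit_day": g_exit[keep],
                    "event": False,
                    "provenance": "included-gap",
                }
            )
            out = pd.concat([out, gaps], ignore_index=True)

    out = out[out["entry_day"] < out["exit_day"]].reset_index(drop=True)
    return out.sort_values(["individual_id", "entry_day"], kind="mergesort").reset_index(drop=True)


def _split_at(df: pd.DataFrame, cuts: np.ndarray, shift: np.ndarray) -> pd.DataFrame:
    """Split [entry, exit) rows at global cut points on a shifted scale.

    ``cuts`` are sorted values on the scale ``day - shift`` (shift = birth day
    for age cuts, 0 for calendar cuts).  Fragment boundaries land exactly on
    cuts strictly inside each interval; endpoints are preserved.
    """
    if len(df) == 0 or len(cuts) == 0:
        return df
    a = df["entry_day"].values - shift
    b = df["exit_day"].values - shift
    lo = np.searchsorted(cuts, a, side="right")
    hi = np.searchsorted(cuts, b, side="left")
    nfrag = hi - lo + 1
    total = int(nfrag.sum())
    parent = np.repeat(np.arange(len(df)), nfrag)
    k = np.arange(total) - np.repeat(np.cumsum(nfrag) - nfrag, nfrag)
    first = k == 0
    last = k == (nfrag[parent] - 1)
    start = np.where(first, a[parent], cuts[np.clip(lo[parent] + k - 1, 0, len(cuts) - 1)])
    end = np.where(last, b[parent], cuts[np.clip(lo[parent] + k, 0, len(cuts) - 1)])
    out = df.iloc[parent].reset_index(drop=True)
    out["entry_day"] = (start + shift[parent]).astype(int)
    out["exit_day"] = (end + shift[parent]).astype(int)
    out["event"] = out["event"].values & last  # death stays with the final fragment
    return out


def split_lexis(
    intervals: pd.DataFrame,
    individuals: pd.DataFrame,
    age_grid: AgeGrid,
    periods: PeriodBreaks,
    by_month: bool = False,
    by_location: bool = False,
) -> pd.DataFrame:
    """Split risk intervals on the Lexis grid and aggregate to cells.

    Every interval is cut at each age-band crossing, analysis-period
    boundary and (if ``by_month``) calendar-month boundary, then deaths and
    person-years are summed per cell.  A death is counted in exactly one
    cell: the one containing the final exposed day at the attained age.

    Returns a tidy cell table with columns ``age_band, sex, period``
    (+ ``year, month`` and/or ``location_id``), ``deaths, pyo``.
    """
    ind = individuals.set_index("individual_id")
    df = intervals.copy()
    df["birth_day"] = to_days(ind.loc[df["individual_id"], "dob"].values)
    df["sex"] = ind.loc[df["individual_id"], "sex"].values
    if (df["entry_day"] < df["birth_day"]).any():
        raise DataIntegrityError("risk interval starts before birth")

    age_cuts = np.asarray(age_grid.day_breaks[1:])
    df = _split_at(df, age_cuts, df["birth_day"].values)
    df = _split_at(df, periods.boundaries(), np.zeros(len(df), dtype=int))
    if by_month:
        cuts = month_starts(*periods.window)
        df = _split_at(df, cuts, np.zeros(len(df), dtype=int))

    band = age_grid.band_of(df["entry_day"].values - df["birth_day"].values)
    df["age_band"] = pd.Categorical.from_codes(band, categories=list(age_grid.labels), ordered=True)
    pidx = periods.period_of(df["entry_day"].values)
    df["period"] = pd.Categorical.from_codes(pidx, categories=list(periods.labels), ordered=True)
    df["pyo"] = (df["exit_day"] - df["entry_day"]) / DAYS_PER_YEAR
    df["deaths"] = df["event"].astype(int)

    keys = ["age_band", "sex", "period"]
    if by_month:
        yr, mo = year_month(df["entry_day"].values)
        df["year"], df["month"] = yr, mo
        keys += ["year", "month"]
    if by_location:
        keys += ["location_id"]
    cells = (
        df.groupby(keys, observed=True, as_index=False)[["deaths", "pyo"]]
        .sum()
        .sort_values(keys, kind="mergesort")
        .reset_index(drop=True)
    )
    return cells


def tabulate(cells: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
    """Aggregate a Lexis cell table over the retained ``keys``.

    Deaths and person-years are summed; marginals are consistent with the
    full table by construction.  ``keys=[]`` returns the grand total row.
    """
    unknown = set(keys) - set(cells.columns)
    if unknown:
        raise KeyError(f"keys not in cell table: {sorted(unknown)}")
    if not keys:
        return cells[["deaths", "pyo"]].sum().to_frame().T
    return (
        cells.groupby(keys, observed=True, as_index=False)[["deaths", "pyo"]]
        .sum()
        .sort_values(keys, kind="mergesort")
        .reset_index(drop=True)
    )
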
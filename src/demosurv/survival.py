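"""Kaplan-Meier survival on the age scale with delayed entry, and abridged
period life tables under alternative risk-time definitions.

Two estimands of longevity are provided: the *median* age at death from a
left-truncated Kaplan-Meier fit (individuals enter the risk set at the age
attained when they come under observation), and the *mean* life expectancy
at birth from an abridged period life table built from central death rates
nMx = deaths / person-years per age interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ages import AgeGrid, DAYS_PER_YEAR

#: classical nax defaults: mean years lived in the interval by those dying in it
A0_INFANT = 0.1   # <1 year interval
A1_CHILD = 1.5    # 1-4 year interval


@dataclass
class KMResult:
    """Left-truncated Kaplan-Meier estimate on the age scale."""

    times: np.ndarray       # distinct death ages (years), ascending
    survival: np.ndarray    # S(t) just after each death age
    at_risk: np.ndarray     # risk-set size at each death age
    n_events: np.ndarray
    median: float           # smallest age with S <= 0.5; nan if never reached

    def survival_at(self, age: float) -> float:
        i = np.searchsorted(self.times, age, side="right")
        return 1.0 if i == 0 else float(self.survival[i - 1])


def km_fit(entry_age, exit_age, event) -> KMResult:
    """Product-limit estimator with delayed entry (left truncation).

    At each distinct death age ``a`` the survival multiplies by
    ``1 - d_a / r_a`` where the risk set ``r_a`` counts intervals with
    ``entry < a <= exit``.  The median is the smallest age at which the
    step function falls to 0.5 or below.
    """
    entry = np.asarray(entry_age, dtype=float)
    exit_ = np.asarray(exit_age, dtype=float)
    ev = np.asarray(event, dtype=bool)
    if np.any(entry >= exit_):
        raise ValueError("entry age must be strictly below exit age")

    death_ages = np.unique(exit_[ev])
    if len(death_ages) == 0:
        return KMResult(death_ages, np.ones(0), np.zeros(0, int), np.zeros(0, int), float("nan"))

    # r_a = #(entry < a) - #(exit < a)
    r = (
        np.searchsorted(np.sort(entry), death_ages, side="left")
        - np.searchsorted(np.sort(exit_), death_ages, side="left")
    )
    d = np.searchsorted(np.sort(exit_[ev]), death_ages, side="right") - np.searchsorted(
        np.sort(exit_[ev]), death_ages, side="left"
    )
    if np.any(r <= 0):
        bad = death_ages[r <= 0][0]
        raise ValueError(f"empty risk set at death age {bad:g}: pathological truncation")
    surv = np.cumprod(1.0 - d / r)
    below = np.nonzero(surv <= 0.5)[0]
    median = float(death_ages[below[0]]) if len(below) else float("nan")
    return KMResult(death_ages, surv, r.astype(int), d.astype(int), median)


def km_from_intervals(intervals: pd.DataFrame, individuals: pd.DataFrame) -> KMResult:
    """KM fit from risk intervals, converting calendar days to attained age."""
    from .ages import to_days

    ind = individuals.set_index("individual_id")
    birth = to_days(ind.loc[intervals["individual_id"], "dob"].values)
    entry = (intervals["entry_day"].values - birth) / DAYS_PER_YEAR
    exit_ = (intervals["exit_day"].values - birth) / DAYS_PER_YEAR
    return km_fit(entry, exit_, intervals["event"].values)


def default_nax(grid: AgeGrid) -> np.ndarray:
    """Classical abridged-life-table nax defaults.

    a0 = 0.1 y for an infant (<1 y) first interval, 1.5 y for a 1-4 y
    second interval, n/2 elsewhere; the open interval's value is ignored
    (1/M is used there).
    """
    starts = grid.band_starts_years()
    widths = np.diff(np.append(starts, np.inf))
    nax = widths / 2.0
    if np.isclose(starts[0], 0) and len(starts) > 1 and np.isclose(starts[1], 1, atol=0.01):
        nax[0] = A0_INFANT
        if len(starts) > 2 and np.isclose(starts[2] - starts[1], 4, atol=0.02):
            nax[1] = A1_CHILD
    return nax


def abridged_life_table(
    deaths,
    pyo,
    grid: AgeGrid,
    nax: np.ndarray | None = None,
    radix: float = 100_000.0,
) -> pd.DataFrame:
    """Abridged period life table from deaths and person-years per interval.

    Converts central death rates nMx = deaths/pyo into conditional death
    probabilities nqx = n*nMx / (1 + (n - nax)*nMx), survivors lx (radix
    100,000), deaths ndx, person-years lived nLx, person-years remaining Tx
    and life expectancy ex = Tx/lx.  The open-ended last interval has
    nqx = 1 and nLx = lx / nMx.

    Returns a DataFrame with columns ``age, n, nMx, nax, nqx, lx, ndx,
    nLx, Tx, ex`` (ages and n in years).
    """
    deaths = np.asarray(deaths, dtype=float)
    pyo = np.asarray(pyo, dtype=float)
    k = grid.n_bands
    if len(deaths) != k or len(pyo) != k:
        raise ValueError("deaths and pyo must align with the age grid")
    if np.any(pyo[:-1] <= 0):
        raise ValueError("zero person-years in a closed age interval")
    if pyo[-1] <= 0 or deaths[-1] <= 0:
        raise ValueError("open interval needs positive deaths and person-years")

    starts = grid.band_starts_years()
    n = np.diff(np.append(starts, np.nan))
    if nax is None:
        nax = default_nax(grid)
    nax = np.asarray(nax, dtype=float).copy()

    nMx = deaths / pyo
    nqx = np.empty(k)
    nqx[:-1] = n[:-1] * nMx[:-1] / (1.0 + (n[:-1] - nax[:-1]) * nMx[:-1])
    if np.any(nqx[:-1] > 1):
        import warnings

        warnings.warn("nqx > 1 clamped to 1 (extreme central death rate)")
        nqx[:-1] = np.minimum(nqx[:-1], 1.0)
    nqx[-1] = 1.0

    lx = np.empty(k)
    lx[0] = radix
    for i in range(k - 1):
        lx[i + 1] = lx[i] * (1.0 - nqx[i])
    ndx = np.append(lx[:-1] - lx[1:], lx[-1])
    nLx = np.empty(k)
    nLx[:-1] = n[:-1] * lx[1:] + nax[:-1] * ndx[:-1]
    nLx[-1] = lx[-1] / nMx[-1] if nMx[-1] > 0 else 0.0
    nax[-1] = nLx[-1] / ndx[-1] if ndx[-1] > 0 else np.nan
    Tx = np.cumsum(nLx[::-1])[::-1]
    ex = Tx / np.where(lx > 0, lx, np.nan)

    return pd.DataFrame(
        {
            "age": starts,
            "n": n,
            "nMx": nMx,
            "nax": nax,
            "nqx": nqx,
            "lx": lx,
            "ndx": ndx,
            "nLx": nLx,
            "Tx": Tx,
            "ex": ex,
        }
    )


def life_table_from_cells(cells: pd.DataFrame, grid: AgeGrid, **kw) -> pd.DataFrame:
    """Life table from a Lexis cell table aggregated on the life-table grid."""
    from .persontime import tabulate

    tab = tabulate(cells, ["age_band"])
    tab = tab.set_index("age_band").reindex(list(grid.labels))
    if tab[["deaths", "pyo"]].isna().any().any():
        raise ValueError("cell table does not cover every life-table age interval")
    return abridged_life_table(tab["deaths"].values, tab["pyo"].values, grid, **kw)


def compare_risk_time_variants(
    cells_standard: pd.DataFrame, cells_madimah: pd.DataFrame, grid: AgeGrid, **kw
) -> pd.DataFrame:
    """Paired life tables under standard vs MADIMAH person-time.

    MADIMAH counts short (<180 d) out-in migration gaps as risk time, so
    its nMx can only be lower for the same deaths; the comparison reports
    per-interval ``nMx_std, nMx_mad, dMx`` and ``ex_std, ex_mad, dex``
    (dex = MADIMAH minus standard; positive when extra exposure lowers
    the rates).
    """
    lt_s = life_table_from_cells(cells_standard, grid, **kw)
    lt_m = life_table_from_cells(cells_madimah, grid, **kw)
    out = lt_s[["age", "n"]].copy()
    out["nMx_std"] = lt_s["nMx"]
    out["nMx_mad"] = lt_m["nMx"]
    out["dMx"] = lt_m["nMx"] - lt_s["nMx"]
    out["ex_std"] = lt_s["ex"]
    out["ex_mad"] = lt_m["ex"]
    out["dex"] = lt_m["ex"] - lt_s["ex"]
    return out
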
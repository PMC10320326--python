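"""Synthetic open-cohort surveillance populations with known ground truth.

Generates a multi-decade open cohort — baseline residents, births, deaths,
in/out-migration with return gaps, administrative locations with
multiplicative log-rate effects, period-declining age- and sex-specific
hazards and an optional seasonal hazard multiplier — so that every
downstream person-time, rate, life-table, seasonality and heterogeneity
computation can be checked against the generating parameters.

Hazards are piecewise-constant within age band x calendar period (x month
for the seasonal stratum); event times are drawn by competing exponential
clocks with change points at every band/period/month boundary, which makes
the analytic stratum rate :func:`expected_rate` an exact oracle.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ages import (
    ANALYSIS_GRID,
    DAYS_PER_YEAR,
    AgeGrid,
    PeriodBreaks,
    from_day,
    month_starts,
    to_day,
    year_month,
)

SEXES = ("F", "M")

#: Default age–sex–period death-rate schedule (deaths per 1000 person-years)
#: for the seven analysis bands over four 4-year periods: a rural East
#: African surveillance population with high neonatal mortality declining
#: steeply after the first period.
DEFAULT_SCHEDULE = {
    "F": {
        "0-28d": (283.0, 172.7, 173.3, 141.6),
        "29-365d": (19.1, 11.5, 9.0, 8.3),
        "1-4y": (5.9, 2.7, 2.5, 1.7),
        "5-14y": (1.2, 0.7, 0.8, 0.7),
        "15-54y": (5.6, 3.6, 3.0, 2.7),
        "55-74y": (21.1, 19.3, 17.5, 13.6),
        "75+y": (69.5, 70.4, 58.0, 63.0),
    },
    "M": {
        "0-28d": (377.2, 228.5, 176.1, 202.8),
        "29-365d": (18.4, 12.2, 11.2, 8.0),
        "1-4y": (6.2, 3.2, 2.7, 2.3),
        "5-14y": (1.6, 0.9, 1.0, 1.0),
        "15-54y": (5.8, 3.9, 3.6, 3.2),
        "55-74y": (30.8, 28.9, 29.8, 26.8),
        "75+y": (84.3, 91.4, 94.5, 96.2),
    },
}


def default_base_hazard(grid: AgeGrid = ANALYSIS_GRID, n_periods: int = 4) -> dict:
    """Default hazard map (band, sex, period index) -> deaths per person-year."""
    out = {}
    for sex in SEXES:
        for band in grid.labels:
            rates = DEFAULT_SCHEDULE[sex][band]
            for p in range(n_periods):
                out[(band, sex, p)] = rates[min(p, len(rates) - 1)] / 1000.0
    return out


@dataclass
class SimConfig:
    """Parameters of the synthetic surveillance cohort.

    Attributes
    ----------
    study_start, study_end : str
        Inclusive calendar bounds of the surveillance window (ISO dates).
    n_baseline : int
        Residents enumerated at the study start.
    birth_rate : float
        Live births per person-year (applied to the baseline count; no
        demographic feedback).
    age_grid : AgeGrid
        Age bands of the hazard schedule.
    base_hazard : dict
        Map (age band label, sex, period index) -> deaths per person-year.
    n_locations : int
    location_effect_sd : float
        SD of per-location Normal effects on the log-rate scale, drawn once
        per simulation.
    seasonal_amplitude : float
        Peak-to-mean hazard ratio of a 12-point cosine monthly profile
        (mean one, so annualized rates are unchanged); 1 disables it.
    seasonal_band, seasonal_periods, seasonal_peak_month
        The stratum the seasonal multiplier applies to (default: ages 1-4 y
        in the first period, peaking in July).
    outmigration_rate : float
        Out-migration events per person-year.
    return_prob : float
        Probability an out-migrant returns (new episode after a gap).
    gap_short_frac, gap_short_range, gap_long_range
        Out->in gap mixture in days: mass below and above the 180-day
        risk-time threshold.
    inmigration_rate : float
        Fresh in-migrants per baseline person-year, ages uniform on
        [0, inmigrant_max_age].
    seed : int
    """

    study_start: str = "2003-01-01"
    study_end: str = "2018-12-31"
    n_baseline: int = 20_000
    birth_rate: float = 0.032
    age_grid: AgeGrid = field(default_factory=AgeGrid.analysis)
    base_hazard: dict | None = None
    n_locations: int = 15
    location_effect_sd: float = 0.08
    seasonal_amplitude: float = 1.5
    seasonal_band: str = "1-4y"
    seasonal_periods: tuple[int, ...] = (0,)
    seasonal_peak_month: int = 7
    outmigration_rate: float = 0.08
    return_prob: float = 0.6
    gap_short_frac: float = 0.5
    gap_short_range: tuple[int, int] = (30, 179)
    gap_long_range: tuple[int, int] = (180, 540)
    inmigration_rate: float = 0.01
    inmigrant_max_age: float = 60.0
    pop_growth_rate: float = 0.028
    periods: PeriodBreaks = field(default_factory=PeriodBreaks.default)
    seed: int = 0

    def __post_init__(self):
        if to_day(self.study_start) >= to_day(self.study_end):
            raise ValueError("study_start must precede study_end")
        if self.base_hazard is None:
            self.base_hazard = default_base_hazard(self.age_grid, len(self.periods.labels))
        if any(v < 0 for v in self.base_hazard.values()):
            raise ValueError("hazards must be non-negative")
        for name in ("birth_rate", "outmigration_rate", "inmigration_rate", "location_effect_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.return_prob <= 1:
            raise ValueError("return_prob must lie in [0, 1]")
        if not 0 <= self.seasonal_amplitude <= 2:
            raise ValueError("seasonal_amplitude (peak-to-mean) must lie in [0, 2]")

    @property
    def window(self) -> tuple[int, int]:
        return to_day(self.study_start), to_day(self.study_end) + 1

    def hazard_array(self) -> np.ndarray:
        """(band, sex, period) hazard per person-year as a dense array."""
        nb, np_ = self.age_grid.n_bands, len(self.periods.labels)
        H = np.zeros((nb, 2, np_))
        for b, band in enumerate(self.age_grid.labels):
            for s, sex in enumerate(SEXES):
                for p in range(np_):
                    H[b, s, p] = self.base_hazard[(band, sex, p)]
        return H

    def seasonal_profile(self) -> np.ndarray:
        """Monthly multiplier, mean exactly one across the 12 months."""
        m = np.arange(1, 13)
        prof = 1.0 + (self.seasonal_amplitude - 1.0) * np.cos(
            2 * np.pi * (m - self.seasonal_peak_month) / 12.0
        )
        return prof / prof.mean()


@dataclass
class TruePopulation:
    """A realized synthetic cohort plus the truth that generated it."""

    individuals: pd.DataFrame   # individual_id, sex, dob, dod
    episodes: pd.DataFrame      # individual_id, location_id, start/end date+reason
    live_births: pd.DataFrame   # date, location_id, individual_id, sex
    truth: dict                 # config + realized location effects


def _stationary_ages(config: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """Baseline ages (days) from a stable-population approximation: density
    proportional to survivorship l(a) of the first-period hazard schedule
    (sexes averaged) discounted by exp(-g*a) for intrinsic growth rate g,
    capped at 95 years.  A positive g yields the young age structure typical
    of a growing surveillance population."""
    H = config.hazard_array()[:, :, 0].mean(axis=1)
    a_grid = np.arange(95)
    mu = np.array([H[config.age_grid.band_of(a * DAYS_PER_YEAR)] for a in a_grid + 0.5])
    l = np.exp(-np.concatenate([[0.0], np.cumsum(mu[:-1])]))
    dens = l * np.exp(-config.pop_growth_rate * a_grid)
    p = dens / dens.sum()
    years = rng.choice(95, size=n, p=p) + rng.random(n)
    return np.round(years * DAYS_PER_YEAR).astype(int)


def simulate_population(config: SimConfig) -> TruePopulation:
    """Simulate the open cohort; deterministic for a fixed seed.

    Every resident experiences competing death and out-migration clocks
    whose rates change at age-band, period and (seasonal stratum) month
    boundaries.  Out-migrants may return after a gap drawn from the
    configured mixture, opening a new episode in the same location.
    """
    rng = np.random.default_rng(config.seed)
    d0, d1 = config.window
    end_date_inc = config.study_end

    loc_effects = rng.normal(0.0, config.location_effect_sd, config.n_locations)
    loc_mult = np.exp(loc_effects)

    H = config.hazard_array()
    band_breaks = list(config.age_grid.day_breaks) + [10**9]
    pstarts = list(config.periods.start_days)
    pends = pstarts[1:] + [d1]
    mstarts = month_starts(d0, d1)
    m_list = mstarts.tolist() + [d1 + 31]
    _, m_months = year_month(mstarts)
    m_months = m_months.tolist()
    profile = config.seasonal_profile()
    sb = (
        list(config.age_grid.labels).index(config.seasonal_band)
        if config.seasonal_amplitude != 1.0 and config.seasonal_band in config.age_grid.labels
        else -1
    )
    sp = set(config.seasonal_periods)
    out_rate_d = config.outmigration_rate / DAYS_PER_YEAR

    # --- assemble the entry roster (deterministic order) ---
    entries: list[tuple[int, int, int, int, str]] = []  # birth_day, sex, loc, entry_day, reason
    ages = _stationary_ages(config, rng, config.n_baseline)
    sexes = rng.integers(0, 2, config.n_baseline)
    locs = rng.integers(0, config.n_locations, config.n_baseline)
    for a, s, l in zip(ages, sexes, locs):
        entries.append((d0 - int(a), int(s), int(l), d0, "enumeration"))

    birth_rows = []
    for mi in range(len(mstarts)):
        m_lo, m_hi = int(mstarts[mi]), int(m_list[mi + 1]) if mi + 1 < len(mstarts) else d1
        m_hi = min(m_hi, d1)
        ndays = m_hi - m_lo
        if ndays <= 0:
            continue
        n_b = rng.poisson(config.birth_rate * config.n_baseline * ndays / DAYS_PER_YEAR)
        for day in np.sort(rng.integers(m_lo, m_hi, n_b)):
            s = int(rng.integers(0, 2))
            l = int(rng.integers(0, config.n_locations))
            entries.append((int(day), s, l, int(day), "birth"))
            birth_rows.append((int(day), l, len(entries) - 1, SEXES[s]))
        n_i = rng.poisson(config.inmigration_rate * config.n_baseline * ndays / DAYS_PER_YEAR)
        for day in np.sort(rng.integers(m_lo, m_hi, n_i)):
            age_d = int(round(rng.random() * config.inmigrant_max_age * DAYS_PER_YEAR))
            s = int(rng.integers(0, 2))
            l = int(rng.integers(0, config.n_locations))
            entries.append((int(day) - age_d, s, l, int(day), "in-migration"))

    # --- simulate each individual's event history ---
    ep_rows: list[tuple] = []
    dod: dict[int, int] = {}
    runif = rng.random
    log = math.log
    g_short_lo, g_short_hi = config.gap_short_range
    g_long_lo, g_long_hi = config.gap_long_range

    for iid, (birth, s, loc, entry, reason) in enumerate(entries):
        lm = loc_mult[loc]
        t = float(entry)
        ep_start, ep_reason = entry, reason
        while True:
            if t >= d1:
                ep_rows.append((iid, loc, ep_start, ep_reason, d1, "study-end"))
                break
            age = t - birth
            b = bisect_right(band_breaks, age) - 1
            p = bisect_right(pstarts, t) - 1
            seg_end = min(birth + band_breaks[b + 1], pends[p], d1)
            mult = 1.0
            if b == sb and p in sp:
                mi = bisect_right(m_list, t) - 1
                seg_end = min(seg_end, m_list[mi + 1])
                mult = profile[m_months[mi] - 1]
            hd = H[b, s, p] * lm * mult / DAYS_PER_YEAR
            h = hd + out_rate_d
            if h > 0.0:
                w = -log(1.0 - runif()) / h
            else:
                w = float("inf")
            if t + w < seg_end:
                te = t + w
                ev_day = int(te) + 1
                if runif() < hd / h:  # death
                    ep_rows.append((iid, loc, ep_start, ep_reason, ev_day, "death"))
                    dod[iid] = ev_day
                    break
                # out-migration, possibly with return
                ep_rows.append((iid, loc, ep_start, ep_reason, ev_day, "out-migration"))
                if runif() < config.return_prob:
                    if runif() < config.gap_short_frac:
                        gap = g_short_lo + int(runif() * (g_short_hi - g_short_lo + 1))
                    else:
                        gap = g_long_lo + int(runif() * (g_long_hi - g_long_lo + 1))
                    re_day = ev_day + gap
                    if re_day < d1:
                        ep_start, ep_reason = re_day, "in-migration"
                        t = float(re_day)
                        continue
                break
            t = float(seg_end)

    individuals = pd.DataFrame(
        {
            "individual_id": np.arange(len(entries)),
            "sex": [SEXES[e[1]] for e in entries],
            "dob": from_day(np.array([e[0] for e in entries])),
            "dod": from_day(
                np.array([dod.get(i, -(10**6)) for i in range(len(entries))])
            ),
        }
    )
    individuals.loc[[i not in dod for i in range(len(entries))], "dod"] = pd.NaT

    ep = pd.DataFrame(
        ep_rows,
        columns=["individual_id", "location_id", "start_day", "start_reason", "end_day", "end_reason"],
    )
    episodes = pd.DataFrame(
        {
            "individual_id": ep["individual_id"],
            "location_id": ep["location_id"],
            "start_date": from_day(ep["start_day"].values),
            "start_reason": ep["start_reason"],
            "end_date": from_day(
                np.where(ep["end_reason"] == "study-end", to_day(end_date_inc), ep["end_day"].values)
            ),
            "end_reason": ep["end_reason"],
        }
    )
    live_births = pd.DataFrame(
        birth_rows, columns=["day", "location_id", "individual_id", "sex"]
    )
    live_births.insert(0, "date", from_day(live_births.pop("day").values))

    return TruePopulation(
        individuals=individuals,
        episodes=episodes,
        live_births=live_births,
        truth={"config": config, "location_effects": loc_effects},
    )


def expected_rate(
    config: SimConfig,
    age_band: str,
    sex: str,
    period: int = 0,
    location_effect: float = 0.0,
    months=None,
) -> float:
    """Analytic death rate (per 1000 person-years) implied by the config.

    The product of the base hazard for the stratum, the location multiplier
    ``exp(location_effect)`` and the seasonal multiplier averaged over the
    requested ``months`` (all twelve by default, where the profile averages
    to one).
    """
    key = (age_band, sex, period)
    if key not in config.base_hazard:
        raise KeyError(f"unknown stratum {key}")
    base = config.base_hazard[key]
    seas = 1.0
    if (
        config.seasonal_amplitude != 1.0
        and age_band == config.seasonal_band
        and period in config.seasonal_periods
    ):
        prof = config.seasonal_profile()
        idx = np.asarray(months if months is not None else np.arange(1, 13)) - 1
        seas = float(prof[idx].mean())
    return 1000.0 * base * math.exp(location_effect) * seas
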
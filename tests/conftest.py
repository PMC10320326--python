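import numpy as np
import pandas as pd
import pytest

import demosurv as ds


@pytest.fixture(scope="session")
def small_pop():
    """A small but complete synthetic cohort shared across tests."""
    cfg = ds.SimConfig(n_baseline=2500, seed=7)
    return cfg, ds.simulate_population(cfg)


def episodes_frame(rows):
    """Build an episode table from (id, loc, start, sreason, end, ereason) tuples."""
    return pd.DataFrame(
        rows,
        columns=["individual_id", "location_id", "start_date", "start_reason", "end_date", "end_reason"],
    )


def individuals_frame(rows):
    """Build an individual table from (id, sex, dob, dod) tuples."""
    return pd.DataFrame(rows, columns=["individual_id", "sex", "dob", "dod"])


def brute_force_cells(intervals, individuals, grid, periods, by_month=False):
    """Day-by-day classification of every exposed calendar day into a Lexis
    cell; the independent oracle for the vectorized splitter."""
    from demosurv.ages import DAYS_PER_YEAR, to_days, year_month

    ind = individuals.set_index("individual_id")
    days: dict[tuple, int] = {}
    deaths: dict[tuple, int] = {}

    def key_of(day, birth, sex):
        band = grid.labels[int(grid.band_of(day - birth))]
        per = periods.labels[int(periods.period_of(day))]
        key = (band, sex, per)
        if by_month:
            y, m = year_month(day)
            key += (int(y), int(m))
        return key

    for row in intervals.itertuples():
        birth = int(to_days([ind.loc[row.individual_id, "dob"]])[0])
        sex = ind.loc[row.individual_id, "sex"]
        for day in range(row.entry_day, row.exit_day):
            k = key_of(day, birth, sex)
            days[k] = days.get(k, 0) + 1
        if row.event:
            k = key_of(row.exit_day - 1, birth, sex)
            deaths[k] = deaths.get(k, 0) + 1

    keys = sorted(set(days) | set(deaths))
    cols = ["age_band", "sex", "period"] + (["year", "month"] if by_month else [])
    out = pd.DataFrame([dict(zip(cols, k)) for k in keys])
    out["deaths"] = [deaths.get(k, 0) for k in keys]
    out["pyo"] = [days.get(k, 0) / DAYS_PER_YEAR for k in keys]
    return out
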
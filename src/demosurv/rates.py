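"""Mortality rates, ratios, declines, direct standardization, Whipple's index."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class RateEstimate:
    """A mortality rate per 1000 person-years with an exact Poisson CI."""

    deaths: int
    pyo: float
    rate: float       # per 1000 PYO, full precision
    ci_low: float
    ci_high: float

    @property
    def display(self) -> float:
        """The rate at the conventional 1-decimal reporting precision."""
        return round(self.rate, 1)


@dataclass(frozen=True)
class MortalityRatio:
    deaths: int
    live_births: int
    ratio: float  # per 1000 live births


def mortality_rate(deaths: int, pyo: float, alpha: float = 0.05) -> RateEstimate:
    """Deaths per 1000 person-years of observation with a Garwood CI.

    The confidence interval is the exact (Garwood) Poisson interval on the
    death count, scaled by the person-time denominator.
    """
    if pyo <= 0:
        raise ValueError("pyo must be positive")
    if deaths < 0 or deaths != int(deaths):
        raise ValueError("deaths must be a non-negative integer")
    d = int(deaths)
    lo = stats.chi2.ppf(alpha / 2, 2 * d) / 2 if d > 0 else 0.0
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * (d + 1)) / 2
    scale = 1000.0 / pyo
    return RateEstimate(d, pyo, d * scale, lo * scale, hi * scale)


def mortality_ratio(deaths: int, live_births: int) -> MortalityRatio:
    """Deaths per 1000 live births in the same calendar period.

    Used for under-5 indicators (IMR, U5MR) where risk time is not
    quantified; can be confounded by changing birth rates because the
    numerator deaths are not all drawn from the denominator cohort.
    """
    if live_births <= 0:
        raise ValueError("live_births must be positive")
    return MortalityRatio(int(deaths), int(live_births), 1000.0 * deaths / live_births)


def percent_decline(rate_from: float, rate_to: float) -> float:
    """Percent decline 100*(1 - rate_to/rate_from); negative if rates rose."""
    if rate_from <= 0:
        raise ValueError("rate_from must be positive")
    return 100.0 * (1.0 - rate_to / rate_from)


def direct_standardize(stratum_rates: dict, reference: dict) -> float:
    """Directly standardized rate: sum of stratum rates weighted by a
    reference age-sex structure (weights normalized to 1).

    Parameters
    ----------
    stratum_rates
        Map stratum key -> rate (float or :class:`RateEstimate`).
    reference
        Map stratum key -> positive reference person-count or weight.
    """
    missing = [k for k, w in reference.items() if w > 0 and k not in stratum_rates]
    if missing:
        raise KeyError(f"stratum rates missing for reference strata: {missing}")
    if any(w < 0 for w in reference.values()):
        raise ValueError("reference weights must be non-negative")
    total = float(sum(reference.values()))
    if total <= 0:
        raise ValueError("reference weights must have positive sum")
    out = 0.0
    for k, w in reference.items():
        if w == 0:
            continue
        r = stratum_rates[k]
        out += (w / total) * (r.rate if isinstance(r, RateEstimate) else float(r))
    return out


def whipple_index(ages) -> float:
    """Whipple's index of age heaping on terminal digits 0 and 5.

    Restricted to reported ages 23-62 inclusive (the classical UN window):
    500 * (count of ages divisible by 5) / (total count).  100 means no
    heaping, 500 means every age ends in 0 or 5.
    """
    a = np.asarray(ages)
    if np.any(a < 0) or not np.issubdtype(a.dtype, np.integer):
        a = a.astype(float)
        if np.any(a < 0) or np.any(a != np.round(a)):
            raise ValueError("ages must be non-negative integers (years)")
        a = a.astype(int)
    win = a[(a >= 23) & (a <= 62)]
    if len(win) == 0:
        raise ValueError("no reported ages in the 23-62 window; index undefined")
    return 500.0 * float(np.sum(win % 5 == 0)) / len(win)


def rate_table(cells: pd.DataFrame, by: list[str]) -> pd.DataFrame:
    """Deaths, PYO and rate per 1000 for each stratum of a Lexis cell table."""
    from .persontime import tabulate

    tab = tabulate(cells, by)
    est = [mortality_rate(int(d), p) for d, p in zip(tab["deaths"], tab["pyo"])]
    tab["rate"] = [e.rate for e in est]
    tab["ci_low"] = [e.ci_low for e in est]
    tab["ci_high"] = [e.ci_high for e in est]
    return tab
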
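"""Monthly mortality series, STL decomposition and count-model tests.

The monthly rate series per age group is decomposed additively (on the
per-1000-PYO rate scale by default) into trend + seasonal + remainder with
STL (Seasonal and Trend decomposition using LOESS); peak and trough months
come from the average seasonal component.  Period differences and
seasonality are tested with negative-binomial (gamma-Poisson) count models
with a log person-time offset, falling back to Poisson when the dispersion
estimate sits on the zero boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tsa.seasonal import STL

logger = logging.getLogger(__name__)


@dataclass
class MonthlySeries:
    """Contiguous monthly deaths/PYO/rate series for one age group."""

    data: pd.DataFrame  # index: monthly PeriodIndex; columns deaths, pyo, rate
    age_group: str = "all"

    @property
    def rate(self) -> pd.Series:
        return self.data["rate"]


@dataclass
class DecompositionResult:
    trend: pd.Series
    seasonal: pd.Series
    remainder: pd.Series
    peak_month: int
    trough_month: int

    def seasonal_by_month(self) -> pd.Series:
        """Average seasonal component per calendar month (1..12)."""
        return self.seasonal.groupby(self.seasonal.index.month).mean()


@dataclass
class CountModelResult:
    model: str                  # "negative-binomial" or "poisson"
    params: pd.Series
    bse: pd.Series
    rate_ratios: pd.Series      # vs the reference (first) period
    llf: float
    pvalues: pd.Series
    lr_stat: float | None = None
    lr_df: int | None = None
    lr_p: float | None = None


def build_monthly_series(cells: pd.DataFrame, age_group: str = "all") -> MonthlySeries:
    """Sum a month-keyed Lexis cell table into a monthly rate series.

    ``age_group`` may be "all" or one of the cell table's age-band labels.
    The resulting index must be contiguous (every month observed).
    """
    if not {"year", "month"} <= set(cells.columns):
        raise ValueError("cell table lacks year/month keys; split with by_month=True")
    df = cells if age_group == "all" else cells[cells["age_band"] == age_group]
    if len(df) == 0:
        raise ValueError(f"no cells for age group {age_group!r}")
    g = df.groupby(["year", "month"], observed=True)[["deaths", "pyo"]].sum().reset_index()
    idx = pd.PeriodIndex(
        pd.to_datetime(dict(year=g["year"], month=g["month"], day=1)), freq="M"
    )
    out = pd.DataFrame({"deaths": g["deaths"].values, "pyo": g["pyo"].values}, index=idx).sort_index()
    full = pd.period_range(out.index[0], out.index[-1], freq="M")
    if len(out) != len(full):
        missing = full.difference(out.index)
        raise ValueError(f"monthly series not contiguous; missing {list(missing[:5])}")
    if (out["pyo"] <= 0).any():
        raise ValueError("months with zero person-years in series")
    out["rate"] = 1000.0 * out["deaths"] / out["pyo"]
    return MonthlySeries(out, age_group)


def stl_decompose(
    series: MonthlySeries,
    seasonal_window: int = 121,
    robust: bool = False,
    log_scale: bool = False,
) -> DecompositionResult:
    """Additive STL decomposition of the monthly rate series.

    ``seasonal_window`` is the LOESS span of the seasonal smoother in
    months (odd); the large default effectively averages the seasonal
    pattern across years ("periodic" behaviour).  With ``log_scale`` the
    decomposition is applied to log(rate + epsilon) instead.
    """
    y = series.rate.astype(float)
    if len(y) < 24:
        raise ValueError("need at least two whole years of monthly data")
    if log_scale:
        y = np.log(y + 1e-6)
    if seasonal_window % 2 == 0:
        seasonal_window += 1
    res = STL(y, period=12, seasonal=seasonal_window, robust=robust).fit()
    seas = pd.Series(res.seasonal, index=y.index)
    by_month = seas.groupby(seas.index.month).mean()
    peak, trough = _extreme_months(by_month)
    return DecompositionResult(
        trend=pd.Series(res.trend, index=y.index),
        seasonal=seas,
        remainder=pd.Series(res.resid, index=y.index),
        peak_month=peak,
        trough_month=trough,
    )


def _extreme_months(by_month: pd.Series) -> tuple[int, int]:
    vals = by_month.values.astype(float)
    mx, mn = vals.max(), vals.min()
    scale = max(np.abs(vals).max(), 1.0)
    if mx - mn <= 1e-8 * scale:
        logger.warning("flat seasonal component; peak/trough tie broken to earliest month")
        first = int(by_month.index[0])
        return first, first
    peak = int(by_month.index[np.argmax(vals)])
    trough = int(by_month.index[np.argmin(vals)])
    return peak, trough


def peak_trough_months(result: DecompositionResult) -> tuple[int, int]:
    """Months (1..12) of the max and min average seasonal component."""
    return _extreme_months(result.seasonal_by_month())


def _fit_count_model(y, X, offset, family: str):
    """NB2 ML fit with Poisson fallback at the dispersion boundary.

    NB nests Poisson as alpha -> 0, so a valid NB fit cannot have a lower
    log-likelihood than the Poisson GLM; fits that do (or whose dispersion
    collapses to the boundary) fall back to Poisson with a logged note.
    """
    pois = sm.GLM(y, X, offset=offset, family=sm.families.Poisson()).fit()
    if family == "nb":
        import warnings

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                nb = sm.NegativeBinomial(y, X, offset=offset).fit(disp=0, maxiter=200)
            alpha = float(np.asarray(nb.params)[-1])
            if np.isfinite(nb.llf) and alpha > 1e-4 and nb.llf >= pois.llf - 1e-6:
                return nb, "negative-binomial"
            logger.info("NB dispersion at boundary (alpha=%.2g); falling back to Poisson", alpha)
        except Exception as err:  # noqa: BLE001 - any optimizer failure falls back
            logger.info("NB fit failed (%s); falling back to Poisson", err)
    return pois, "poisson"


def period_effect_test(yearly: pd.DataFrame, family: str = "nb") -> CountModelResult:
    """Test period differences in yearly death counts with an offset model.

    ``yearly`` needs columns ``year, deaths, pyo, period``; the model is
    count ~ C(period) with offset log(pyo), reference = first period.
    Reported rate ratios compare each period with the reference; the LR
    test compares against the intercept-only model.
    """
    if (yearly["deaths"] % 1 != 0).any():
        raise ValueError("death counts must be integers")
    periods = pd.Categorical(yearly["period"]).categories
    if len(periods) < 2:
        raise ValueError("need at least two periods")
    if yearly.groupby("period", observed=True).size().min() < 2:
        raise ValueError("need at least two years per period")

    dummies = pd.get_dummies(yearly["period"], drop_first=True, dtype=float)
    X = sm.add_constant(dummies)
    offset = np.log(yearly["pyo"].values.astype(float))
    y = yearly["deaths"].values.astype(float)
    fit, label = _fit_count_model(y, X, offset, family)
    X0 = np.ones((len(y), 1))
    fit0, _ = _fit_count_model(y, X0, offset, "poisson" if label == "poisson" else family)
    k = len(periods) - 1
    lr = max(0.0, 2.0 * (fit.llf - fit0.llf))
    names = list(X.columns)
    params = pd.Series(np.asarray(fit.params)[: len(names)], index=names)
    bse = pd.Series(np.asarray(fit.bse)[: len(names)], index=names)
    pv = pd.Series(np.asarray(fit.pvalues)[: len(names)], index=names)
    rr = np.exp(params.drop("const"))
    rr[str(periods[0])] = 1.0
    return CountModelResult(
        label, params, bse, rr, float(fit.llf), pv, lr, k, float(stats.chi2.sf(lr, k))
    )


def seasonality_interaction_test(monthly: pd.DataFrame, family: str = "nb") -> CountModelResult:
    """Likelihood-ratio test of month x period interaction in monthly counts.

    ``monthly`` needs columns ``month, period, deaths, pyo``.  Compares
    count ~ month + period against count ~ month * period (both with a
    log-PYO offset); a significant interaction means the seasonal profile
    differs across periods.
    """
    need = {"month", "period", "deaths", "pyo"}
    if not need <= set(monthly.columns):
        raise ValueError(f"monthly table needs columns {sorted(need)}")
    design = monthly.groupby(["month", "period"], observed=True).size()
    months = monthly["month"].unique()
    periods = pd.Categorical(monthly["period"]).categories
    empty = [
        (m, p) for m in sorted(months) for p in periods if (m, p) not in design.index
    ]
    if empty:
        raise ValueError(f"empty month x period design cells: {empty[:6]}")

    mo = pd.get_dummies(monthly["month"].astype("category"), drop_first=True, prefix="m", dtype=float)
    pe = pd.get_dummies(monthly["period"], drop_first=True, prefix="p", dtype=float)
    X_main = sm.add_constant(pd.concat([mo, pe], axis=1))
    inter = pd.DataFrame(
        {
            f"{mc}:{pc}": mo[mc] * pe[pc]
            for mc in mo.columns
            for pc in pe.columns
        }
    )
    X_full = pd.concat([X_main, inter], axis=1)
    offset = np.log(monthly["pyo"].values.astype(float))
    y = monthly["deaths"].values.astype(float)

    fit_full, label = _fit_count_model(y, X_full, offset, family)
    fit_main, _ = _fit_count_model(y, X_main, offset, "poisson" if label == "poisson" else family)
    df = inter.shape[1]
    lr = max(0.0, 2.0 * (fit_full.llf - fit_main.llf))
    names = list(X_full.columns)
    params = pd.Series(np.asarray(fit_full.params)[: len(names)], index=names)
    pv = pd.Series(np.asarray(fit_full.pvalues)[: len(names)], index=names)
    bse = pd.Series(np.asarray(fit_full.bse)[: len(names)], index=names)
    pe_cols = [c for c in params.index if c.startswith("p_")]
    rr = np.exp(params[pe_cols]) if pe_cols else pd.Series(dtype=float)
    return CountModelResult(
        label, params, bse, rr, float(fit_full.llf), pv, lr, df, float(stats.chi2.sf(lr, df))
    )
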
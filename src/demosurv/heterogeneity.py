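"""Geographic heterogeneity of mortality: random-effects Poisson model,
boundary LR test, SD-equality z-test, quantile map classes and per-location
Kaplan-Meier medians.

The central quantity is the standard deviation of location-level random
intercepts in a log-link Poisson model of death counts with a person-time
offset, adjusted for age band and sex.  ``exp(1.96 * SD)`` approximates the
multiplicative interval about the median location rate containing 95% of
location-specific rates.

The mixed model is estimated by maximum likelihood with an adaptive
Gauss-Hermite quadrature over the location intercepts: with a log link and
Poisson counts, each location's integrand depends on its data only through
the death total and the offset-weighted sum of fixed-effect means, so the
per-location integral is one-dimensional and cheap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, stats
from scipy.special import gammaln

logger = logging.getLogger(__name__)

_GH_NODES = 15


@dataclass
class PoissonMixedFit:
    """ML fit of a Poisson GLMM with one Gaussian random intercept level."""

    beta: np.ndarray
    beta_names: list[str]
    sigma: float          # SD of the location random intercepts (log scale)
    sigma_se: float       # delta-method SE (nan at the boundary)
    llf: float
    llf_fixed: float      # same fixed effects, no random intercept
    converged: bool
    n_groups: int


@dataclass
class HeterogeneityResult:
    period: str
    sd_log_rates: float
    sd_se: float
    approx95: float       # exp(1.96 * sd): 95% multiplicative span about the median rate
    lr_stat: float
    lr_p: float
    sd_diff: float | None = None   # vs the reference period's SD
    z_p: float | None = None


def _group_reduce(y, eta, groups):
    """Per-group death totals and sums of exp(eta) (fixed-effect means)."""
    k = groups.max() + 1
    Y = np.bincount(groups, weights=y, minlength=k)
    S = np.bincount(groups, weights=np.exp(eta), minlength=k)
    return Y, S


def _mixed_nll(params, y, X, offset, groups, gh_x, gh_w):
    """Negative log-likelihood via adaptive Gauss-Hermite quadrature.

    Each location contributes log INT exp(Y*u - S*exp(u)) N(u; 0, s^2) du
    plus the u-free Poisson terms; the integral is centred and scaled at
    the posterior mode of u (Laplace point) before quadrature.
    """
    beta, sigma = params[:-1], params[-1]
    eta = X @ beta + offset
    Y, S = _group_reduce(y, eta, groups)
    base = float(np.sum(y * eta - gammaln(y + 1)))

    if sigma < 1e-8:
        return -(base - float(np.sum(S)))

    inv_v = 1.0 / sigma**2
    # Newton for the mode of h(u) = Y u - S e^u - u^2 / (2 s^2)
    u = np.zeros_like(Y)
    for _ in range(50):
        eu = np.exp(u)
        g = Y - S * eu - u * inv_v
        hpp = -S * eu - inv_v
        step = g / hpp
        u -= np.clip(step, -1.0, 1.0)
        if np.max(np.abs(g)) < 1e-10:
            break
    eu = np.exp(u)
    tau = 1.0 / np.sqrt(S * eu + inv_v)

    # adaptive GH: u_k = mode + sqrt(2) tau x_k
    uk = u[:, None] + np.sqrt(2.0) * tau[:, None] * gh_x[None, :]
    hk = (
        Y[:, None] * uk
        - S[:, None] * np.exp(uk)
        - 0.5 * uk**2 * inv_v
        - np.log(sigma)
        - 0.5 * np.log(2 * np.pi)
    )
    lse = hk + gh_x[None, :] ** 2 + np.log(gh_w)[None, :]
    m = lse.max(axis=1)
    log_int = m + np.log(np.sum(np.exp(lse - m[:, None]), axis=1)) + 0.5 * np.log(2.0) + np.log(tau)
    return -(base + float(np.sum(log_int)))


def _design(cells: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    ab = pd.get_dummies(cells["age_band"], drop_first=True, prefix="age", dtype=float)
    sx = pd.get_dummies(cells["sex"], drop_first=True, prefix="sex", dtype=float)
    X = sm.add_constant(pd.concat([ab, sx], axis=1))
    return X.values.astype(float), list(X.columns)


def fit_poisson_mixed(
    cells: pd.DataFrame, gh_nodes: int = _GH_NODES
) -> PoissonMixedFit:
    """Fit the location random-intercept Poisson model to a Lexis cell table.

    ``cells`` needs columns ``age_band, sex, location_id, deaths, pyo``
    (one period's data); zero-PYO cells are dropped.
    """
    df = cells[cells["pyo"] > 0].reset_index(drop=True)
    locs = pd.Categorical(df["location_id"])
    if len(locs.categories) < 2:
        raise ValueError("need at least two locations")
    groups = locs.codes.astype(int)
    y = df["deaths"].values.astype(float)
    if np.any(y % 1 != 0):
        raise ValueError("death counts must be integers")
    X, names = _design(df)
    offset = np.log(df["pyo"].values.astype(float))

    glm = sm.GLM(y, X, offset=offset, family=sm.families.Poisson()).fit()
    llf_fixed = float(glm.llf)

    gh_x, gh_w = hermgauss(gh_nodes)
    x0 = np.append(np.asarray(glm.params), 0.1)
    bounds = [(None, None)] * X.shape[1] + [(0.0, 3.0)]
    res = optimize.minimize(
        _mixed_nll,
        x0,
        args=(y, X, offset, groups, gh_x, gh_w),
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    if not res.success:
        logger.warning("mixed-model optimizer: %s", res.message)
    sigma = float(res.x[-1])
    llf = -float(res.fun)

    sigma_se = float("nan")
    if sigma > 1e-4:
        H = _num_hessian(
            lambda p: _mixed_nll(p, y, X, offset, groups, gh_x, gh_w), res.x
        )
        try:
            cov = np.linalg.inv(H)
            if cov[-1, -1] > 0:
                sigma_se = float(np.sqrt(cov[-1, -1]))
        except np.linalg.LinAlgError:
            pass

    return PoissonMixedFit(
        beta=res.x[:-1],
        beta_names=names,
        sigma=sigma,
        sigma_se=sigma_se,
        llf=llf,
        llf_fixed=llf_fixed,
        converged=bool(res.success),
        n_groups=len(locs.categories),
    )


def _num_hessian(f, x, eps=1e-4):
    n = len(x)
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            xi, xj = np.zeros(n), np.zeros(n)
            xi[i] = eps
            xj[j] = eps
            H[i, j] = H[j, i] = (
                f(x + xi + xj) - f(x + xi - xj) - f(x - xi + xj) + f(x - xi - xj)
            ) / (4 * eps * eps)
    return H


def lr_test_between_location(llf_mixed: float, llf_fixed: float, boundary: bool = True) -> tuple[float, float]:
    """LR test of the location random effect.

    Under the null the SD sits on the parameter-space boundary, so the
    reference distribution is the 50:50 mixture of a point mass at zero and
    chi-square(1); ``boundary=False`` uses plain chi-square(1).
    """
    stat = max(0.0, 2.0 * (llf_mixed - llf_fixed))
    p = stats.chi2.sf(stat, 1)
    return stat, float(0.5 * p if boundary else p)


def fit_location_random_effect(
    cells: pd.DataFrame, period: str = "", reference: "HeterogeneityResult | None" = None
) -> HeterogeneityResult:
    """One period's heterogeneity summary: SD of location log rates,
    exp(1.96*SD), boundary LR test, and (if a reference period result is
    given) the SD difference and z-test against it."""
    fit = fit_poisson_mixed(cells)
    stat, p = lr_test_between_location(fit.llf, fit.llf_fixed)
    out = HeterogeneityResult(
        period=period,
        sd_log_rates=fit.sigma,
        sd_se=fit.sigma_se,
        approx95=float(np.exp(1.96 * fit.sigma)),
        lr_stat=stat,
        lr_p=p,
    )
    if reference is not None:
        out.sd_diff = reference.sd_log_rates - fit.sigma
        if all(np.isfinite(se) and se > 0 for se in (reference.sd_se, fit.sigma_se)):
            _, out.z_p = sd_equality_ztest(
                reference.sd_log_rates, reference.sd_se, fit.sigma, fit.sigma_se
            )
        else:
            logger.warning(
                "SD estimate at the boundary in %s or reference; z-test undefined", period
            )
            out.z_p = float("nan")
    return out


def sd_equality_ztest(sd_a: float, se_a: float, sd_b: float, se_b: float) -> tuple[float, float]:
    """Two-sided Normal z-test of equality of two random-effect SDs.

    Returns (sd_a - sd_b, p).  SEs come from the fitted models via the
    delta method on the variance estimate.
    """
    if not (np.isfinite(se_a) and np.isfinite(se_b)) or se_a <= 0 or se_b <= 0:
        raise ValueError("both standard errors must be positive and finite")
    diff = sd_a - sd_b
    z = diff / np.hypot(se_a, se_b)
    return float(diff), float(2.0 * stats.norm.sf(abs(z)))


@dataclass
class QuantileClassification:
    k: int
    breaks: np.ndarray                    # k-1 pooled-quantile cut values
    assignment: pd.DataFrame              # location, period, rate, class_


def quantile_classes(rates: pd.DataFrame, k: int = 5) -> QuantileClassification:
    """Equal-count (quantile) map classes from the pooled rate series.

    Breaks sit at the 1/k .. (k-1)/k empirical quantiles of *all*
    location-period rates pooled across periods, and the one classification
    is applied to every period's map; each rate gets the lowest class whose
    upper break is >= the rate.  ``rates`` needs columns
    ``location_id, period, rate``.
    """
    if k < 2:
        raise ValueError("need at least two classes")
    vals = rates["rate"].values.astype(float)
    if np.ptp(vals) == 0:
        logger.warning("all rates identical; degenerate single-class map")
    breaks = np.quantile(vals, np.arange(1, k) / k)
    cls = np.searchsorted(breaks, vals, side="left") + 1
    out = rates[["location_id", "period", "rate"]].copy()
    out["class_"] = cls
    return QuantileClassification(k, breaks, out)


def median_age_at_death_by_location(
    intervals: pd.DataFrame, individuals: pd.DataFrame, periods=None
) -> pd.DataFrame:
    """Per-location (and optionally per-period) KM median age at death.

    Reuses the left-truncated KM fit per location; returns a tidy table of
    medians plus, per period, the max-min span across locations.
    """
    from .ages import DAYS_PER_YEAR, to_days
    from .persontime import _split_at
    from .survival import km_fit

    df = intervals.copy()
    if periods is not None:
        # period KM uses only risk time inside the period; entry is the age
        # attained at the later of period start and cohort entry
        df = _split_at(df, periods.boundaries(), np.zeros(len(df), dtype=int))
    ind = individuals.set_index("individual_id")
    birth = to_days(ind.loc[df["individual_id"], "dob"].values)
    df["entry_age"] = (df["entry_day"].values - birth) / DAYS_PER_YEAR
    df["exit_age"] = (df["exit_day"].values - birth) / DAYS_PER_YEAR
    if periods is not None:
        df["period"] = pd.Categorical.from_codes(
            periods.period_of(df["entry_day"].values), categories=list(periods.labels)
        )
        keys = ["period", "location_id"]
    else:
        keys = ["location_id"]
    rows = []
    for key, grp in df.groupby(keys, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        km = km_fit(grp["entry_age"], grp["exit_age"], grp["event"])
        rows.append(dict(zip(keys, key)) | {"median_age": km.median})
    out = pd.DataFrame(rows)
    if "period" in out.columns:
        span = out.groupby("period", observed=True)["median_age"].agg(lambda m: m.max() - m.min())
        out = out.merge(span.rename("period_span"), on="period")
    return out


def median_span(medians) -> float:
    """Max - min of a collection of medians (the reported location span)."""
    m = np.asarray(medians, dtype=float)
    return float(np.nanmax(m) - np.nanmin(m))
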
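"""End-to-end analysis pipeline with stable file contracts.

Stages: simulate (or load) episode tables -> validate -> person-time on the
Lexis grid -> rate tables and declines -> life tables and KM medians (under
both risk-time rules) -> seasonality -> geographic heterogeneity.  All
interchange is CSV with ISO-8601 dates; every run writes a manifest with
the config hash, seed and row counts so reruns are auditable and, for a
fixed seed, byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ages import ANALYSIS_GRID, LIFETABLE_GRID, AgeGrid, PeriodBreaks, to_day, to_days
from .heterogeneity import (
    fit_location_random_effect,
    median_age_at_death_by_location,
    quantile_classes,
)
from .persontime import (
    END_REASONS,
    START_REASONS,
    DataIntegrityError,
    build_risk_intervals,
    split_lexis,
    tabulate,
)
from .rates import direct_standardize, mortality_rate, percent_decline, rate_table
from .seasonality import build_monthly_series, period_effect_test, stl_decompose
from .simulate import SimConfig, simulate_population
from .survival import compare_risk_time_variants, km_from_intervals, life_table_from_cells

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Configuration of one pipeline run (YAML-loadable)."""

    study_start: str = "2003-01-01"
    study_end: str = "2018-12-31"
    period_years: tuple[int, ...] = (2003, 2007, 2011, 2015)
    rule: str = "standard"
    seed: int = 0
    n_baseline: int = 20_000
    outdir: str = "runs/demo"
    reference_structure: str | None = None   # CSV age_band,sex,weight; default: own mid-study PYO
    stages: tuple[str, ...] = ("rates", "lifetable", "season", "heterogeneity")
    sim_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("period_years", "stages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    @property
    def periods(self) -> PeriodBreaks:
        end_year = pd.Timestamp(self.study_end).year + 1
        return PeriodBreaks.from_years(list(self.period_years), end_year)

    @property
    def window(self) -> tuple[int, int]:
        return to_day(self.study_start), to_day(self.study_end) + 1

    def sim_config(self) -> SimConfig:
        return SimConfig(
            study_start=self.study_start,
            study_end=self.study_end,
            n_baseline=self.n_baseline,
            periods=self.periods,
            seed=self.seed,
            **self.sim_overrides,
        )


def validate_inputs(
    episodes: pd.DataFrame, individuals: pd.DataFrame, strict: bool = False
) -> dict:
    """Schema/integrity checks on episode and individual tables.

    Returns a report dict mapping violation class -> list of offending
    identifiers (empty lists when clean).  With ``strict`` a non-empty
    report raises :class:`DataIntegrityError`.
    """
    report: dict[str, list] = {
        "duplicate_individual_ids": [],
        "unknown_start_reason": [],
        "unknown_end_reason": [],
        "unparseable_dates": [],
        "overlapping_episodes": [],
        "episode_ends_before_start": [],
        "death_outside_episodes": [],
    }
    dup = individuals["individual_id"][individuals["individual_id"].duplicated()]
    report["duplicate_individual_ids"] = dup.unique().tolist()
    report["unknown_start_reason"] = sorted(
        set(episodes["start_reason"].dropna()) - START_REASONS
    )
    report["unknown_end_reason"] = sorted(set(episodes["end_reason"].dropna()) - END_REASONS)

    ep = episodes.copy()
    for col in ("start_date", "end_date"):
        parsed = pd.to_datetime(ep[col], errors="coerce")
        bad = ep[col].notna() & parsed.isna()
        if bad.any():
            report["unparseable_dates"] += ep.loc[bad, "individual_id"].tolist()
        ep[col] = parsed

    ok = ep["start_date"].notna()
    ep = ep[ok].sort_values(["individual_id", "start_date"], kind="mergesort")
    closed = ep["end_date"].notna()
    before = closed & (ep["end_date"] < ep["start_date"])
    report["episode_ends_before_start"] = ep.loc[before, "individual_id"].unique().tolist()
    same = ep["individual_id"].values[1:] == ep["individual_id"].values[:-1]
    prev_end = ep["end_date"].values[:-1]
    ovl = same & pd.notna(prev_end) & (ep["start_date"].values[1:] < prev_end)
    report["overlapping_episodes"] = pd.unique(ep["individual_id"].values[1:][ovl]).tolist()

    died = individuals[pd.notna(individuals.get("dod"))]
    if len(died):
        death_eps = ep[ep["end_reason"] == "death"].set_index("individual_id")["end_date"]
        for iid, d in zip(died["individual_id"], pd.to_datetime(died["dod"])):
            if iid not in death_eps.index or pd.Timestamp(death_eps.loc[iid]) != d:
                report["death_outside_episodes"].append(iid)

    n_bad = sum(len(v) for v in report.values())
    if strict and n_bad:
        raise DataIntegrityError(f"validation failed: {n_bad} violations {report}")
    return report


def _reference_structure(cells: pd.DataFrame, cfg: AnalysisConfig) -> dict:
    """Reference age-sex weights: a user CSV, else the run's own mid-study
    person-time structure (analogue of standardizing to a mid-study census)."""
    if cfg.reference_structure:
        ref = pd.read_csv(cfg.reference_structure)
        return {(r.age_band, r.sex): float(r.weight) for r in ref.itertuples()}
    mid = cfg.periods.labels[len(cfg.periods.labels) // 2]
    tab = tabulate(cells[cells["period"] == mid], ["age_band", "sex"])
    return {(r.age_band, r.sex): float(r.pyo) for r in tab.itertuples()}


def _standardized_location_rates(
    cells_loc: pd.DataFrame, ref: dict, periods: PeriodBreaks
) -> pd.DataFrame:
    rows = []
    for (loc, per), grp in cells_loc.groupby(["location_id", "period"], observed=True):
        tab = tabulate(grp, ["age_band", "sex"]).set_index(["age_band", "sex"])
        strata = {}
        for key in ref:
            if key in tab.index and tab.loc[key, "pyo"] > 0:
                strata[key] = 1000.0 * tab.loc[key, "deaths"] / tab.loc[key, "pyo"]
            else:
                strata[key] = 0.0
        rows.append(
            {"location_id": loc, "period": per, "rate": direct_standardize(strata, ref)}
        )
    return pd.DataFrame(rows)


def run_pipeline(cfg: AnalysisConfig, population=None) -> dict:
    """Run the configured stages end to end; returns the result bundle.

    With ``population=None`` a synthetic cohort is simulated from the
    config; otherwise a :class:`~demosurv.simulate.TruePopulation` (or any
    object with ``individuals``/``episodes``/``live_births`` frames) is
    analysed.  All outputs are written under ``cfg.outdir``.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    counts: dict[str, int] = {}

    if population is None:
        logger.info("simulating population (n_baseline=%d, seed=%d)", cfg.n_baseline, cfg.seed)
        population = simulate_population(cfg.sim_config())
    individuals, episodes = population.individuals, population.episodes
    results["validation"] = validate_inputs(episodes, individuals)

    window, periods = cfg.window, cfg.periods
    intervals = build_risk_intervals(episodes, window, cfg.rule, individuals)
    counts["intervals"] = len(intervals)

    cells = split_lexis(intervals, individuals, ANALYSIS_GRID, periods)
    cells_loc = split_lexis(intervals, individuals, ANALYSIS_GRID, periods, by_location=True)
    cells_month = split_lexis(intervals, individuals, ANALYSIS_GRID, periods, by_month=True)
    results["cells"] = cells
    for name, df in [("cells", cells), ("cells_by_location", cells_loc), ("cells_by_month", cells_month)]:
        df.to_csv(outdir / f"{name}.csv", index=False)
        counts[name] = len(df)

    if "rates" in cfg.stages:
        rt = rate_table(cells, ["age_band", "period", "sex"])
        rt_tot = rate_table(cells, ["age_band", "period"])
        rt_tot["sex"] = "Total"
        rates_tbl = pd.concat([rt_tot, rt], ignore_index=True)
        rates_tbl.to_csv(outdir / "rates.csv", index=False)
        results["rates"] = rates_tbl

        crude = rate_table(cells, ["period"])
        crude["rate_display"] = crude["rate"].round(1)
        crude.to_csv(outdir / "crude_rates.csv", index=False)
        results["crude_rates"] = crude
        first, last = crude["rate"].iloc[0], crude["rate"].iloc[-1]
        results["overall_decline_pct"] = percent_decline(first, last)

    if "lifetable" in cfg.stages:
        lt_cells = {
            rule: split_lexis(
                build_risk_intervals(episodes, window, rule, individuals),
                individuals,
                LIFETABLE_GRID,
                periods,
            )
            for rule in ("standard", "madimah")
        }
        lts = {}
        for per in periods.labels:
            sub = lt_cells[cfg.rule][lt_cells[cfg.rule]["period"] == per]
            lts[per] = life_table_from_cells(sub, LIFETABLE_GRID)
            lts[per].to_csv(outdir / f"lifetable_{per}.csv", index=False)
        results["life_tables"] = lts
        results["e0_by_period"] = {p: float(lt["ex"].iloc[0]) for p, lt in lts.items()}
        results["madimah_comparison"] = compare_risk_time_variants(
            lt_cells["standard"], lt_cells["madimah"], LIFETABLE_GRID
        )
        results["madimah_comparison"].to_csv(outdir / "madimah_comparison.csv", index=False)

        km = km_from_intervals(intervals, individuals)
        results["km_median_age"] = km.median
        pd.DataFrame(
            {"age": km.times, "survival": km.survival, "at_risk": km.at_risk}
        ).to_csv(outdir / "km_overall.csv", index=False)

    if "season" in cfg.stages:
        series = build_monthly_series(cells_month, "all")
        dec = stl_decompose(series)
        comp = pd.DataFrame(
            {
                "rate": series.rate,
                "trend": dec.trend,
                "seasonal": dec.seasonal,
                "remainder": dec.remainder,
            }
        )
        comp.to_csv(outdir / "stl_components.csv")
        results["stl"] = dec
        results["peak_trough"] = (dec.peak_month, dec.trough_month)

        yearly = cells_month.groupby("year", observed=True)[["deaths", "pyo"]].sum().reset_index()
        yearly["period"] = [
            periods.labels[int(periods.period_of(to_day(f"{y}-07-01")))] for y in yearly["year"]
        ]
        pe = period_effect_test(yearly)
        results["period_effect"] = pe
        (outdir / "period_effect.json").write_text(
            json.dumps(
                {
                    "model": pe.model,
                    "rate_ratios": {str(k): v for k, v in pe.rate_ratios.items()},
                    "lr_stat": pe.lr_stat,
                    "lr_p": pe.lr_p,
                },
                indent=2,
            )
        )

    if "heterogeneity" in cfg.stages:
        het, ref_res = [], None
        for per in periods.labels:
            sub = cells_loc[cells_loc["period"] == per]
            res = fit_location_random_effect(sub, per, reference=ref_res)
            if ref_res is None:
                ref_res = res
            het.append(res)
        het.append(fit_location_random_effect(cells_loc, f"{periods.labels[0][:4]}-{cfg.study_end[2:4]}"))
        het_tbl = pd.DataFrame([dataclasses.asdict(h) for h in het])
        het_tbl.to_csv(outdir / "heterogeneity.csv", index=False)
        results["heterogeneity"] = het_tbl

        ref = _reference_structure(cells, cfg)
        loc_rates = _standardized_location_rates(cells_loc, ref, periods)
        qc = quantile_classes(loc_rates)
        qc.assignment.to_csv(outdir / "location_classes.csv", index=False)
        results["location_classes"] = qc

        med = median_age_at_death_by_location(intervals, individuals, periods)
        med.to_csv(outdir / "median_age_by_location.csv", index=False)
        results["median_by_location"] = med

    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(cfg),
        "config_hash": hashlib.sha256(
            json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": cfg.seed,
        "rule": cfg.rule,
        "n_individuals": len(individuals),
        "n_episodes": len(episodes),
        "total_pyo": float(cells["pyo"].sum()),
        "total_deaths": int(cells["deaths"].sum()),
        "row_counts": counts,
        "outputs": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(outdir.glob("*.csv"))
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    results["manifest"] = manifest
    return results
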
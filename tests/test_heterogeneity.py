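"""Location random-effects Poisson model, tests, classes and medians."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import demosurv as ds

BANDS = list(ds.ANALYSIS_GRID.labels)
BASE = {b: r / 1000 for b, r in zip(BANDS, [300, 20, 6, 1.4, 5.7, 25, 77])}
PYO = {"0-28d": 150, "29-365d": 2000, "1-4y": 8500, "5-14y": 17500,
       "15-54y": 24000, "55-74y": 3300, "75+y": 560}


def simulate_cells(seed, sd=0.08, n_loc=15, pyo_scale=1.0):
    """Cell-level Poisson draws with planted location effects."""
    rng = np.random.default_rng(seed)
    u = rng.normal(0, sd, n_loc) if sd > 0 else np.zeros(n_loc)
    rows = []
    for l in range(n_loc):
        for b in BANDS:
            for s in ("F", "M"):
                pyo = PYO[b] * pyo_scale
                rows.append(
                    {
                        "age_band": b,
                        "sex": s,
                        "location_id": l,
                        "pyo": float(pyo),
                        "deaths": int(rng.poisson(BASE[b] * np.exp(u[l]) * pyo)),
                    }
                )
    return pd.DataFrame(rows)


class TestMixedModel:
    def test_recovers_planted_sd(self):
        fit = ds.fit_poisson_mixed(simulate_cells(0, sd=0.08))
        assert fit.converged
        assert fit.sigma == pytest.approx(0.08, abs=0.04)
        assert np.isfinite(fit.sigma_se) and fit.sigma_se > 0

    def test_matches_lme4_glmer(self, tmp_path):
        """Independent oracle: R lme4 glmer with adaptive quadrature."""
        cells = simulate_cells(3, sd=0.1)
        csv = tmp_path / "cells.csv"
        cells.to_csv(csv, index=False)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            d$loc <- factor(d$location_id)
            m <- glmer(deaths ~ age_band + sex + (1|loc) + offset(log(pyo)),
                       data=d, family=poisson, nAGQ=15)
            cat(sqrt(unlist(VarCorr(m))), "\\n")
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        sd_r = float(out.stdout.strip().split()[-1])
        fit = ds.fit_poisson_mixed(cells)
        assert fit.sigma == pytest.approx(sd_r, abs=0.002)

    def test_invariant_to_location_relabelling(self):
        cells = simulate_cells(5, sd=0.1)
        fit1 = ds.fit_poisson_mixed(cells)
        relab = cells.assign(location_id=(cells.location_id * 7 + 3) % 15 + 100)
        fit2 = ds.fit_poisson_mixed(relab)
        assert fit1.sigma == pytest.approx(fit2.sigma, abs=1e-5)

    def test_single_location_rejected(self):
        cells = simulate_cells(1).query("location_id == 0")
        with pytest.raises(ValueError, match="two locations"):
            ds.fit_poisson_mixed(cells)

    def test_heterogeneity_result_fields(self):
        res = ds.fit_location_random_effect(simulate_cells(7, sd=0.1), period="P0")
        assert res.approx95 == pytest.approx(np.exp(1.96 * res.sd_log_rates))
        assert res.approx95 >= 1.0
        assert 0 <= res.lr_p <= 1

    def test_approx95_monotone_in_sd(self):
        sds = np.linspace(0, 0.3, 10)
        vals = np.exp(1.96 * sds)
        assert (np.diff(vals) > 0).all()


class TestLRTest:
    def test_boundary_mixture_at_zero_statistic(self):
        """Identical log-likelihoods give p = 0.5 under the 50:50 mixture."""
        stat, p = ds.lr_test_between_location(-100.0, -100.0)
        assert stat == 0.0 and p == 0.5

    def test_plain_chisq_option(self):
        _, p_mix = ds.lr_test_between_location(-98.0, -100.0)
        _, p_plain = ds.lr_test_between_location(-98.0, -100.0, boundary=False)
        assert p_plain == pytest.approx(2 * p_mix)

    def test_power_at_planted_sd(self):
        """Planted SD 0.15 with large person-time: LR test rejects."""
        fit = ds.fit_poisson_mixed(simulate_cells(11, sd=0.15, pyo_scale=2.0))
        _, p = ds.lr_test_between_location(fit.llf, fit.llf_fixed)
        assert p < 0.001


class TestSDEqualityZTest:
    def test_equal_sds_p_one(self):
        diff, p = ds.sd_equality_ztest(0.08, 0.01, 0.08, 0.01)
        assert diff == 0.0 and p == pytest.approx(1.0)

    def test_three_se_difference(self):
        """Difference equal to 3 combined SEs: two-sided p ~ 0.0027."""
        se = 0.01 / np.sqrt(2)
        diff, p = ds.sd_equality_ztest(0.10 + 3 * 0.01, se, 0.10, se)
        assert p == pytest.approx(0.0027, abs=2e-4)

    def test_null_uniform_p(self):
        rng = np.random.default_rng(1)
        ps = []
        for _ in range(500):
            a, b = rng.normal(0.1, 0.01, 2)
            ps.append(ds.sd_equality_ztest(a, 0.01, b, 0.01)[1])
        ps = np.asarray(ps)
        assert abs((ps < 0.05).mean() - 0.05) < 0.03
        assert abs(ps.mean() - 0.5) < 0.05

    def test_missing_se_rejected(self):
        with pytest.raises(ValueError):
            ds.sd_equality_ztest(0.1, float("nan"), 0.1, 0.01)


class TestQuantileClasses:
    @staticmethod
    def _frame(rates):
        return pd.DataFrame(
            {"location_id": range(len(rates)), "period": "P0", "rate": rates}
        )

    def test_equal_counts_with_distinct_rates(self):
        rng = np.random.default_rng(2)
        qc = ds.quantile_classes(self._frame(rng.normal(10, 2, 60)), k=5)
        counts = qc.assignment["class_"].value_counts()
        assert sorted(counts.index) == [1, 2, 3, 4, 5]
        assert counts.max() - counts.min() <= 1
        assert len(qc.breaks) == 4

    def test_all_identical_degenerate(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="demosurv.heterogeneity"):
            qc = ds.quantile_classes(self._frame([3.0] * 10), k=5)
        assert (qc.assignment["class_"] == 1).all()
        assert any("identical" in r.message for r in caplog.records)

    def test_tie_straddling_break_deterministic(self):
        """Ties at a break all take the lowest admissible class; counts can
        differ by at most the number of tied values."""
        rates = [1, 2, 3, 4, 4, 4, 7, 8, 9, 10]
        qc = ds.quantile_classes(self._frame(rates), k=2)
        tied = qc.assignment[qc.assignment.rate == 4]["class_"]
        assert tied.nunique() == 1
        counts = qc.assignment["class_"].value_counts()
        assert counts.max() - counts.min() <= 3
        # brute-force check of the assignment rule
        for r, c in zip(qc.assignment.rate, qc.assignment["class_"]):
            want = 1 + sum(b < r for b in qc.breaks)
            assert c == want

    def test_pooled_breaks_shared_across_periods(self):
        df = pd.concat(
            [
                self._frame(np.arange(10.0)),
                self._frame(np.arange(10.0) + 20).assign(period="P1"),
            ]
        )
        qc = ds.quantile_classes(df, k=5)
        # pooled breaks: every late-period rate classes at or above every
        # early-period rate (the two periods do not overlap in rate)
        p0 = qc.assignment.query("period == 'P0'")["class_"]
        p1 = qc.assignment.query("period == 'P1'")["class_"]
        assert p1.min() >= p0.max()
        assert p1.max() == 5 and p0.min() == 1

    def test_k_validation(self):
        with pytest.raises(ValueError):
            ds.quantile_classes(self._frame([1, 2, 3]), k=1)


class TestMedianByLocation:
    def test_span_arithmetic(self):
        from demosurv.heterogeneity import median_span

        assert median_span([65, 70, 72]) == 7

    def test_shared_hazard_small_span(self, small_pop):
        cfg, pop = small_pop
        iv = ds.build_risk_intervals(pop.episodes, cfg.window, "standard")
        med = ds.median_age_at_death_by_location(iv, pop.individuals)
        assert med.median_age.notna().sum() >= 10
        # same generating hazards: medians vary by sampling noise only
        assert med.median_age.max() - med.median_age.min() < 40

    def test_doubled_hazard_lowest_median(self):
        """A location with doubled hazard yields the lowest KM median."""
        rng = np.random.default_rng(9)
        rows = []
        for loc, mult in [(0, 1.0), (1, 1.0), (2, 2.0)]:
            ages = rng.exponential(60 / mult, 600)
            for a in ages:
                rows.append({"location_id": loc, "entry": 0.0, "exit": max(a, 0.01), "event": True})
        df = pd.DataFrame(rows)
        meds = {}
        for loc, grp in df.groupby("location_id"):
            meds[loc] = ds.km_fit(grp.entry, grp.exit, grp.event).median
        assert min(meds, key=meds.get) == 2
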
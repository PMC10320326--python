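"""Risk-interval construction and Lexis splitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import demosurv as ds
from demosurv.ages import DAYS_PER_YEAR, to_day
from demosurv.persontime import MADIMAH_GAP_DAYS, _split_at

from conftest import brute_force_cells, episodes_frame, individuals_frame

WINDOW = (to_day("2003-01-01"), to_day("2019-01-01"))
PERIODS = ds.PeriodBreaks.default()


class TestBuildRiskIntervals:
    def test_single_death_episode_is_identity(self):
        """One 14-day episode ending in death maps to one 14-day interval."""
        ep = episodes_frame([(1, 0, "2003-01-01", "enumeration", "2003-01-15", "death")])
        iv = ds.build_risk_intervals(ep, WINDOW, "standard")
        assert len(iv) == 1
        assert iv.loc[0, "exit_day"] - iv.loc[0, "entry_day"] == 14
        assert bool(iv.loc[0, "event"])

    @pytest.mark.parametrize(
        "in_date, gap_days, included",
        [("2010-06-01", 92, True), ("2010-10-01", 214, False)],
    )
    def test_madimah_gap_threshold(self, in_date, gap_days, included):
        """Out 2010-03-01 then back in: gaps under 180 days are risk time
        under MADIMAH only; 180+ days are excluded under both rules."""
        ep = episodes_frame(
            [
                (1, 3, "2003-01-01", "enumeration", "2010-03-01", "out-migration"),
                (1, 5, in_date, "in-migration", None, "study-end"),
            ]
        )
        std = ds.build_risk_intervals(ep, WINDOW, "standard")
        mad = ds.build_risk_intervals(ep, WINDOW, "madimah")
        assert len(std) == 2
        pyo_std = (std.exit_day - std.entry_day).sum() / DAYS_PER_YEAR
        pyo_mad = (mad.exit_day - mad.entry_day).sum() / DAYS_PER_YEAR
        if included:
            assert len(mad) == 3
            gap = mad[mad.provenance == "included-gap"]
            assert int(gap.exit_day.iloc[0] - gap.entry_day.iloc[0]) == gap_days
            # included gap keeps the previous residence location
            assert gap.location_id.iloc[0] == 3
            assert pyo_mad - pyo_std == pytest.approx(gap_days / DAYS_PER_YEAR)
        else:
            assert len(mad) == 2
            assert pyo_mad == pyo_std

    def test_overlapping_episodes_rejected(self):
        ep = episodes_frame(
            [
                (9, 0, "2004-01-01", "enumeration", "2006-01-01", "out-migration"),
                (9, 1, "2005-06-01", "in-migration", None, "study-end"),
            ]
        )
        with pytest.raises(ds.DataIntegrityError, match="9"):
            ds.build_risk_intervals(ep, WINDOW, "standard")

    def test_death_outside_episodes_rejected(self):
        ep = episodes_frame([(4, 0, "2004-01-01", "enumeration", "2005-01-01", "out-migration")])
        ind = individuals_frame([(4, "F", "1980-05-05", "2006-03-03")])
        with pytest.raises(ds.DataIntegrityError, match="outside"):
            ds.build_risk_intervals(ep, WINDOW, "standard", ind)

    def test_window_clipping_censors_post_window_death(self):
        ep = episodes_frame([(1, 0, "2001-05-01", "enumeration", "2020-06-01", "death")])
        iv = ds.build_risk_intervals(ep, WINDOW, "standard")
        assert iv.loc[0, "entry_day"] == WINDOW[0]
        assert iv.loc[0, "exit_day"] == WINDOW[1]
        assert not bool(iv.loc[0, "event"])


class TestSplitLexis:
    def test_infant_year_stays_in_first_band(self):
        """Birth 2005-07-01 followed one year: all 365 days in the <1y band."""
        grid = ds.AgeGrid.from_year_breaks([0, 1, 5], ["<1y", "1-4y", "5+y"])
        ep = episodes_frame([(1, 0, "2005-07-01", "birth", "2006-07-01", "out-migration")])
        ind = individuals_frame([(1, "F", "2005-07-01", None)])
        iv = ds.build_risk_intervals(ep, WINDOW, "standard")
        cells = ds.split_lexis(iv, ind, grid, PERIODS)
        assert set(cells.age_band) == {"<1y"}
        assert cells.pyo.sum() == pytest.approx(365 / DAYS_PER_YEAR)

    def test_no_split_inside_one_cell(self):
        ep = episodes_frame([(1, 0, "2004-02-01", "in-migration", "2004-03-01", "out-migration")])
        ind = individuals_frame([(1, "M", "1970-01-01", None)])
        iv = ds.build_risk_intervals(ep, WINDOW, "standard")
        cells = ds.split_lexis(iv, ind, ds.ANALYSIS_GRID, PERIODS, by_month=True)
        assert len(cells) == 1
        assert cells.pyo.iloc[0] == pytest.approx(29 / DAYS_PER_YEAR)

    def test_death_lands_in_exactly_one_cell(self, small_pop):
        cfg, pop = small_pop
        iv = ds.build_risk_intervals(pop.episodes, cfg.window, "standard", pop.individuals)
        cells = ds.split_lexis(iv, pop.individuals, ds.ANALYSIS_GRID, cfg.periods, by_month=True)
        assert cells.deaths.sum() == iv.event.sum() == pop.individuals.dod.notna().sum()

    @pytest.mark.parametrize("by_month", [False, True])
    def test_conservation_under_partitioning(self, small_pop, by_month):
        """Total PYO is invariant to the age/period/month partition."""
        cfg, pop = small_pop
        iv = ds.build_risk_intervals(pop.episodes, cfg.window, "standard", pop.individuals)
        total = (iv.exit_day - iv.entry_day).sum() / DAYS_PER_YEAR
        for grid in (ds.ANALYSIS_GRID, ds.LIFETABLE_GRID):
            cells = ds.split_lexis(iv, pop.individuals, grid, cfg.periods, by_month=by_month)
            assert cells.pyo.sum() == pytest.approx(total, abs=1e-9)

    def test_brute_force_oracle_small_population(self):
        """Vectorized splitter equals the day-by-day loop on <=50 people."""
        cfg = ds.SimConfig(n_baseline=40, birth_rate=0.1, inmigration_rate=0.05, seed=11)
        pop = ds.simulate_population(cfg)
        keep = pop.individuals.individual_id[:50]
        ind = pop.individuals[pop.individuals.individual_id.isin(keep)]
        eps = pop.episodes[pop.episodes.individual_id.isin(keep)]
        iv = ds.build_risk_intervals(eps, cfg.window, "standard")
        got = ds.split_lexis(iv, ind, ds.ANALYSIS_GRID, cfg.periods, by_month=True)
        want = brute_force_cells(iv, ind, ds.ANALYSIS_GRID, cfg.periods, by_month=True)
        keys = ["age_band", "sex", "period", "year", "month"]
        got = got.astype({"age_band": str, "period": str}).set_index(keys).sort_index()
        want = want.set_index(keys).sort_index()
        pd.testing.assert_index_equal(got.index, want.index)
        assert (got.deaths == want.deaths).all()
        np.testing.assert_allclose(got.pyo, want.pyo, atol=1 / DAYS_PER_YEAR)


class TestMadimahDominance:
    def test_pyo_dominance_and_threshold(self, small_pop):
        """MADIMAH PYO >= standard PYO, equality iff no gap under 180 days."""
        cfg, pop = small_pop
        std = ds.build_risk_intervals(pop.episodes, cfg.window, "standard")
        mad = ds.build_risk_intervals(pop.episodes, cfg.window, "madimah")
        p_std = (std.exit_day - std.entry_day).sum()
        p_mad = (mad.exit_day - mad.entry_day).sum()
        gaps = mad[mad.provenance == "included-gap"]
        assert p_mad >= p_std
        assert len(gaps) > 0  # the gap mixture plants short gaps
        assert ((gaps.exit_day - gaps.entry_day) < MADIMAH_GAP_DAYS).all()
        assert p_mad - p_std == (gaps.exit_day - gaps.entry_day).sum()
        # per-individual dominance
        a = std.groupby("individual_id").apply(lambda g: (g.exit_day - g.entry_day).sum(), include_groups=False)
        b = mad.groupby("individual_id").apply(lambda g: (g.exit_day - g.entry_day).sum(), include_groups=False)
        assert (b.reindex(a.index, fill_value=0) >= a).all()


class TestTabulate:
    def test_grand_total_and_idempotence(self, small_pop):
        cfg, pop = small_pop
        iv = ds.build_risk_intervals(pop.episodes, cfg.window, "standard")
        cells = ds.split_lexis(iv, pop.individuals, ds.ANALYSIS_GRID, cfg.periods, by_location=True)
        total = ds.tabulate(cells, [])
        assert total.deaths.iloc[0] == cells.deaths.sum()
        one = ds.tabulate(cells, ["age_band", "sex"])
        two = ds.tabulate(ds.tabulate(cells, ["age_band", "sex", "period"]), ["age_band", "sex"])
        pd.testing.assert_frame_equal(one, two)

    def test_unknown_key_rejected(self, small_pop):
        cfg, pop = small_pop
        iv = ds.build_risk_intervals(pop.episodes, cfg.window, "standard")
        cells = ds.split_lexis(iv, pop.individuals, ds.ANALYSIS_GRID, cfg.periods)
        with pytest.raises(KeyError):
            ds.tabulate(cells, ["village"])


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    entry=st.integers(min_value=12000, max_value=17000),
    length=st.integers(min_value=1, max_value=4000),
    cuts=st.lists(st.integers(min_value=11000, max_value=22000), max_size=8),
)
def test_split_at_partitions_exactly(entry, length, cuts):
    """_split_at returns contiguous fragments that tile [entry, exit) with
    interior boundaries exactly on the cut points."""
    df = pd.DataFrame(
        {"entry_day": [entry], "exit_day": [entry + length], "event": [True]}
    )
    cut_arr = np.unique(cuts)
    out = _split_at(df, cut_arr, np.zeros(1, dtype=int))
    assert out.entry_day.iloc[0] == entry and out.exit_day.iloc[-1] == entry + length
    assert (out.entry_day.values[1:] == out.exit_day.values[:-1]).all()
    assert (out.exit_day - out.entry_day).sum() == length
    inner = out.exit_day.values[:-1]
    assert all(b in cut_arr for b in inner)
    assert out.event.sum() == 1 and bool(out.event.iloc[-1])
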
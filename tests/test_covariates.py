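"""Covariate derivation: seasonal windows, flow thresholds, assembly, screening."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import graylinggrowth.covariates as cov


def _series(dates, values, kind="temperature"):
    return cov.DailySeries(pd.Series(values, index=pd.DatetimeIndex(dates)), kind=kind)


class TestWindows:
    def test_mean_of_constant_series(self):
        idx = pd.date_range("2010-01-01", "2010-12-31", freq="D")
        s = _series(idx, np.full(len(idx), 10.0))
        assert cov.window_mean(s, 2010, cov.SPRING_AUTUMN) == pytest.approx(10.0)
        assert cov.window_mean(s, 2010, cov.AUTUMN_WINTER) == pytest.approx(10.0)

    def test_growing_season_window_is_183_days(self):
        # 1 Apr - 30 Sep of a non-leap year; values 1..183 -> mean (1+183)/2
        idx = pd.date_range("2010-04-01", "2010-09-30", freq="D")
        assert len(idx) == 183
        s = _series(idx, np.arange(1.0, 184.0))
        assert cov.window_mean(s, 2010, cov.SPRING_AUTUMN) == pytest.approx(92.0)

    def test_winter_window_spans_two_calendar_years(self):
        # Oct of year-1 through Mar of year: value 1 before 1 Jan, 2 after
        idx = pd.date_range("2010-10-01", "2011-03-31", freq="D")
        vals = np.where(idx.year == 2010, 1.0, 2.0)
        s = _series(idx, vals)
        n10 = int((idx.year == 2010).sum())  # 92 days Oct-Dec
        n11 = int((idx.year == 2011).sum())  # 90 days Jan-Mar (non-leap)
        expected = (n10 * 1.0 + n11 * 2.0) / (n10 + n11)
        assert cov.window_mean(s, 2011, cov.AUTUMN_WINTER) == pytest.approx(expected)
        assert n10 + n11 == 182

    def test_empty_window_raises_with_year_named(self):
        idx = pd.date_range("2010-01-01", "2010-03-01", freq="D")
        s = _series(idx, np.zeros(len(idx)))
        with pytest.raises(ValueError, match="2011"):
            cov.window_mean(s, 2011, cov.SPRING_AUTUMN)

    def test_duplicate_dates_rejected(self):
        idx = pd.DatetimeIndex(["2010-01-01", "2010-01-01"])
        with pytest.raises(ValueError, match="duplicate"):
            cov.DailySeries(pd.Series([1.0, 2.0], index=idx))


class TestHotDays:
    def test_threshold_is_strict(self, daily_temp):
        idx = pd.date_range("2010-04-01", "2010-09-30", freq="D")
        vals = np.full(len(idx), 15.0)
        vals[:3] = [19.9, 20.0, 20.1]
        s = _series(idx, vals)
        assert cov.count_days_above(s, 20.0, 2010) == 1

    def test_all_days_hot(self):
        idx = pd.date_range("2010-04-01", "2010-09-30", freq="D")
        s = _series(idx, np.full(len(idx), 25.0))
        assert cov.count_days_above(s, 20.0, 2010) == 183

    def test_none_hot(self, daily_temp):
        assert cov.count_days_above(daily_temp, 100.0, 2010) == 0


class TestFlowThresholds:
    def test_equally_spaced_points(self):
        # 0,10,...,100 tiled across enough days: interpolated percentiles
        idx = pd.date_range("2003-01-01", periods=110, freq="D")
        vals = np.tile(np.arange(0.0, 101.0, 10.0), 10)
        s = _series(idx, vals, kind="discharge")
        q90, q10 = cov.flow_thresholds(s, (2003, 2003))
        assert q90 == pytest.approx(10.0)
        assert q10 == pytest.approx(90.0)

    def test_constant_series_warns_and_collapses(self):
        idx = pd.date_range("2003-01-01", periods=150, freq="D")
        s = _series(idx, np.full(150, 5.0), kind="discharge")
        with pytest.warns(UserWarning, match="constant"):
            q90, q10 = cov.flow_thresholds(s, (2003, 2003))
        assert q90 == q10 == 5.0

    def test_quantile_ordering_and_round_trip(self):
        rng = np.random.default_rng(3)
        idx = pd.date_range("2003-01-01", "2007-12-31", freq="D")
        vals = np.exp(rng.normal(0.5, 0.6, len(idx)))
        s = _series(idx, vals, kind="discharge")
        q90, q10 = cov.flow_thresholds(s, (2003, 2007))
        med = float(np.median(vals))
        assert q90 <= med <= q10
        # fraction of period days at or below Q90 within one day-count of 10%
        frac = (vals <= q90).mean()
        assert abs(frac - 0.10) <= 1.0 / len(vals) + 1e-12

    def test_too_few_values_rejected(self):
        idx = pd.date_range("2003-01-01", periods=50, freq="D")
        s = _series(idx, np.ones(50), kind="discharge")
        with pytest.raises(ValueError, match="<100"):
            cov.flow_thresholds(s, (2003, 2003))


class TestFlowDays:
    def test_threshold_day_counts_in_both_directions(self):
        idx = pd.date_range("2010-04-01", "2010-09-30", freq="D")
        vals = np.full(len(idx), 2.0)
        s = _series(idx, vals, kind="discharge")
        # exactly at threshold counts for both (inclusive comparisons)
        assert cov.count_flow_days(s, 2010, 2.0, "low") == 183
        assert cov.count_flow_days(s, 2010, 2.0, "high") == 183

    def test_all_zero_discharge_below_low_threshold(self):
        idx = pd.date_range("2010-04-01", "2010-09-30", freq="D")
        s = _series(idx, np.zeros(len(idx)), kind="discharge")
        assert cov.count_flow_days(s, 2010, 1.0, "low") == 183

    def test_high_threshold_above_maximum(self):
        idx = pd.date_range("2010-04-01", "2010-09-30", freq="D")
        s = _series(idx, np.linspace(0, 5, len(idx)), kind="discharge")
        assert cov.count_flow_days(s, 2010, 10.0, "high") == 0


def _raw_frame(years=(2010, 2011, 2012), sites=(1, 2)):
    rng = np.random.default_rng(0)
    rows = []
    for v in ("meanT_SA", "meanT_AW", "lowflow_days"):
        for y in years:
            rows.append((y, np.nan, v, float(rng.normal(10, 2))))
    for v in ("grayling_juv_abund",):
        for y in years:
            for s in sites:
                rows.append((y, s, v, float(rng.poisson(40))))
    return pd.DataFrame(rows, columns=["year", "site", "variable", "value"])


SMALL_SETS = {1: ["meanT_SA", "grayling_juv_abund"], 2: ["meanT_AW", "lowflow_days"]}


class TestAssemble:
    def test_stage_sets_respected(self):
        table = cov.assemble(_raw_frame(), SMALL_SETS, sites=[1, 2])
        l1_vars = set(table.data.loc[table.data["stage"] == 1, "variable"])
        assert l1_vars == set(SMALL_SETS[1])
        assert "meanT_AW" not in l1_vars

    def test_year_level_values_replicated_across_sites(self):
        table = cov.assemble(_raw_frame(), SMALL_SETS, sites=[1, 2])
        sub = table.data.query("variable == 'meanT_SA' and year == 2010")
        assert sub["raw_value"].nunique() == 1
        assert len(sub) == 2

    def test_site_level_values_vary(self):
        table = cov.assemble(_raw_frame(), SMALL_SETS, sites=[1, 2])
        sub = table.data.query("variable == 'grayling_juv_abund' and year == 2010")
        assert len(sub) == 2

    def test_missing_year_raises_listing_gap(self):
        raw = _raw_frame()
        raw = raw.loc[~((raw["variable"] == "meanT_AW") & (raw["year"] == 2011))]
        with pytest.raises(ValueError, match="missing"):
            cov.assemble(raw, SMALL_SETS, sites=[1, 2])

    def test_deterministic(self):
        t1 = cov.assemble(_raw_frame(), SMALL_SETS, sites=[1, 2])
        t2 = cov.assemble(_raw_frame(), SMALL_SETS, sites=[1, 2])
        pd.testing.assert_frame_equal(t1.data, t2.data)


class TestStandardise:
    def test_three_point_example(self):
        raw = pd.DataFrame(
            {
                "year": [1, 2, 3],
                "site": np.nan,
                "variable": "v",
                "value": [1.0, 2.0, 3.0],
            }
        )
        table = cov.assemble(raw, {1: ["v"]}, sites=[1])
        out = cov.z_standardise(table)
        np.testing.assert_allclose(
            np.sort(out.data["std_value"].to_numpy()), [-1.0, 0.0, 1.0]
        )

    def test_standardised_columns_centred(self, small_study):
        table = small_study["covariates"]
        for var, grp in table.data.groupby("variable"):
            support = grp.drop_duplicates(["year", "site"])["std_value"]
            assert abs(support.mean()) < 1e-10
            assert support.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_constant_column_rejected(self):
        raw = pd.DataFrame(
            {"year": [1, 2], "site": np.nan, "variable": "v", "value": [5.0, 5.0]}
        )
        table = cov.assemble(raw, {1: ["v"]}, sites=[1])
        with pytest.raises(ValueError, match="zero variance"):
            cov.z_standardise(table)

    @settings(deadline=None, max_examples=25)
    @given(
        st.lists(
            st.floats(min_value=-1e3, max_value=1e3),
            min_size=4,
            max_size=12,
            unique=True,
        )
    )
    def test_idempotent_up_to_tolerance(self, values):
        raw = pd.DataFrame(
            {
                "year": np.arange(len(values)),
                "site": np.nan,
                "variable": "v",
                "value": values,
            }
        )
        t1 = cov.z_standardise(cov.assemble(raw, {1: ["v"]}, sites=[1]))
        # feed the standardised values back through as raw values
        raw2 = t1.data.rename(columns={"std_value": "value"})[
            ["year", "site", "variable", "value"]
        ]
        t2 = cov.z_standardise(cov.assemble(raw2, {1: ["v"]}, sites=[1]))
        np.testing.assert_allclose(
            t2.data["std_value"].to_numpy(), t1.data["std_value"].to_numpy(), atol=1e-12
        )


class TestCollinearityScreen:
    def _table(self, corr_pair=False, n=40, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal(n)
        b = a.copy() if corr_pair else rng.standard_normal(n)
        raw = pd.DataFrame(
            {
                "year": np.repeat(np.arange(n), 1),
                "site": np.nan,
                "variable": "a",
                "value": a,
            }
        )
        raw2 = raw.copy()
        raw2["variable"] = "b"
        raw2["value"] = b
        table = cov.assemble(pd.concat([raw, raw2]), {1: ["a", "b"]}, sites=[1])
        return cov.z_standardise(table)

    def test_duplicated_column_flagged_at_r_one(self):
        table = self._table(corr_pair=True)
        out, report = cov.collinearity_screen(table, drop_list=("b",))
        assert report["flagged_pairs"][0]["r"] == pytest.approx(1.0)
        assert "b" in report["dropped"]
        assert "b" not in out.stage_sets[1]

    def test_unresolved_pair_demands_choice(self):
        table = self._table(corr_pair=True)
        with pytest.raises(ValueError, match="no configured resolution"):
            cov.collinearity_screen(table, drop_list=())

    def test_independent_columns_not_flagged(self):
        table = self._table(corr_pair=False, n=400, seed=1)
        out, report = cov.collinearity_screen(table, drop_list=())
        assert report["flagged_pairs"] == []
        assert out.stage_sets[1] == ["a", "b"]

    def test_default_config_drops_hot_days_keeps_mean_temperature(self, small_study):
        report = small_study["screen_report"]
        assert "highT_days" in report["dropped"]
        table = small_study["covariates"]
        for l in (1, 2, 3):
            assert "highT_days" not in table.stage_sets[l]
        assert "meanT_SA" in table.stage_sets[1]
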
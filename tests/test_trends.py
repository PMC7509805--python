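"""Trend statistics against brute-force oracles and printed arithmetic."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from tundragreen import trends as trd


def brute_force_mk_p(x):
    """Two-sided MK p by exhaustive enumeration over all permutations."""
    x = np.asarray(x, dtype=float)
    n = x.size

    def s_stat(v):
        return sum(np.sign(v[j] - v[i]) for i in range(n) for j in range(i + 1, n))

    s_obs = abs(s_stat(x))
    if s_obs == 0:
        return 1.0
    count = sum(abs(s_stat(np.asarray(p))) >= s_obs
                for p in itertools.permutations(x))
    return count / math.factorial(n)


def brute_force_theil_sen(x, t):
    slopes = [(x[j] - x[i]) / (t[j] - t[i])
              for i in range(len(x)) for j in range(i + 1, len(x))
              if t[j] != t[i]]
    return float(np.median(slopes))


class TestMannKendall:
    def test_strictly_increasing(self):
        r = trd.mann_kendall(np.arange(10, dtype=float))
        assert r.s == 45
        assert r.tau == pytest.approx(1.0)
        assert r.p < 1e-4

    def test_strictly_decreasing(self):
        r = trd.mann_kendall(-np.arange(10, dtype=float))
        assert r.tau == pytest.approx(-1.0)

    def test_constant_series(self):
        r = trd.mann_kendall([2.0, 2.0, 2.0, 2.0, 2.0])
        assert r.tau == 0.0
        assert r.p == 1.0

    def test_exact_p_equals_permutation_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=6)
            r = trd.mann_kendall(x)
            assert r.method == "exact"
            assert r.p == pytest.approx(brute_force_mk_p(x), abs=1e-12)

    def test_exact_p_matches_scipy_kendalltau(self):
        """Independent cross-check: MK on a tie-free series equals the exact
        Kendall tau test of the values against time."""
        rng = np.random.default_rng(1)
        for n in (5, 7, 9):
            x = rng.normal(size=n)
            r = trd.mann_kendall(x)
            tau, p = stats.kendalltau(np.arange(n), x, method="exact")
            assert r.p == pytest.approx(p, abs=1e-12)
            assert r.tau == pytest.approx(tau, abs=1e-12)

    def test_requires_four_values(self):
        with pytest.raises(ValueError, match=">= 4"):
            trd.mann_kendall([1.0, 2.0, 3.0])

    def test_null_rejection_rate_close_to_alpha(self):
        rng = np.random.default_rng(2)
        rej = sum(trd.mann_kendall(rng.normal(size=32)).p <= 0.10
                  for _ in range(2000))
        assert abs(rej / 2000 - 0.10) < 0.025


class TestTheilSen:
    def test_exact_line(self):
        t = np.arange(10, dtype=float)
        assert trd.theil_sen(2 * t, t) == pytest.approx(2.0, abs=1e-12)

    def test_small_fixture_against_pairwise_median(self):
        x = np.array([1.0, 3.0, 2.0, 5.0])
        t = np.array([1.0, 2.0, 3.0, 4.0])
        assert trd.theil_sen(x, t) == pytest.approx(brute_force_theil_sen(x, t))

    def test_single_outlier_does_not_move_slope(self):
        t = np.arange(20, dtype=float)
        x = 0.5 * t
        x[18] += 50.0
        assert trd.theil_sen(x, t) == pytest.approx(0.5, abs=1e-3)
        # OLS, by contrast, is pulled far off by the same outlier
        assert abs(np.polyfit(t, x, 1)[0] - 0.5) > 0.1

    def test_duplicate_times_skipped(self):
        x = np.array([0.0, 1.0, 5.0, 2.0])
        t = np.array([0.0, 1.0, 1.0, 2.0])
        assert np.isfinite(trd.theil_sen(x, t))

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=12))
    def test_matches_brute_force_on_random_fixtures(self, xs):
        t = np.arange(len(xs), dtype=float)
        x = np.asarray(xs)
        assert trd.theil_sen(x, t) == pytest.approx(
            brute_force_theil_sen(x, t), rel=1e-12, abs=1e-12)

    def test_matches_scipy_theilslopes(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(size=15)
            t = np.arange(15, dtype=float)
            assert trd.theil_sen(x, t) == pytest.approx(
                stats.theilslopes(x, t).slope, rel=1e-10)


class TestClassifyTrend:
    def test_clear_trends_classified(self):
        t = np.arange(1985, 2017, dtype=float)
        up = 0.3 + 0.002 * (t - 2000)
        down = 0.3 - 0.002 * (t - 2000)
        assert trd.classify_trend(up, t, prewhiten=None).trend_class == "greening"
        assert trd.classify_trend(down, t, prewhiten=None).trend_class == "browning"

    def test_insignificant_is_none(self):
        rng = np.random.default_rng(4)
        t = np.arange(1985, 2017, dtype=float)
        x = 0.3 + rng.normal(0, 0.05, t.size)
        res = trd.classify_trend(x, t, alpha=1e-6, prewhiten=None)
        assert res.trend_class == "none"

    def test_class_consistent_with_p_and_slope(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            x = rng.normal(0, 1, 20)
            res = trd.classify_trend(x, alpha=0.10, prewhiten=None)
            if res.mk_p <= 0.10 and res.sen_slope > 0:
                assert res.trend_class == "greening"
            elif res.mk_p <= 0.10 and res.sen_slope < 0:
                assert res.trend_class == "browning"
            else:
                assert res.trend_class == "none"

    def test_zhang_prewhitening_removes_ar1_false_positives(self):
        """Strongly autocorrelated trendless series reject far above alpha
        with plain MK; the iterative pre-whitening variant pulls the rate
        back down (trend-free pre-whitening is known to under-correct at
        strong lag-1 autocorrelation, so it is not held to this bound)."""
        rng = np.random.default_rng(6)
        plain = pw = 0
        for _ in range(150):
            e = rng.normal(size=40)
            x = np.empty(40)
            x[0] = e[0]
            for i in range(1, 40):
                x[i] = 0.7 * x[i - 1] + e[i]
            plain += trd.classify_trend(x, prewhiten=None).trend_class != "none"
            pw += trd.classify_trend(x, prewhiten="zhang").trend_class != "none"
        assert pw < plain

    @pytest.mark.parametrize("variant", ["yuepilon", "zhang"])
    def test_prewhitening_keeps_iid_rejection_near_alpha(self, variant):
        """On serially independent nulls pre-whitening leaves the rejection
        rate close to the nominal level."""
        rng = np.random.default_rng(16)
        rej = sum(trd.classify_trend(rng.normal(size=32), alpha=0.10,
                                     prewhiten=variant).trend_class != "none"
                  for _ in range(400))
        assert abs(rej / 400 - 0.10) < 0.05

    @pytest.mark.parametrize("variant", ["yuepilon", "zhang"])
    def test_prewhitening_preserves_clear_trend(self, variant):
        t = np.arange(1985, 2017, dtype=float)
        up = 0.3 + 0.003 * (t - 2000)
        res = trd.classify_trend(up, t, prewhiten=variant)
        assert res.trend_class == "greening"
        assert res.sen_slope == pytest.approx(0.003, abs=1e-6)


class TestScreenSites:
    def _table(self, values_by_site):
        rows = [(s, y, v) for s, vals in values_by_site.items()
                for y, v in enumerate(vals)]
        return pd.DataFrame(rows, columns=["site_id", "year", "ndvimax"])

    def test_barren_and_short_records_excluded(self):
        tbl = self._table({
            "barren": [0.08] * 15,
            "short": [0.5] * 9,
            "boundary": [0.10] * 10,
            "good": [0.4] * 20,
        })
        kept = trd.screen_sites(tbl)
        assert set(kept) == {"boundary", "good"}


class TestCorrelations:
    def test_comonotone_series_give_unit_correlation(self):
        years = range(2000, 2012)
        nd = pd.Series(np.arange(12, dtype=float), index=years)
        sw = pd.Series(np.arange(12, dtype=float) ** 2, index=years)
        r = trd.correlate_ndvi_swi(nd, sw)
        assert r.r_s == pytest.approx(1.0)

    def test_small_fixture_matches_rank_formula(self):
        rng = np.random.default_rng(7)
        years = range(1990, 2000)
        nd = pd.Series(rng.normal(size=10), index=years)
        sw = pd.Series(rng.normal(size=10), index=years)
        r = trd.correlate_ndvi_swi(nd, sw)
        # brute-force Spearman: Pearson correlation of the rank vectors
        rx = nd.rank().to_numpy()
        ry = sw.rank().to_numpy()
        expected = np.corrcoef(rx, ry)[0, 1]
        assert r.r_s == pytest.approx(expected, abs=1e-12)

    def test_two_year_mean_drops_first_year(self):
        years = list(range(2000, 2012))
        nd = pd.Series(np.arange(12, dtype=float), index=years)
        sw = pd.Series(np.arange(12, dtype=float), index=years)
        r = trd.correlate_ndvi_swi(nd, sw, mode="two-year-mean")
        assert r.n == 11

    def test_detrended_independent_trends_near_zero(self):
        rng = np.random.default_rng(8)
        years = np.arange(1985, 2017)
        rs = []
        for _ in range(50):
            nd = pd.Series(0.01 * years + rng.normal(0, 1, years.size), index=years)
            sw = pd.Series(0.05 * years + rng.normal(0, 1, years.size), index=years)
            rs.append(trd.correlate_ndvi_swi(nd, sw, mode="detrended").r_s)
        assert abs(np.mean(rs)) < 0.06

    def test_insufficient_overlap_flagged(self):
        nd = pd.Series([1.0] * 5, index=range(2000, 2005))
        sw = pd.Series([1.0] * 5, index=range(2010, 2015))
        r = trd.correlate_ndvi_swi(nd, sw)
        assert not r.ok and math.isnan(r.r_s)


class TestAggregateZone:
    def _df(self, data):
        rows = [(s, y, v) for s, series in data.items() for y, v in series.items()]
        return pd.DataFrame(rows, columns=["site_id", "year", "ndvimax"])

    def test_single_site_returns_own_anomalies(self):
        df = self._df({"a": {2000: 0.3, 2001: 0.5}})
        out = trd.aggregate_zone(df, pd.Series({"a": "Low"}))
        assert out["anomaly"].tolist() == pytest.approx([-0.1, 0.1])

    def test_mirror_image_sites_cancel(self):
        df = self._df({"a": {2000: 0.3, 2001: 0.5}, "b": {2000: 0.5, 2001: 0.3}})
        out = trd.aggregate_zone(df, pd.Series({"a": "Low", "b": "Low"}))
        assert np.allclose(out["anomaly"], 0.0)

    def test_recovers_injected_zone_trend(self):
        rng = np.random.default_rng(9)
        years = np.arange(2000, 2020)
        data = {f"s{i}": dict(zip(years, 0.4 + 0.002 * (years - 2010)
                                  + rng.normal(0, 0.01, years.size)))
                for i in range(30)}
        out = trd.aggregate_zone(self._df(data), pd.Series({f"s{i}": "Oro"
                                                            for i in range(30)}))
        slope = trd.theil_sen(out["anomaly"].to_numpy(), out["year"].to_numpy())
        assert slope == pytest.approx(0.002, abs=5e-4)


class TestSummaries:
    def test_ratio_from_printed_percentages(self):
        assert round(trd.greening_browning_ratio(37.3, 4.7), 1) == 7.9
        assert round(trd.greening_browning_ratio(21.3, 6.0), 1) == 3.6
        assert trd.greening_browning_ratio(10.0, 10.0) == 1.0

    def test_infinite_ratio_reported(self):
        draws = [["greening"] * 3 + ["none"] * 7,
                 ["greening"] * 2 + ["browning"] + ["none"] * 7]
        out = trd.summarize_classes(draws)
        row = out[out["statistic"] == "greening_browning_ratio"].iloc[0]
        assert row["n_infinite"] == 1

    def test_summary_ci_ordering(self):
        rng = np.random.default_rng(10)
        draws = [rng.choice(trd.TREND_CLASSES, size=50).tolist() for _ in range(40)]
        out = trd.summarize_classes(draws)
        assert (out["ci_low"] <= out["median"]).all()
        assert (out["median"] <= out["ci_high"]).all()

    @pytest.mark.parametrize("frac,window,expected", [
        (0.011, 16, 16 / 0.011),
        (1.0, 16, 16.0),
        (0.5, 10, 20.0),
    ])
    def test_fire_rotation(self, frac, window, expected):
        assert trd.fire_rotation(frac, window) == pytest.approx(expected, rel=1e-9)

    def test_fire_rotation_zero_fraction_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert math.isnan(trd.fire_rotation(0.0, 16))
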
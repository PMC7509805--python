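"""Generator contracts: known truth, determinism, and physical bounds."""

import io

import numpy as np
import pandas as pd
import pytest

from tundragreen import synthetic as syn
from tundragreen import climate as cl
from tundragreen import trends as trd


class TestGenerateSites:
    def test_exact_class_fractions(self, sites100):
        counts = sites100["trend_class_true"].value_counts()
        assert counts["greening"] == 37
        assert counts["browning"] == 5
        assert counts["none"] == 58

    def test_zero_fractions_give_zero_slopes(self):
        sites = syn.generate_sites(10, frac_greening=0, frac_browning=0, seed=3)
        assert (sites["trend_slope_true"] == 0).all()

    def test_slope_sign_matches_class(self, sites100):
        for cls, sign in [("greening", 1), ("browning", -1), ("none", 0)]:
            sl = sites100.loc[sites100["trend_class_true"] == cls, "trend_slope_true"]
            assert (np.sign(sl) == sign).all()

    def test_barren_sites_below_threshold(self, sites100):
        assert (sites100.loc[sites100["barren_flag"], "base_ndvimax"] < 0.10).all()
        assert sites100["base_ndvimax"].between(0, 1).all()

    @pytest.mark.parametrize("kwargs,fragment", [
        (dict(frac_greening=1.2), "frac_greening"),
        (dict(frac_browning=-0.1), "frac_browning"),
        (dict(frac_greening=0.7, frac_browning=0.4), "frac_greening + frac_browning"),
    ])
    def test_invalid_fractions_name_parameter(self, kwargs, fragment):
        with pytest.raises(ValueError, match=fragment.replace("+", r"\+")):
            syn.generate_sites(50, seed=0, **{**dict(frac_greening=0.3,
                                                     frac_browning=0.1), **kwargs})

    def test_same_seed_byte_identical(self):
        bufs = []
        for _ in range(2):
            df = syn.generate_sites(60, 0.3, 0.1, seed=42)
            buf = io.StringIO()
            df.to_csv(buf, index=False)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]


class TestSimulateObservations:
    def test_same_seed_byte_identical(self, sites100):
        a = syn.simulate_observations(sites100, range(1995, 2000), seed=7)
        b = syn.simulate_observations(sites100, range(1995, 2000), seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_physical_bounds(self, sites100):
        obs = syn.simulate_observations(sites100, range(1985, 2017), seed=8)
        assert obs["ndvi"].between(-1, 1).all()
        assert (obs[["red", "nir"]] > 0).all().all()
        assert (obs[["red", "nir"]] < 1).all().all()
        assert obs["doy"].between(152, 243).all()

    def test_noiseless_obs_equal_seasonal_curve(self, dense_noiseless):
        """With no noise and no sensor offset, every observation sits exactly
        on the site's seasonal trajectory for that year."""
        sub, obs, truth = dense_noiseless
        merged = obs.merge(truth, on=["site_id", "year"]) \
                    .merge(sub[["site_id", "peak_doy_true"]], on="site_id")
        expected = syn.seasonal_ndvi(merged["doy"], merged["peak_doy_true"],
                                     merged["ndvimax_true"])
        np.testing.assert_allclose(merged["ndvi"], expected, atol=1e-9)

    def test_observation_at_peak_equals_annual_max(self):
        val = syn.seasonal_ndvi(200.0, 200.0, 0.55)
        assert val == pytest.approx(0.55, abs=1e-12)

    def test_sensor_offset_shifts_ndvi_additively(self):
        s = syn.SensorModel("L8", ndvi_offset=0.02, radiometric_bound=0.03,
                            active_years=(2013, 2016))
        ref = syn.SensorModel("L7", ndvi_offset=0.0, radiometric_bound=0.05,
                              active_years=(1999, 2016))
        base = 0.41
        diff = syn.apply_sensor_offset(base, s) - syn.apply_sensor_offset(base, ref)
        assert diff == pytest.approx(0.02, abs=1e-12)

    def test_empty_sites_empty_output(self):
        empty = syn.generate_sites(1, 0, 0, seed=0).iloc[:0]
        obs = syn.simulate_observations(empty, range(2000, 2005), seed=1)
        assert obs.empty

    def test_density_schedule_medians_track_archive_profile(self):
        """Median clear-sky summer scene counts across 500 sites come out
        within +-1 of 0, 2, 4, 7 in 1985, 1995, 2005, 2015."""
        sites = syn.generate_sites(500, 0, 0, seed=21)
        obs = syn.simulate_observations(sites, range(1985, 2017), seed=22)
        counts = (obs.groupby(["site_id", "year"]).size()
                  .unstack(fill_value=0)
                  .reindex(index=sites["site_id"], columns=range(1985, 2017),
                           fill_value=0))
        for year, target in [(1985, 0), (1995, 2), (2005, 4), (2015, 7)]:
            med = counts[year].median()
            assert abs(med - target) <= 1, f"{year}: median {med} vs {target}"

    def test_reflectance_to_ndvi_roundtrip(self):
        red, nir = syn.ndvi_to_bands(0.37, 0.33)
        assert syn.bands_to_ndvi(red, nir) == pytest.approx(0.37)
        assert red + nir == pytest.approx(0.33)


class TestAnnualTruth:
    def test_ols_recovers_injected_slope_exactly(self, sites100):
        """Without noise or temperature coupling the truth is exactly linear."""
        truth = syn.annual_ndvimax_truth(sites100, range(1985, 2017))
        years = np.arange(1985, 2017)
        for site_id, slope in zip(sites100["site_id"][:20],
                                  sites100["trend_slope_true"][:20]):
            v = truth.loc[truth["site_id"] == site_id, "ndvimax_true"].to_numpy()
            fit = np.polyfit(years, v, 1)[0]
            assert fit == pytest.approx(slope, abs=1e-12)

    def test_swi_coupling_enters_truth(self, sites100):
        anom = {y: (1.0 if y % 2 else -1.0) for y in range(2000, 2010)}
        truth = syn.annual_ndvimax_truth(sites100.iloc[:3], range(2000, 2010),
                                         swi_anomaly=anom)
        base = syn.annual_ndvimax_truth(sites100.iloc[:3], range(2000, 2010))
        diff = truth["ndvimax_true"] - base["ndvimax_true"]
        coup = sites100.iloc[0]["temp_coupling"]
        assert abs(diff.iloc[1]) == pytest.approx(coup, abs=1e-12)


class TestTemperatureEnsemble:
    def test_no_warming_no_noise_constant_swi(self):
        t = syn.simulate_temperature_ensemble(
            2, cells=3, years=range(2000, 2010), warming_rate=0.0, seed=5,
            year_anomaly_sd=0, dataset_offset_sd=0, dataset_noise_sd=0,
            cell_offset_sd=0)
        swi = cl.compute_swi(t["monthly"][t["monthly"]["dataset"] == "d0"])
        assert swi.groupby("cell")["swi"].nunique().eq(1).all()

    def test_all_cold_months_zero_swi(self):
        t = syn.simulate_temperature_ensemble(
            2, cells=1, years=range(2000, 2005), warming_rate=0.0, seed=5,
            climatology=[-10.0] * 12, year_anomaly_sd=0, dataset_offset_sd=0,
            dataset_noise_sd=0, cell_offset_sd=0)
        swi = cl.compute_swi(t["monthly"][t["monthly"]["dataset"] == "d0"])
        assert (swi["swi"] == 0).all()

    def test_injected_swi_change_recovered(self):
        """A 5 degC SWI increase injected over 32 years is recovered by the
        ensemble-median Theil-Sen trend within two standard errors."""
        t = syn.simulate_temperature_ensemble(
            5, cells=30, years=range(1985, 2017), warming_rate=1.5625, seed=9)
        swis = cl.swi_from_monthly_table(t["monthly"])
        real = cl.synthesize_swi(swis, np.random.default_rng(10))
        cell_changes = []
        for _, g in real.groupby("cell"):
            s = g.set_index("year")["swi"]
            cell_changes.append(trd.theil_sen(s.to_numpy(), s.index.to_numpy()) * 31)
        mean_change = np.mean(cell_changes)
        se = np.std(cell_changes, ddof=1) / np.sqrt(len(cell_changes))
        assert abs(mean_change - 1.5625 * 3.1) <= 2 * max(se, 0.05)

    def test_requires_two_datasets(self):
        with pytest.raises(ValueError, match="n_datasets"):
            syn.simulate_temperature_ensemble(1, cells=1, years=range(2000, 2005))


class TestDrivers:
    def test_contains_correlated_pair(self, sites100):
        d = syn.simulate_drivers(sites100, 20, seed=13)
        corr = d.drop(columns="site_id").corr().abs()
        np.fill_diagonal(corr.values, 0)
        assert corr.values.max() > 0.75

    def test_predictor_floor_enforced(self, sites100):
        with pytest.raises(ValueError, match="n_predictors"):
            syn.simulate_drivers(sites100, 2, seed=13)

    def test_informative_predictors_separate_classes(self, sites100):
        d = syn.simulate_drivers(sites100, 20, seed=13)
        merged = d.merge(sites100[["site_id", "trend_class_true"]], on="site_id")
        means = merged.groupby("trend_class_true")["delta_swi"].mean()
        assert means["greening"] > means["none"] > means["browning"]


class TestFieldSeries:
    def test_perfect_coupling_preserves_ranks(self, sites100):
        truth = syn.annual_ndvimax_truth(sites100.iloc[:2], range(1990, 2018))
        fs = syn.simulate_field_series(truth, "ANPP", coupling=1.0, seed=14)
        for site, g in fs.groupby("site_id"):
            t = truth[truth["site_id"] == site].set_index("year")["ndvimax_true"]
            v = g.set_index("year")["value"]
            assert (t.rank() == v.rank()).all()

    def test_anpp_nonnegative_rwi_mean_one(self, sites100):
        truth = syn.annual_ndvimax_truth(sites100.iloc[:4], range(1990, 2018))
        anpp = syn.simulate_field_series(truth, "ANPP", 0.5, seed=15)
        rwi = syn.simulate_field_series(truth, "RWI", 0.5, seed=16)
        assert (anpp["value"] >= 0).all()
        for _, g in rwi.groupby("site_id"):
            assert g["value"].mean() == pytest.approx(1.0, abs=1e-9)

    def test_zero_coupling_mean_correlation_near_zero(self, sites100):
        """Over many replicate sites the mean rank correlation at zero
        coupling is within sampling error of zero."""
        from scipy.stats import spearmanr
        sites = syn.generate_sites(150, 0.37, 0.05, seed=17)
        truth = syn.annual_ndvimax_truth(sites, range(1985, 2017),
                                         interannual_sd=0.02, seed=18)
        fs = syn.simulate_field_series(truth, "GPP", coupling=0.0, seed=19)
        rs = []
        for site, g in fs.groupby("site_id"):
            t = truth[truth["site_id"] == site].set_index("year")["ndvimax_true"]
            v = g.set_index("year")["value"]
            rs.append(spearmanr(t.loc[v.index], v)[0])
        assert abs(np.mean(rs)) < 0.05

    def test_invalid_coupling_rejected(self, sites100):
        truth = syn.annual_ndvimax_truth(sites100.iloc[:1], range(2000, 2010))
        with pytest.raises(ValueError, match="coupling"):
            syn.simulate_field_series(truth, "ANPP", coupling=1.5)
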
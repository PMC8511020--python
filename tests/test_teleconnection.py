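"""Lagged-correlation detection and the population/land-area flag rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ensogrowth import synthetic as syn
from ensogrowth import teleconnection as tc
from tests.conftest import make_config


def toy_grid(pixel_values, years, months, pixels=None):
    """Assemble a ClimateGrid from a (n_pixels, T) array."""
    arr = np.asarray(pixel_values, dtype=float)
    n = arr.shape[0]
    if pixels is None:
        pixels = pd.DataFrame(
            {
                "pixel": np.arange(n),
                "lat": 0.0,
                "lon": np.arange(n) * 0.5,
                "country": "C00",
                "admin1": "C00A0",
                "population": 1.0,
                "land_area": 1.0,
            }
        )
    return tc.ClimateGrid(
        pixels=pixels, years=years, months=months, temperature=arr, precipitation=arr
    )


def monthly_series(n_years, start_year=1980, rng=None, values=None):
    t = np.arange(n_years * 12)
    years = start_year + t // 12
    months = t % 12 + 1
    if values is None:
        values = rng.standard_normal(len(t))
    return pd.DataFrame({"year": years, "month": months, "value": values})


class TestMonthlyLagCorrelation:
    def test_pixel_equal_to_lagged_index_has_r_one(self):
        rng = np.random.default_rng(0)
        series = monthly_series(30, rng=rng)
        vals = series["value"].to_numpy()
        years, months = series["year"].to_numpy()[2:], series["month"].to_numpy()[2:]
        grid = toy_grid(vals[:-2][None, :], years, months)
        r, p, n = tc.monthly_lag_correlation(grid, series, "temperature", lag=2, detrend=False)
        np.testing.assert_allclose(r[0], 1.0, atol=1e-12)
        assert (p[0] < 1e-12).all()

    def test_matches_pearson_on_hand_paired_vectors(self):
        rng = np.random.default_rng(1)
        series = monthly_series(30, rng=rng)
        vals = series["value"].to_numpy()
        years, months = series["year"].to_numpy()[2:], series["month"].to_numpy()[2:]
        noise = rng.standard_normal(len(years))
        pix = 0.8 * vals[:-2] + noise
        grid = toy_grid(pix[None, :], years, months)
        r, p, _ = tc.monthly_lag_correlation(grid, series, "temperature", lag=2, detrend=False)
        # oracle: pair month-m pixel values with the index two months back
        idx = {(y, m): v for y, m, v in series.itertuples(index=False)}
        for m in range(1, 13):
            sel = months == m
            yv = pix[sel]
            tpairs = years[sel] * 12 + (m - 1) - 2
            xv = np.array([idx[(t // 12, t % 12 + 1)] for t in tpairs])
            r_ref, p_ref = stats.pearsonr(yv, xv)
            assert r[0, m - 1] == pytest.approx(r_ref, abs=1e-10)
            assert p[0, m - 1] == pytest.approx(p_ref, rel=1e-6)

    def test_null_mean_significant_months_near_alpha_level(self):
        rng = np.random.default_rng(2)
        series = monthly_series(30, rng=rng)
        years, months = series["year"].to_numpy()[2:], series["month"].to_numpy()[2:]
        pix = rng.standard_normal((400, len(years)))
        grid = toy_grid(pix, years, months)
        r, p, _ = tc.monthly_lag_correlation(grid, series, "temperature", lag=2)
        counts = tc.significant_month_count(r, p, alpha=0.05)
        # E[count] = 12 * 0.05 = 0.6; 400 pixels x 12 months
        se = np.sqrt(12 * 0.05 * 0.95 / 400)
        assert abs(counts.mean() - 0.6) < 4 * se

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        series = monthly_series(25, rng=rng)
        years, months = series["year"].to_numpy()[2:], series["month"].to_numpy()[2:]
        pix = rng.standard_normal((3, len(years)))
        grid = toy_grid(pix, years, months)
        r1, _, _ = tc.monthly_lag_correlation(grid, series, "temperature")
        grid2 = toy_grid(2.5 * pix - 7.0, years, months)
        series2 = series.assign(value=-3.0 * series["value"] + 1.0)
        r2, _, _ = tc.monthly_lag_correlation(grid2, series2, "temperature")
        np.testing.assert_allclose(np.abs(r1), np.abs(r2), atol=1e-10)

    def test_zero_variance_pixel_is_degenerate_not_significant(self):
        rng = np.random.default_rng(4)
        series = monthly_series(20, rng=rng)
        years, months = series["year"].to_numpy()[2:], series["month"].to_numpy()[2:]
        pix = np.vstack([np.full(len(years), 3.14), rng.standard_normal(len(years))])
        grid = toy_grid(pix, years, months)
        r, p, _ = tc.monthly_lag_correlation(grid, series, "temperature", detrend=False)
        assert np.isnan(r[0]).all() and np.isnan(p[0]).all()
        assert tc.significant_month_count(r, p)[0] == 0

    def test_short_window_rejected(self):
        rng = np.random.default_rng(5)
        series = monthly_series(5, rng=rng)
        years, months = series["year"].to_numpy()[2:], series["month"].to_numpy()[2:]
        grid = toy_grid(rng.standard_normal((1, len(years))), years, months)
        with pytest.raises(ValueError, match=">= 10"):
            tc.monthly_lag_correlation(grid, series, "temperature")


class TestPixelFlagRule:
    def test_min_months_boundary(self):
        r = np.full((1, 12), 0.5)
        p = np.ones((1, 12))
        p[0, :3] = 0.01
        assert tc.pixel_teleconnected(r, p)[0]
        p[0, 2] = 0.2  # only 2 significant months now
        assert not tc.pixel_teleconnected(r, p)[0]

    def test_sign_restriction(self):
        r = np.full((1, 12), -0.6)
        p = np.full((1, 12), 1e-6)
        assert not tc.pixel_teleconnected(r, p, sign="positive")[0]
        assert tc.pixel_teleconnected(r, p, sign="negative")[0]
        assert tc.pixel_teleconnected(r, p, sign="any")[0]


class TestAggregationRules:
    def geography(self, pops, areas):
        n = len(pops)
        return pd.DataFrame(
            {
                "pixel": np.arange(n),
                "lat": 0.0,
                "lon": 0.0,
                "country": "X",
                "admin1": "XA",
                "population": pops,
                "land_area": areas,
            }
        )

    def test_country_rule_weak_inequality_at_half(self):
        px = self.geography([499, 501], [1, 1])
        assert not tc.country_teleconnected(np.array([True, False]), px, "X")
        px2 = self.geography([500, 500], [1, 1])
        assert tc.country_teleconnected(np.array([True, False]), px2, "X")
        assert tc.country_teleconnected(np.array([True, True]), px, "X")

    def test_admin_rule_strict_inequality_at_half(self):
        px = self.geography([1, 1], [50.0, 50.0])
        assert not tc.admin_positive_precip(np.array([True, False]), px, "XA")
        px2 = self.geography([1, 1], [51.0, 49.0])
        assert tc.admin_positive_precip(np.array([True, False]), px2, "XA")

    def test_mixed_country_matches_hand_summed_share(self):
        rng = np.random.default_rng(6)
        pops = rng.integers(1, 100, size=10).astype(float)
        px = self.geography(pops, np.ones(10))
        flags = rng.random(10) < 0.5
        share = pops[flags].sum() / pops.sum()
        assert tc.country_teleconnected(flags, px, "X") == (share >= 0.5)

    def test_zero_weight_errors(self):
        px = self.geography([0, 0], [0, 0])
        with pytest.raises(ValueError, match="population"):
            tc.country_teleconnected(np.array([True, True]), px, "X")
        with pytest.raises(ValueError, match="land area"):
            tc.admin_positive_precip(np.array([True, True]), px, "XA")

    def test_flags_monotone_in_flagged_weight(self):
        # raising a flagged pixel's weight can never turn a true flag false
        rng = np.random.default_rng(7)
        pops = rng.integers(1, 50, size=8).astype(float)
        flags = np.array([True, True, False, True, False, False, True, False])
        px = self.geography(pops, pops)
        if tc.country_teleconnected(flags, px, "X"):
            pops2 = pops.copy()
            pops2[0] *= 10
            px2 = self.geography(pops2, pops2)
            assert tc.country_teleconnected(flags, px2, "X")


class TestFullDetection:
    def test_planted_world_recovered_exactly(self, small_world):
        cfg = small_world.config
        tele = tc.build_teleconnection_map(small_world.grid, small_world.nino)
        truth = small_world.tele_truth
        assert tele.teleconnected_countries() == truth.teleconnected_countries()
        pd.testing.assert_series_equal(
            tele.admin_pos_precip, truth.admin_pos_precip, check_names=False
        )

    def test_map_csv_export(self, tmp_path, small_world):
        tele = syn.ground_truth_teleconnection(small_world.config)
        tele.write_csv(
            tmp_path / "px.csv", tmp_path / "country.csv", tmp_path / "admin.csv"
        )
        country = pd.read_csv(tmp_path / "country.csv")
        assert {"country", "teleconnected"} == set(country.columns)
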
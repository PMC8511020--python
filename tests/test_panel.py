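"""Fixed-effects WLS estimator, clustered variance, FWL and placebo tools."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.stats.sandwich_covariance import cov_cluster_2groups

from ensogrowth import panel as pn
from ensogrowth import synthetic as syn
from ensogrowth.pipeline import prepare_estimation_table
from tests.conftest import make_config


def small_table(seed=7, n=1500, **overrides):
    cfg = make_config(seed=seed, **overrides)
    world = syn.simulate_world(cfg, with_grid=False, n_children=n)
    table, _ = prepare_estimation_table(world.nino, world.tele_truth, world.children)
    return table


def explicit_design(design):
    """Exposure/controls plus one dummy per fixed-effect cell."""
    n = len(design.y)
    D = np.zeros((n, design.n_cells))
    D[np.arange(n), design.fe_codes] = 1.0
    return np.column_stack([design.X, D])


class TestFitFeWls:
    def test_exact_identification_on_noise_free_data(self):
        # no noise at all: the solver must return the planted coefficients
        # to machine precision
        table = small_table(
            n=2500,
            effects__child_noise_sd=0.0,
            survey__flagged_fraction=0.0,
            survey__missing_fraction=0.0,
            survey__missing_mother_fraction=0.0,
        )
        res = pn.fit_model(table, pn.ModelSpec())
        assert res.params["nino"] == pytest.approx(-0.0251, abs=1e-8)
        assert res.params["nino_x_pos_precip"] == pytest.approx(0.0733, abs=1e-8)
        assert res.r2 == pytest.approx(1.0, abs=1e-10)

    def test_matches_statsmodels_wls_with_explicit_dummies(self):
        table = small_table(n=900)
        design = pn.build_design(table, pn.ModelSpec())
        res = pn.fit_fe_wls(design)
        X = explicit_design(design)
        ref = sm.WLS(design.y, X, weights=design.w).fit()
        np.testing.assert_allclose(
            res.params.to_numpy(), ref.params[: design.X.shape[1]], atol=1e-8
        )

    def test_absorbed_and_explicit_dummies_agree(self, prepared_table, default_spec):
        design = pn.build_design(prepared_table, default_spec)
        a = pn.fit_fe_wls(design, absorb=True)
        b = pn.fit_fe_wls(design, absorb=False)
        common = a.params.index
        np.testing.assert_allclose(a.params, b.params[common], atol=1e-9)
        np.testing.assert_allclose(a.se, b.se[common], atol=1e-9)
        assert a.r2 == pytest.approx(b.r2, abs=1e-10)

    def test_weight_scale_invariance(self, prepared_table, default_spec):
        res = pn.fit_model(prepared_table, default_spec)
        scaled = prepared_table.copy()
        scaled["w"] = scaled["w"] * 137.0
        res2 = pn.fit_model(scaled, default_spec)
        np.testing.assert_allclose(res.params, res2.params, rtol=1e-10)
        np.testing.assert_allclose(res.se, res2.se, rtol=1e-8)
        assert res.r2 == pytest.approx(res2.r2, abs=1e-12)

    def test_collinear_column_pruned_with_log(self, prepared_table):
        # urban enters the country×urban cells, so a country-interacted
        # urban control is exactly collinear and must be pruned, not crash
        spec = pn.ModelSpec(controls=("mother_edu", "mother_age", "urban"))
        res = pn.fit_model(prepared_table, spec)
        assert any(name.startswith("urban:") for name in res.dropped)
        assert np.isfinite(res.params["nino"])

    def test_design_column_count_matches_combinatorics(self, prepared_table):
        design = pn.build_design(prepared_table, pn.ModelSpec())
        n_countries = prepared_table["country"].nunique()
        n_cols = 2 + 2 * n_countries  # exposure, interaction, 2 controls × country
        for r in prepared_table["region"].unique():
            months = prepared_table.loc[prepared_table.region == r, "int_month"].nunique()
            n_cols += months - 1  # reference month dropped per region
        n_cols += prepared_table["region"].nunique()  # linear trends
        assert design.X.shape[1] == n_cols

    def test_saturated_fixed_effects_rejected(self):
        # one fixed-effect cell per observation leaves nothing to estimate
        table = small_table(n=1500).sample(40, random_state=0).copy()
        table["rowid"] = np.arange(len(table))
        spec = pn.ModelSpec(fe_cells=("rowid",))
        with pytest.raises(ValueError, match="rank zero|parameters|single cluster"):
            pn.fit_model(table, spec)


class TestTwowayClusterVariance:
    def test_meat_matches_explicit_score_outer_products(self, prepared_table, default_spec):
        design = pn.build_design(prepared_table, default_spec)
        res = pn.fit_fe_wls(design, keep_meat=True)
        # rebuild scores by hand from the demeaned design and residuals
        Xd = pn._group_weighted_demean(design.X, design.fe_codes, design.w, design.n_cells)
        yd = pn._group_weighted_demean(design.y, design.fe_codes, design.w, design.n_cells)
        e = yd - Xd @ res.params.reindex(design.names).fillna(0.0).to_numpy()
        S = Xd * (design.w * e)[:, None]
        for dim in ("tropical_year", "admin1"):
            codes = design.clusters[dim]
            U = np.zeros((codes.max() + 1, S.shape[1]))
            np.add.at(U, codes, S)
            np.testing.assert_allclose(res.meat_components[dim], U.T @ U, rtol=1e-8)
        c1, c2 = design.clusters["tropical_year"], design.clusters["admin1"]
        inter = pd.factorize(c1.astype(np.int64) * (c2.max() + 1) + c2)[0]
        U = np.zeros((inter.max() + 1, S.shape[1]))
        np.add.at(U, inter, S)
        np.testing.assert_allclose(res.meat_components["intersection"], U.T @ U, rtol=1e-8)

    def test_matches_statsmodels_two_group_sandwich(self):
        table = small_table(n=800, effects__year_shock_sd=0.05)
        design = pn.build_design(table, pn.ModelSpec())
        res = pn.fit_fe_wls(design, small_sample=False)
        X = explicit_design(design)
        ref = sm.WLS(design.y, X, weights=design.w).fit()
        groups = np.column_stack(
            [design.clusters["tropical_year"], design.clusters["admin1"]]
        )
        cov_both = cov_cluster_2groups(ref, groups, use_correction=False)[0]
        k = design.X.shape[1]
        np.testing.assert_allclose(
            res.vcov.to_numpy()[:k, :k], cov_both[:k, :k], rtol=1e-6, atol=1e-12
        )

    def test_singleton_clusters_reduce_to_heteroskedastic_sandwich(self):
        table = small_table(n=700)
        table = table.reset_index(drop=True)
        table["obs_id"] = np.arange(len(table))
        spec = pn.ModelSpec(clusters=("obs_id", "obs_id2"))
        table["obs_id2"] = table["obs_id"]
        design = pn.build_design(table, spec)
        res = pn.fit_fe_wls(design, small_sample=False)
        # direct HC sandwich on the demeaned design
        Xd = pn._group_weighted_demean(design.X, design.fe_codes, design.w, design.n_cells)
        yd = pn._group_weighted_demean(design.y, design.fe_codes, design.w, design.n_cells)
        beta = res.params.reindex(design.names).fillna(0.0).to_numpy()
        e = yd - Xd @ beta
        bread = np.linalg.inv(Xd.T @ (Xd * design.w[:, None]))
        meat = (Xd * (design.w * e)[:, None]).T @ (Xd * (design.w * e)[:, None])
        V = bread @ meat @ bread
        np.testing.assert_allclose(res.vcov.to_numpy(), V, rtol=1e-7)

    def test_single_cluster_dimension_rejected(self, prepared_table):
        table = prepared_table.copy()
        table["one"] = 1
        with pytest.raises(ValueError, match="single cluster"):
            pn.build_design(table, pn.ModelSpec(clusters=("one", "admin1")))


class TestFrischWaughLovell:
    def test_partialled_slope_equals_joint_coefficient(self, prepared_table, default_spec):
        res = pn.fit_model(prepared_table, default_spec)
        slope, _, _ = pn.partial_out(prepared_table, default_spec)
        assert slope == pytest.approx(res.params["nino"], rel=1e-12)

    def test_curve_global_slope_equals_subsample_fit(self, prepared_table, default_spec):
        curves = pn.fwl_residual_curve(prepared_table, default_spec)
        sub_spec = dataclasses.replace(default_spec, include_interaction=False)
        for label, mask in (
            ("neg_neutral", ~prepared_table["pos_precip"]),
            ("positive", prepared_table["pos_precip"]),
        ):
            res = pn.fit_model(prepared_table.loc[mask], sub_spec)
            assert curves[label].slope == pytest.approx(res.params["nino"], rel=1e-10)

    def test_epanechnikov_support(self):
        u = np.array([-1.5, -1.0, -0.5, 0.0, 0.5, 1.0, 1.5])
        k = pn.epanechnikov(u)
        assert (k[np.abs(u) >= 1.0] == 0).all()
        assert k[3] == pytest.approx(0.75)

    def test_local_linear_recovers_line(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(-2, 2, 600)
        y = 1.5 * x - 0.3
        fit, se = pn.local_polynomial(x, y, np.ones_like(x), np.array([0.0, 1.0]), 0.7)
        np.testing.assert_allclose(fit, [-0.3, 1.2], atol=1e-8)
        np.testing.assert_allclose(se, 0.0, atol=1e-6)

    def test_bad_bandwidth(self, prepared_table, default_spec):
        with pytest.raises(ValueError, match="bandwidth"):
            pn.fwl_residual_curve(prepared_table, default_spec, bandwidth=0.0)


class TestPlacebo:
    def test_identity_permutation_reproduces_observed(self, prepared_table, default_spec):
        pl = pn.placebo_randomization(
            prepared_table, default_spec, n_perm=5, seed=0, include_identity=True
        )
        assert pl.draws[0] == pytest.approx(pl.observed, rel=1e-10)
        res = pn.fit_model(prepared_table, default_spec)
        assert pl.observed == pytest.approx(res.params["nino"], rel=1e-10)

    def test_rank_p_value_definition(self, prepared_table, default_spec):
        pl = pn.placebo_randomization(prepared_table, default_spec, n_perm=49, seed=1)
        expected = (1 + np.sum(np.abs(pl.draws) >= abs(pl.observed))) / 50
        assert pl.p_value == pytest.approx(expected)

    def test_too_few_years_rejected(self, prepared_table, default_spec):
        sub = prepared_table[prepared_table["tropical_year"] < prepared_table["tropical_year"].min() + 3]
        with pytest.raises(ValueError, match="5 distinct"):
            pn.placebo_randomization(sub, default_spec, n_perm=10, seed=0)


class TestSubsampleEffects:
    def test_full_sample_stratum_equals_pooled_estimate(self):
        # a world whose waves all fall in one decade: the decade "split" is
        # the identity partition and must reproduce the pooled estimate
        cfg = make_config(seed=13, n_years=10, start_year=1990)
        world = syn.simulate_world(cfg, with_grid=False, n_children=4000)
        table, _ = prepare_estimation_table(world.nino, world.tele_truth, world.children)
        spec = pn.ModelSpec()
        out = pn.subsample_effects(table, spec, by="decade")
        assert len(out) == 1
        pooled = pn.fit_model(
            table.loc[~table["pos_precip"]],
            dataclasses.replace(spec, include_interaction=False),
            spectral_fix=True,
        )
        assert out["estimate"].iloc[0] == pytest.approx(pooled.params["nino"], rel=1e-10)

    def test_region_strata_cover_sample(self, prepared_table, default_spec):
        out = pn.subsample_effects(prepared_table, default_spec, by="region")
        nonpos = prepared_table.loc[~prepared_table["pos_precip"]]
        assert out["n"].sum() == len(nonpos)
        assert set(out["stratum"]) == set(nonpos["region"].unique())
        assert np.isfinite(out[["estimate", "se"]].to_numpy()).all()

    def test_unknown_stratifier_rejected(self, prepared_table, default_spec):
        with pytest.raises(ValueError, match="decade|region"):
            pn.subsample_effects(prepared_table, default_spec, by="country")


class TestSpecToggles:
    def test_decade_fe_and_unweighted_variants_run(self, prepared_table):
        spec = pn.ModelSpec(trend="decade_fe", weight_col=None)
        res = pn.fit_model(prepared_table, spec)
        assert np.isfinite(res.params["nino"])

    def test_age_interaction_adds_term(self, prepared_table):
        res = pn.fit_model(prepared_table, pn.ModelSpec(age_interaction=True))
        assert "nino_x_age24plus" in res.params.index

    def test_lagged_exposure_columns_used(self, prepared_table, small_world):
        from ensogrowth import exposure as expo

        table = prepared_table.copy()
        means = expo.tropical_year_means(small_world.nino)
        lag_map = {t: means.get(t - 1, np.nan) for t in table["tropical_year"].unique()}
        table["nino_lag1"] = table["tropical_year"].map(lag_map)
        table = table.dropna(subset=["nino_lag1"])
        res = pn.fit_model(table, pn.ModelSpec(lagged_exposures=1))
        assert "nino_lag1" in res.params.index
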
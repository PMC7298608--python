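"""Survey design, field simulation and the full synthetic survey generator."""

import numpy as np
import pandas as pd
import pytest

from graingeo.covariance import (
    Coregionalization,
    MaternCorrelation,
    empirical_variogram,
    matern_corr,
)
from graingeo.synthetic import (
    COVARIATE_NAMES,
    SOIL_PROPERTIES,
    SurveyConfig,
    assemble_survey,
    draw_design,
    gaussian_field_grid,
    plot_layout,
    simulate_fields,
)


class TestPlotLayout:
    def test_five_offsets_with_printed_radii(self):
        pts = plot_layout()
        assert len(pts) == 5
        assert pts[0] == (0.0, 0.0)
        # long axis: circumferences of the 100- and 75-m^2 subplots
        assert pts[1] == (5.64, 0.0)
        assert pts[2] == (-4.89, 0.0)
        # short axis: 25- and 50-m^2 subplots
        assert abs(pts[3][1]) == 2.82
        assert abs(pts[4][1]) == 3.99


class TestDrawDesign:
    def test_default_counts(self):
        d = draw_design(SurveyConfig())
        assert (~d["close_pair"]).sum() == 475
        assert d["close_pair"].sum() == 25

    def test_close_pair_distances_within_bounds(self):
        cfg = SurveyConfig()
        d = draw_design(cfg)
        pairs = d[d["close_pair"]]
        prim = d.set_index("site_id")
        for _, row in pairs.iterrows():
            p = prim.loc[int(row["pair_of"])]
            dist_m = 1000.0 * np.hypot(row["x_km"] - p["x_km"], row["y_km"] - p["y_km"])
            assert 100.0 <= dist_m <= 1000.0

    def test_no_close_pairs_gives_primary_only(self):
        cfg = SurveyConfig(n_close_pairs=0)
        d = draw_design(cfg)
        assert len(d) == cfg.n_primary

    def test_quadrant_spread(self):
        cfg = SurveyConfig()
        d = draw_design(cfg)
        prim = d[~d["close_pair"]]
        W, H = cfg.frame_km
        qx = prim["x_km"] > W / 2
        qy = prim["y_km"] > H / 2
        for fx in (qx, ~qx):
            for fy in (qy, ~qy):
                assert (fx & fy).mean() >= 0.15

    def test_coordinates_inside_frame(self):
        cfg = SurveyConfig(frame_km=(80.0, 50.0), n_primary=100, n_close_pairs=10)
        d = draw_design(cfg)
        assert d["x_km"].between(0, 80).all()
        assert d["y_km"].between(0, 50).all()

    def test_deterministic_given_seed(self):
        d1 = draw_design(SurveyConfig(seed=3))
        d2 = draw_design(SurveyConfig(seed=3))
        pd.testing.assert_frame_equal(d1, d2)
        assert d1.to_csv() == d2.to_csv()

    def test_frame_too_small_raises(self):
        with pytest.raises(ValueError, match="too small"):
            draw_design(SurveyConfig(frame_km=(3.0, 3.0), grid_spacing_km=0.5,
                                     n_primary=400, n_close_pairs=0))

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            SurveyConfig(n_primary=0)
        with pytest.raises(ValueError):
            SurveyConfig(teff_fraction=1.5)
        with pytest.raises(ValueError):
            SurveyConfig(close_pair_bounds_m=(500.0, 100.0))


class TestSimulateFields:
    def test_nugget_only_variance(self):
        coreg = Coregionalization([[0.7]], [[0.0]], MaternCorrelation(0.5, 5.0))
        coords = np.random.default_rng(1).uniform(0, 100, (10000, 2))
        z = simulate_fields(coords, coreg, 5)
        assert np.var(z[:, 0]) == pytest.approx(0.7, rel=0.05)

    def test_zero_covariance_gives_zero_field(self):
        coreg = Coregionalization(np.zeros((2, 2)), np.zeros((2, 2)),
                                  MaternCorrelation(1.0, 5.0))
        z = simulate_fields(np.random.uniform(0, 10, (50, 2)), coreg, 1)
        assert np.all(z == 0.0)

    def test_cross_correlation_grows_as_nugget_vanishes(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 60, (500, 2))
        m = MaternCorrelation(0.5, 10.0)
        r = 0.9

        def field_corr(nugget_share):
            s = 1.0 - nugget_share
            S = s * np.array([[1.0, r], [r, 1.0]])
            T = nugget_share * np.eye(2)
            z = simulate_fields(coords, Coregionalization(T, S, m), 7)
            return np.corrcoef(z[:, 0], z[:, 1])[0, 1]

        lo, hi = field_corr(0.6), field_corr(0.05)
        assert 0 < lo < hi <= 0.95

    def test_variogram_matches_generating_model(self):
        """Binned Matheron variogram within 15% of the model at phi and 2*phi."""
        tau2, sigma2, phi = 0.2, 0.8, 10.0
        m = MaternCorrelation(0.5, phi)
        coreg = Coregionalization([[tau2]], [[sigma2]], m)
        rng = np.random.default_rng(12)
        coords = rng.uniform(0, 240, (2000, 2))
        z = simulate_fields(coords, coreg, rng)[:, 0]
        edges = np.array([8.0, 12.0, 18.0, 22.0])  # bins centred near phi, 2*phi
        ev = empirical_variogram(z, coords, bin_edges=edges)
        for lag, gamma in [(ev.lags[0], ev.gamma[0]), (ev.lags[2], ev.gamma[2])]:
            model_gamma = tau2 + sigma2 * (1.0 - matern_corr(lag, m))
            assert gamma == pytest.approx(model_gamma, rel=0.15)


class TestAssembleSurvey:
    def test_schema(self, small_survey):
        t = small_survey.table
        for col in ["site_id", "x_km", "y_km", "crop", "close_pair",
                    "grain_se_mg_kg"] + SOIL_PROPERTIES:
            assert col in t.columns
        assert set(t["crop"].unique()) <= {"teff", "wheat"}
        assert (t["grain_se_mg_kg"] > 0).all()
        assert (t["se_nit"] > 0).all() and (t["se_pho"] > 0).all()
        assert set(small_survey.grids) == set(COVARIATE_NAMES)

    def test_one_crop_one_grain_value_per_site(self, small_survey):
        t = small_survey.table
        assert t["site_id"].is_unique
        assert t["grain_se_mg_kg"].notna().all()

    def test_grids_share_geometry(self, small_survey):
        grids = list(small_survey.grids.values())
        assert all(g.same_geometry(grids[0]) for g in grids)

    def test_deterministic_given_seed(self):
        cfg = SurveyConfig(frame_km=(50.0, 50.0), n_primary=40, n_close_pairs=4,
                           covariate_cell_km=5.0, seed=2)
        s1 = assemble_survey(cfg)
        s2 = assemble_survey(cfg)
        assert s1.table.to_csv() == s2.table.to_csv()  # byte-identical
        np.testing.assert_array_equal(s1.grids["slope"].values,
                                      s2.grids["slope"].values)

    def test_different_seeds_same_schema_different_values(self):
        c1 = SurveyConfig(frame_km=(50.0, 50.0), n_primary=40, n_close_pairs=4,
                          covariate_cell_km=5.0, seed=2)
        c2 = SurveyConfig(frame_km=(50.0, 50.0), n_primary=40, n_close_pairs=4,
                          covariate_cell_km=5.0, seed=3)
        s1, s2 = assemble_survey(c1), assemble_survey(c2)
        assert list(s1.table.columns) == list(s2.table.columns)
        assert not np.allclose(s1.table["grain_se_mg_kg"], s2.table["grain_se_mg_kg"])

    def test_null_effects_give_constant_grain(self):
        cfg = SurveyConfig(
            frame_km=(50.0, 50.0), n_primary=30, n_close_pairs=0,
            covariate_cell_km=5.0, true_soil_coefs={}, latent_effect=0.0,
            nugget_vars=(0.0, 0.0), correlated_vars=(0.0, 0.0),
            beta0=(-2.0, -2.0), seed=4,
        )
        s = assemble_survey(cfg)
        np.testing.assert_allclose(s.table["grain_se_mg_kg"], np.exp(-2.0), rtol=1e-12)

    def test_truth_record_contents(self, small_survey):
        truth = small_survey.truth
        assert truth["kappa"] == small_survey.config.kappa
        assert set(truth["true_soil_coefs"]) <= set(SOIL_PROPERTIES)
        assert "precipitation" in truth["signal_covariates"]


class TestGaussianFieldGrid:
    def test_white_noise_limit(self):
        rng = np.random.default_rng(0)
        f = gaussian_field_grid(60, 60, 1.0, lambda d: (d == 0).astype(float), rng)
        assert np.var(f) == pytest.approx(1.0, rel=0.1)
        assert abs(np.corrcoef(f[:, :-1].ravel(), f[:, 1:].ravel())[0, 1]) < 0.05

    def test_smooth_field_is_locally_correlated(self):
        rng = np.random.default_rng(1)
        f = gaussian_field_grid(80, 80, 1.0, lambda d: np.exp(-d / 10.0), rng)
        assert np.corrcoef(f[:, :-1].ravel(), f[:, 1:].ravel())[0, 1] > 0.8
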
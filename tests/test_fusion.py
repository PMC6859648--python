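"""Residuals, covariance estimation and fitting, ordinary kriging, and
the fused surface."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from aqfuse.dispersion import ConcentrationField, ReceptorGrid
from aqfuse.fusion import (
    CovarianceModel,
    ResidualKriging,
    compute_residuals,
    experimental_covariance,
    fit_exponential,
    fuse,
    krige,
)
from aqfuse.monitoring import ObservationSet


def obs_set(coords, z, o):
    coords = np.asarray(coords, dtype=float)
    return ObservationSet(pd.DataFrame({
        "id": [f"s{i}" for i in range(len(coords))],
        "kind": "stationary",
        "x": coords[:, 0], "y": coords[:, 1],
        "z": np.asarray(z, dtype=float), "o": np.asarray(o, dtype=float),
    }))


class TestResiduals:
    def test_equal_vectors_zero_residuals(self):
        obs = obs_set([(0, 0), (1, 0), (0, 1)], [1, 2, 3], [1, 2, 3])
        r = compute_residuals(obs)
        assert (r["residual"] == 0).all()
        assert r.attrs["mean_residual"] == 0.0

    def test_constant_offset(self):
        obs = obs_set([(0, 0), (1, 0)], [3, 4], [1, 2])
        r = compute_residuals(obs)
        np.testing.assert_allclose(r["residual"], 2.0)

    def test_underprediction_scenario(self):
        z = np.array([2.0, 4.0, 6.0])
        obs = obs_set([(0, 0), (1, 0), (2, 0)], z, 0.5 * z)
        r = compute_residuals(obs)
        np.testing.assert_allclose(r["residual"], 0.5 * z)


class TestExperimentalCovariance:
    def test_constant_residuals_zero_covariance(self):
        coords = np.random.default_rng(0).uniform(0, 1000, (10, 2))
        emp = experimental_covariance(coords, np.full(10, 5.0))
        np.testing.assert_allclose(emp["covariance"], 0.0, atol=1e-20)

    def test_zero_lag_bin_is_sample_variance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        coords = rng.uniform(0, 1000, (30, 2))
        emp = experimental_covariance(coords, x)
        assert emp.iloc[0]["lag"] == 0.0
        assert emp.iloc[0]["covariance"] == pytest.approx(x.var(), rel=1e-12)

    def test_single_site_rejected(self):
        with pytest.raises(ValueError):
            experimental_covariance(np.array([[0.0, 0.0]]), np.array([1.0]))

    def test_recovers_generating_exponential_model(self):
        """Residuals drawn from C(h)=1*exp(-3h/2000) at 200 sites: the
        binned estimate stays within 3 standard errors of the model."""
        rng = np.random.default_rng(7)
        coords = rng.uniform(0, 5000, (200, 2))
        model = CovarianceModel(sill=1.0, range_m=2000.0)
        cov = model(cdist(coords, coords))
        np.fill_diagonal(cov, model.sill * (1 + 1e-9))
        x = np.linalg.cholesky(cov) @ rng.standard_normal(200)
        emp = experimental_covariance(coords, x, n_lags=8)
        for _, row in emp.iterrows():
            if row["sparse"]:
                continue
            se = 3.0 * model.sill / np.sqrt(row["n_pairs"])
            assert abs(row["covariance"] - model(row["lag"])) < 3 * se


class TestFitExponential:
    def test_noise_free_self_consistency(self):
        lags = np.linspace(0, 4000, 12)
        cov = 2.0 * np.exp(-3.0 * lags / 1500.0)
        fit = fit_exponential(lags, cov, np.full(12, 50))
        assert fit.sill == pytest.approx(2.0, rel=0.01)
        assert fit.range_m == pytest.approx(1500.0, rel=0.01)
        assert not fit.at_range_bound

    def test_flat_positive_covariance_hits_range_bound(self):
        lags = np.linspace(0, 3000, 8)
        fit = fit_exponential(lags, np.full(8, 1.3), np.full(8, 20))
        assert fit.at_range_bound

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential(np.array([0.0, 1.0]), np.array([1.0, 0.5]),
                            np.array([5, 5]))


class TestKrige:
    MODEL = CovarianceModel(sill=1.0, range_m=1000.0)

    def test_exactness_at_data_points(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(0, 2000, (8, 2))
        x = rng.normal(size=8)
        est, var = krige(coords, x, self.MODEL, coords)
        np.testing.assert_allclose(est, x, atol=1e-7)
        np.testing.assert_allclose(var, 0.0, atol=1e-7)

    def test_symmetric_pair_gives_half_weights(self):
        coords = np.array([[0.0, 0.0], [2000.0, 0.0]])
        target = np.array([[1000.0, 0.0]])
        est, var, w = krige(coords, np.array([1.0, 3.0]), self.MODEL,
                            target, return_weights=True)
        np.testing.assert_allclose(w[0], [0.5, 0.5], atol=1e-10)
        assert est[0] == pytest.approx(2.0)

    def test_weights_match_dense_linear_system_oracle(self):
        """5-point configuration solved independently with the full
        (n+1) system assembled by hand."""
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 3000, (5, 2))
        x = rng.normal(size=5)
        target = np.array([[1200.0, 900.0]])
        est, var, w = krige(coords, x, self.MODEL, target,
                            return_weights=True)
        c_dd = self.MODEL(cdist(coords, coords)) + 1e-10 * np.eye(5)
        k = np.block([[c_dd, np.ones((5, 1))],
                      [np.ones((1, 5)), np.zeros((1, 1))]])
        rhs = np.append(self.MODEL(cdist(target, coords))[0], 1.0)
        sol = np.linalg.solve(k, rhs)
        np.testing.assert_allclose(w[0], sol[:5], atol=1e-8)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(4)
        coords = rng.uniform(0, 3000, (12, 2))
        x = rng.normal(size=12)
        targets = rng.uniform(0, 3000, (20, 2))
        _, _, w = krige(coords, x, self.MODEL, targets, return_weights=True)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-9)

    def test_far_field_tends_to_residual_mean(self):
        """Beyond 5x the range from all (mutually uncorrelated) sites,
        the estimate collapses to the residual mean."""
        rng = np.random.default_rng(5)
        # sites spaced far apart relative to the range, so the implicit
        # generalized-least-squares mean is the arithmetic mean
        coords = rng.uniform(0, 50_000, (10, 2))
        x = rng.normal(2.5, 1.0, size=10)
        far = np.array([[120_000.0, 120_000.0]])
        est, var = krige(coords, x, self.MODEL, far)
        assert abs(est[0] - x.mean()) < 0.01 * np.sqrt(self.MODEL.sill)

    def test_variance_nondecreasing_along_ray(self):
        """1-D site layout: kriging variance grows with distance from
        the nearest datum."""
        coords = np.column_stack([np.arange(5) * 500.0, np.zeros(5)])
        x = np.ones(5)
        ds = np.linspace(0, 3000, 40)
        targets = np.column_stack([2000.0 + ds, np.zeros(40)])
        _, var = krige(coords, x, self.MODEL, targets)
        assert np.all(np.diff(var) >= -1e-10)

    def test_duplicate_coordinates_reported(self):
        coords = np.array([[0.0, 0.0], [0.0, 0.0], [500.0, 0.0]])
        with pytest.raises(np.linalg.LinAlgError, match="duplicated"):
            krige(coords, np.array([1.0, 2.0, 3.0]), self.MODEL,
                  np.array([[100.0, 100.0]]))


class TestFuseAndModelSurface:
    def model_field(self, values):
        n = values.shape[0]
        grid = ReceptorGrid((0, 0), n, n, 100.0)
        return ConcentrationField(grid=grid, pollutant="ec25",
                                  values={"all": values})

    def test_zero_residual_field_returns_model(self):
        surface = np.random.default_rng(6).random((4, 4))
        field = self.model_field(surface)
        fused = fuse(field, np.zeros(16), np.zeros(16))
        np.testing.assert_allclose(fused.values, surface)
        assert fused.n_floored == 0

    def test_negative_fused_values_floored_and_counted(self):
        field = self.model_field(np.full((3, 3), 0.1))
        fused = fuse(field, np.full(9, -0.5), np.ones(9))
        assert np.all(fused.values == 0.0)
        assert fused.n_floored == 9

    def test_grid_shape_mismatch_rejected(self):
        field = self.model_field(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            fuse(field, np.zeros(5), np.zeros(5))


class TestResidualKrigingModel:
    def synthetic_obs(self, n=27, seed=11):
        """Sites with spatially correlated model underprediction."""
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, 8000, (n, 2))
        model = CovarianceModel(sill=0.04, range_m=3000.0)
        cov = model(cdist(coords, coords))
        np.fill_diagonal(cov, model.sill * (1 + 1e-9))
        deficit = 0.2 + np.linalg.cholesky(cov) @ rng.standard_normal(n)
        o = rng.uniform(0.5, 1.5, n)
        return obs_set(coords, o + deficit, o)

    def test_fit_reports_positive_covariance_parameters(self):
        res = ResidualKriging(self.synthetic_obs()).fit()
        assert res.covariance.sill > 0
        assert res.covariance.range_m > 0
        assert res.params["nugget"] == 0.0

    def test_in_sample_fusion_reproduces_observations(self):
        obs = self.synthetic_obs()
        res = ResidualKriging(obs).fit()
        scores = res.predict_at_sites(loo=False)
        np.testing.assert_allclose(scores["fused"], scores["z"], atol=1e-8)

    def test_loo_differs_from_in_sample(self):
        obs = self.synthetic_obs()
        res = ResidualKriging(obs).fit()
        loo = res.predict_at_sites(loo=True)
        assert not np.allclose(loo["fused"], loo["z"], atol=1e-8)

    def test_covariance_plot_shows_fit_curve(self):
        import matplotlib
        matplotlib.use("Agg")
        res = ResidualKriging(self.synthetic_obs()).fit()
        ax = res.plot_covariance()
        assert ax.get_xlabel() == "lag h [m]"
        assert len(ax.lines) >= 1

    def test_summary_mentions_fit_quantities(self):
        res = ResidualKriging(self.synthetic_obs()).fit()
        text = res.summary()
        assert "sill" in text and "range" in text and "n sites" in text

    def test_fused_grid_exact_at_sites_via_direct_prediction(self):
        obs = self.synthetic_obs(n=12)
        res = ResidualKriging(obs).fit()
        est, var = res.predict_residual(obs.coords)
        fused_at_sites = obs.o + est
        np.testing.assert_allclose(fused_at_sites, obs.z, atol=1e-8)
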
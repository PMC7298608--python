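"""Likelihood correctness, GLS identities, LR tests and parameter recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from graingeo.covariance import Coregionalization, MaternCorrelation, build_joint_cov
from graingeo.lmm import (
    CoregPacker,
    LMMFit,
    ObservationStack,
    adjusted_r2,
    fit_lmm,
    lr_test,
    negloglik,
    profile_kappa,
    univariate_stack,
)
from conftest import univariate_spatial_frame


def _const_stack(y, coords, X=None, labels=None):
    n = len(y)
    return ObservationStack(
        var=np.zeros(n, int), site=np.arange(n), coords=coords, y=y,
        X=X if X is not None else np.ones((n, 1)),
        labels=labels or ["const"],
    )


class TestNegloglik:
    def test_iid_matches_closed_form(self, rng):
        n = 60
        y = rng.normal(2.0, 1.0, n)
        coords = rng.uniform(0, 10, (n, 2))
        stack = _const_stack(y, coords)
        packer = CoregPacker(1, 0.5)
        s2 = 1.7
        coreg = Coregionalization([[s2]], [[0.0]], MaternCorrelation(0.5, 3.0))
        nll = negloglik(packer.pack(coreg), stack, packer, "ML")
        r = y - y.mean()  # GLS mean under iid = sample mean
        closed = 0.5 * (n * np.log(2 * np.pi * s2) + np.sum(r**2) / s2)
        assert nll == pytest.approx(closed, abs=1e-8)

    def test_reml_ml_determinant_identity(self, rng):
        """REML nll - ML nll = 0.5 log|X'V^-1 X| - (k/2) log 2pi at any params."""
        n, k = 10, 2
        coords = rng.uniform(0, 20, (n, 2))
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        stack = _const_stack(y, coords, X, ["const", "x1"])
        packer = CoregPacker(1, 1.5)
        coreg = Coregionalization([[0.4]], [[0.8]], MaternCorrelation(1.5, 5.0))
        x = packer.pack(coreg)
        ml = negloglik(x, stack, packer, "ML")
        reml = negloglik(x, stack, packer, "REML")
        V = build_joint_cov(stack.var, coords, coreg, site_id=stack.site)
        Vi = np.linalg.inv(V)
        _, logdetA = np.linalg.slogdet(X.T @ Vi @ X)
        assert reml - ml == pytest.approx(0.5 * logdetA - 0.5 * k * np.log(2 * np.pi),
                                          abs=1e-8)

    def test_gls_beta_invariant_to_covariance_scale(self, rng):
        df = univariate_spatial_frame(50, seed=2, frame=40.0)
        stack = univariate_stack(df, "resp")
        packer = CoregPacker(1, 0.5)
        m = MaternCorrelation(0.5, 8.0)

        def beta_at(scale):
            coreg = Coregionalization([[0.4 * scale]], [[0.6 * scale]], m)
            V = build_joint_cov(stack.var, stack.coords, coreg, site_id=stack.site)
            Vi = np.linalg.inv(V)
            A = stack.X.T @ Vi @ stack.X
            return np.linalg.solve(A, stack.X.T @ Vi @ stack.y)

        np.testing.assert_allclose(beta_at(1.0), beta_at(7.3), rtol=1e-10)

    def test_row_order_invariance(self, rng):
        df = univariate_spatial_frame(30, seed=3, frame=40.0)
        stack = univariate_stack(df, "resp")
        perm = rng.permutation(30)
        shuffled = ObservationStack(stack.var[perm], stack.site[perm],
                                    stack.coords[perm], stack.y[perm],
                                    stack.X[perm], stack.labels)
        packer = CoregPacker(1, 0.5)
        coreg = Coregionalization([[0.5]], [[0.5]], MaternCorrelation(0.5, 10.0))
        x = packer.pack(coreg)
        assert negloglik(x, stack, packer, "ML") == pytest.approx(
            negloglik(x, shuffled, packer, "ML"), abs=1e-10)


class TestGLSBruteForce:
    def test_matches_weighted_least_squares(self, rng):
        """At fixed covariance, GLS beta equals brute-force WLS with V^-1."""
        n = 12
        coords = rng.uniform(0, 15, (n, 2))
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        stack = _const_stack(y, coords, X, ["const", "x1"])
        coreg = Coregionalization([[0.3]], [[0.7]], MaternCorrelation(2.0, 5.0))
        fit = fit_lmm(stack, method="ML", kappa=2.0)
        V = build_joint_cov(stack.var, coords, fit.coreg, site_id=stack.site)
        Vi = np.linalg.inv(V)
        beta_bf = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        np.testing.assert_allclose(fit.beta, beta_bf, atol=1e-8)


class TestFitUnivariate:
    def test_parameter_recovery(self):
        """Median estimates across replicates near truth (sigma2=tau2=0.5, phi=15)."""
        taus, sigmas, phis = [], [], []
        for seed in range(12):
            df = univariate_spatial_frame(300, seed=seed, frame=300.0,
                                          tau2=0.5, sigma2=0.5, phi=15.0)
            fit = fit_lmm(univariate_stack(df, "resp"), method="ML", kappa=0.5)
            taus.append(fit.coreg.T[0, 0])
            sigmas.append(fit.coreg.S[0, 0])
            phis.append(fit.phi)
        assert abs(np.median(taus) - 0.5) < 0.125
        assert abs(np.median(sigmas) - 0.5) < 0.125
        assert 7.5 < np.median(phis) < 30.0

    def test_no_spurious_spatial_variance_under_iid_truth(self, rng):
        """With S = 0 truth the fitted spatial variance is not LR-significant."""
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            n = 80
            y = r.normal(size=n)
            coords = r.uniform(0, 50, (n, 2))
            stack = _const_stack(y, coords)
            fit = fit_lmm(stack, method="ML", kappa=0.5)
            # closed-form nugget-only ML log-likelihood
            resid = y - y.mean()
            s2 = np.mean(resid**2)
            ll0 = -0.5 * (n * np.log(2 * np.pi * s2) + n)
            dev = max(2 * (fit.loglik - ll0), 0.0)
            if chi2.sf(dev, 2) > 0.05:
                hits += 1
        assert hits >= 8

    def test_duplicated_variable_recovers_unit_correlation(self):
        """Two identical variables (same sites, same values) -> cross-corr near 1."""
        df = univariate_spatial_frame(60, seed=9, frame=100.0)
        frames = [df, df.assign(resp=df["resp"])]
        from graingeo.lmm import build_stack

        stack = build_stack(frames, [[], []], "resp", var_names=["a", "b"])
        fit = fit_lmm(stack, method="ML", kappa=0.5, n_starts=2, mask01=False,
                      maxiter=3000)
        total = fit.coreg.T + fit.coreg.S
        r = total[0, 1] / np.sqrt(total[0, 0] * total[1, 1])
        assert r > 0.95


class TestLRTest:
    def _fit_like(self, labels, loglik, method="ML"):
        coreg = Coregionalization([[0.5]], [[0.5]], MaternCorrelation(0.5, 5.0))
        k = len(labels)
        return LMMFit(labels=labels, beta=np.zeros(k), beta_se=np.zeros(k),
                      coreg=coreg, loglik=loglik, method=method, n_obs=50)

    def test_equal_likelihood_gives_p_one(self):
        f0 = self._fit_like(["const"], -100.0)
        f1 = self._fit_like(["const", "x"], -100.0)
        assert lr_test(f0, f1) == 1.0

    def test_chi2_quantile(self):
        f0 = self._fit_like(["const"], -100.0)
        f1 = self._fit_like(["const", "x"], -100.0 + 3.841 / 2.0)
        assert lr_test(f0, f1) == pytest.approx(0.050, abs=5e-4)

    def test_negative_deviance_clamped_with_warning(self):
        f0 = self._fit_like(["const"], -100.0)
        f1 = self._fit_like(["const", "x"], -100.001)
        assert lr_test(f0, f1) == 1.0
        f1b = self._fit_like(["const", "x"], -100.1)
        with pytest.warns(UserWarning, match="clamped"):
            assert lr_test(f0, f1b) == 1.0

    def test_contract_errors(self):
        f0 = self._fit_like(["const", "z"], -100.0)
        f1 = self._fit_like(["const", "x"], -99.0)
        with pytest.raises(ValueError, match="nested"):
            lr_test(f0, f1)
        r0 = self._fit_like(["const"], -100.0, method="REML")
        r1 = self._fit_like(["const", "x"], -99.0, method="REML")
        with pytest.raises(ValueError, match="ML"):
            lr_test(r0, r1)


class TestProfileKappa:
    def test_single_point_grid(self, small_stack):
        best, table = profile_kappa(small_stack, kappa_grid=[2.0])
        assert best == 2.0
        assert len(table) == 1

    def test_table_has_one_row_per_kappa(self, small_stack):
        grid = [0.5, 1.0, 2.0]
        _, table = profile_kappa(small_stack, kappa_grid=grid)
        assert len(table) == len(grid)
        assert table["ok"].all()

    def test_empty_grid_rejected(self, small_stack):
        with pytest.raises(ValueError):
            profile_kappa(small_stack, kappa_grid=[])


class TestAdjustedR2:
    def test_constant_only_is_zero(self, small_stack):
        fit = fit_lmm(small_stack, method="ML", kappa=0.5)
        assert adjusted_r2(fit, small_stack) == 0.0

    def test_perfect_fit_is_one(self, rng):
        n = 40
        coords = rng.uniform(0, 50, (n, 2))
        x1 = rng.normal(size=n)
        y = 2.0 + 3.0 * x1
        X = np.column_stack([np.ones(n), x1])
        stack = _const_stack(y, coords, X, ["const", "x1"])
        fit = LMMFit(labels=["const", "x1"], beta=np.array([2.0, 3.0]),
                     beta_se=np.zeros(2),
                     coreg=Coregionalization([[1.0]], [[0.0]],
                                             MaternCorrelation(0.5, 5.0)),
                     loglik=0.0, method="ML", n_obs=n)
        assert adjusted_r2(fit, stack) == pytest.approx(1.0)

    def test_noise_predictor_does_not_inflate(self, rng):
        n = 120
        coords = rng.uniform(0, 50, (n, 2))
        x1 = rng.normal(size=n)
        y = 1.0 + 0.8 * x1 + rng.normal(scale=0.5, size=n)
        noise = rng.normal(size=n)
        df = pd.DataFrame({"site_id": np.arange(n), "x_km": coords[:, 0],
                           "y_km": coords[:, 1], "resp": y, "x1": x1, "junk": noise})
        f1 = fit_lmm(univariate_stack(df, "resp", ["x1"]), method="ML", kappa=0.5)
        f2 = fit_lmm(univariate_stack(df, "resp", ["x1", "junk"]), method="ML", kappa=0.5)
        r1 = adjusted_r2(f1, univariate_stack(df, "resp", ["x1"]))
        r2 = adjusted_r2(f2, univariate_stack(df, "resp", ["x1", "junk"]))
        assert r2 < r1 + 0.01


class TestStackContract:
    def test_duplicate_variable_site_pair_rejected(self, rng):
        with pytest.raises(ValueError, match="at most once"):
            ObservationStack(var=[0, 0], site=[1, 1], coords=np.zeros((2, 2)),
                             y=np.zeros(2), X=np.ones((2, 1)), labels=["const"])

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            ObservationStack(var=[0, 0], site=[0, 1], coords=np.zeros((2, 2)),
                             y=np.array([0.0, np.nan]), X=np.ones((2, 1)),
                             labels=["const"])
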
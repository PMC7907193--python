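"""Separable space-time likelihood, MCMC fit, DIC and imputation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import cdist
from scipy.stats import multivariate_normal

from fearscape.stmodel import (
    Hyperparameters,
    McmcSettings,
    StDataset,
    ar1_correlation,
    design_matrix,
    dic,
    fit,
    impute_covariate_via_model,
    matern1_correlation,
    st_covariance,
    st_loglik,
    standardize_covariates,
    transform_response,
)
from fearscape.synthetic import simulate_dataset


def _random_instance(rng, S=None, T=None):
    S = S or int(rng.integers(3, 9))
    T = T or int(rng.integers(2, 9))
    coords = rng.uniform(0, 4000, (S, 2))
    p = int(rng.integers(0, 3))
    z = rng.standard_normal((S, T, p))
    beta = rng.normal(0, 0.5, p + 1)
    hp = Hyperparameters(
        a=float(rng.uniform(-0.9, 0.9)),
        rho=float(rng.uniform(200, 4000)),
        sigma2_omega=float(rng.uniform(0.05, 2.0)),
        sigma2_eps=float(rng.uniform(0.05, 2.0)),
    )
    y = rng.standard_normal((S, T))
    # random missingness but at least one observed cell
    miss = rng.random((S, T)) < 0.15
    miss.flat[rng.integers(0, S * T)] = False
    y[miss] = np.nan
    return y, z, beta, hp, coords


def _dense_oracle(y, z, beta, hp, coords):
    """Independent dense construction of the marginal Gaussian log-density."""
    S, T = y.shape
    d = cdist(coords, coords)
    R_S = matern1_correlation(d, hp.rho)
    S_T = hp.sigma2_omega / (1 - hp.a**2) * ar1_correlation(T, hp.a)
    cov = np.kron(S_T, R_S) + hp.sigma2_eps * np.eye(S * T)
    yv = y.T.ravel()
    obs = ~np.isnan(yv)
    mu = design_matrix(z) @ beta
    return multivariate_normal(mu[obs], cov[np.ix_(obs, obs)]).logpdf(yv[obs])


class TestTransforms:
    def test_log1p_identities(self):
        out = transform_response(np.array([[0.0, np.e - 1, np.nan]]))
        assert out[0, 0] == 0.0
        assert out[0, 1] == pytest.approx(1.0)
        assert np.isnan(out[0, 2])

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            transform_response(np.array([[-0.1]]))

    def test_standardize_hand_example(self):
        z = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1)
        out, rec = standardize_covariates(z, ["x"])
        assert np.allclose(out.ravel(), [-1, 0, 1])
        assert rec.mean == (2.0,)
        assert rec.sd == (1.0,)

    def test_standardize_idempotent(self, rng):
        z = rng.standard_normal((5, 4, 1))
        z1, rec = standardize_covariates(z, ["x"])
        z2, _ = standardize_covariates(z1, ["x"])
        assert np.allclose(z1, z2, atol=1e-12)

    def test_constant_column_named(self):
        z = np.ones((3, 2, 1))
        with pytest.raises(ValueError, match="myvar"):
            standardize_covariates(z, ["myvar"])

    def test_scaling_record_reapplies(self, rng):
        z = rng.uniform(0, 100, (4, 3, 2))
        z_std, rec = standardize_covariates(z, ["a", "b"])
        assert np.allclose(rec.apply(z), z_std)


class TestLoglik:
    def test_matches_dense_oracle(self, rng):
        for _ in range(25):
            y, z, beta, hp, coords = _random_instance(rng)
            assert st_loglik(y, z, beta, hp, coords) == pytest.approx(
                _dense_oracle(y, z, beta, hp, coords), abs=1e-8
            )

    def test_temporal_independence_limit(self, rng):
        y, z, beta, hp0, coords = _random_instance(rng, S=5, T=4)
        hp = Hyperparameters(0.0, hp0.rho, hp0.sigma2_omega, hp0.sigma2_eps)
        ll = st_loglik(y, z, beta, hp, coords)
        # with a = 0, occasions factorise into independent spatial Gaussians
        d = cdist(coords, coords)
        cov_t = hp.sigma2_omega * matern1_correlation(d, hp.rho) + hp.sigma2_eps * np.eye(5)
        mu = design_matrix(z) @ beta
        total = 0.0
        for t in range(4):
            yt = y[:, t]
            obs = ~np.isnan(yt)
            mt = mu[t * 5 : (t + 1) * 5][obs]
            total += multivariate_normal(mt, cov_t[np.ix_(obs, obs)]).logpdf(yt[obs])
        assert ll == pytest.approx(total, abs=1e-8)

    def test_no_field_limit(self, rng):
        y, z, beta, hp0, coords = _random_instance(rng, S=4, T=3)
        hp = Hyperparameters(0.5, hp0.rho, 1e-12, 0.7)
        ll = st_loglik(y, z, beta, hp, coords)
        yv = y.T.ravel()
        obs = ~np.isnan(yv)
        mu = design_matrix(z) @ beta
        iid = stats.norm.logpdf(yv[obs], mu[obs], np.sqrt(0.7)).sum()
        assert ll == pytest.approx(iid, abs=1e-5)

    def test_invalid_hyperparameters(self):
        with pytest.raises(ValueError):
            Hyperparameters(1.0, 100.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            Hyperparameters(0.5, -1.0, 1.0, 1.0)


class TestFit:
    def test_recovers_truth(self, recovery_fit):
        data, truth, result = recovery_fit
        means = result.beta_mean
        assert abs(means[1] - 0.5) < 0.15
        assert abs(means[2] + 0.3) < 0.15
        assert abs(means[3]) < 0.15 and abs(means[4]) < 0.15
        a_mean = result.summary.loc["a", "mean"]
        assert abs(a_mean - truth["hp"].a) < 0.2

    def test_summary_shape_and_ordering(self, recovery_fit):
        _, _, result = recovery_fit
        s = result.summary
        assert list(s.columns) == ["mean", "sd", "q2.5", "q50", "q97.5", "mode"]
        assert (s["q2.5"] <= s["q50"]).all() and (s["q50"] <= s["q97.5"]).all()
        assert {"intercept", "a", "rho", "sigma2_omega", "sigma2_eps"} <= set(s.index)

    def test_significance_flag(self, recovery_fit):
        _, _, result = recovery_fit
        sig = result.significant()
        assert sig["x1"] and sig["x2"]

    def test_missing_cells_get_predictions(self, recovery_fit):
        data, truth, result = recovery_fit
        miss = np.isnan(data.y)
        assert miss.any()
        eta = result.eta_mean
        assert np.isfinite(eta).all()
        # predictions at masked cells track the withheld latent truth
        true_eta = truth["beta0"] + data.z @ truth["beta"] + truth["xi"]
        r = np.corrcoef(eta[miss], true_eta[miss])[0, 1]
        assert r > 0.5

    def test_seed_determinism(self):
        data, _ = simulate_dataset(9, n_sites=6, T=6, beta=(0.4,))
        mc = McmcSettings(iterations=300, burnin=100, thin=2, seed=3)
        f1 = fit(data, mcmc=mc)
        f2 = fit(data, mcmc=mc)
        pd.testing.assert_frame_equal(f1.summary, f2.summary)
        assert f1.dic["dic"] == f2.dic["dic"]

    def test_likelihood_swamped_limit_keeps_prior_sd(self):
        # a single observed cell cannot inform a covariate coefficient:
        # its posterior sd should stay near the prior scale sqrt(1000)
        rng = np.random.default_rng(0)
        y = np.full((4, 3), np.nan)
        y[0, 0] = 0.3
        data = StDataset(rng.uniform(0, 1000, (4, 2)), y, rng.standard_normal((4, 3, 1)), ("x1",))
        f = fit(data, mcmc=McmcSettings(iterations=600, burnin=200, thin=2, seed=1))
        assert f.summary.loc["x1", "sd"] > 15.0

    def test_covariate_order_invariance(self):
        data, _ = simulate_dataset(13, n_sites=8, T=8, beta=(0.6, -0.4))
        swapped = StDataset(
            data.coords, data.y, data.z[:, :, ::-1].copy(), ("x2", "x1")
        )
        mc = McmcSettings(iterations=800, burnin=300, thin=2, seed=2)
        f1 = fit(data, mcmc=mc)
        f2 = fit(swapped, mcmc=mc)
        for nm in ("x1", "x2"):
            assert f1.summary.loc[nm, "mean"] == pytest.approx(
                f2.summary.loc[nm, "mean"], abs=0.05
            )


class TestDic:
    def test_duplicated_data_doubles_mean_deviance(self):
        data, _ = simulate_dataset(21, n_sites=5, T=4, beta=(0.5,))
        mc = McmcSettings(iterations=400, burnin=150, thin=2, seed=4)
        f = fit(data, mcmc=mc)
        # stack the same sites twice at a tiny offset: deviance is additive
        data2 = StDataset(
            np.vstack([data.coords, data.coords + 1.0]),
            np.vstack([data.y, data.y]),
            np.vstack([data.z, data.z]),
            data.covariate_names,
        )
        d1 = dic(f, data)
        # evaluate the same draws against the doubled dataset
        f_double = type(f)(
            summary=f.summary, dic={}, draws={
                **f.draws, "xi": np.concatenate([f.draws["xi"], f.draws["xi"]], axis=1)
            },
            eta_mean=f.eta_mean, covariate_names=f.covariate_names, coords=data2.coords,
            converged=f.converged, acceptance_rate=f.acceptance_rate, seed=f.seed,
        )
        d2 = dic(f_double, data2)
        assert d2["mean_deviance"] == pytest.approx(2 * d1["mean_deviance"], rel=1e-9)

    def test_no_draws_rejected(self, recovery_fit):
        data, _, result = recovery_fit
        empty = type(result)(
            summary=result.summary, dic={}, draws={"beta": np.empty((0, 5))},
            eta_mean=result.eta_mean, covariate_names=result.covariate_names,
            coords=result.coords, converged=True, acceptance_rate=0.0, seed=0,
        )
        with pytest.raises(ValueError):
            dic(empty, data)


class TestImputation:
    def test_full_grid_output_and_fidelity(self):
        data, truth = simulate_dataset(
            31, n_sites=21, T=24, beta=(0.5, -0.3), missing_frac=0.1,
            hp=Hyperparameters(a=0.6, rho=1500.0, sigma2_omega=0.08, sigma2_eps=0.02),
        )
        eta, r, aux_fit = impute_covariate_via_model(
            data, mcmc=McmcSettings(iterations=1200, burnin=400, thin=2, seed=6)
        )
        assert eta.shape == (21, 24)
        assert eta.size == 504
        assert np.isfinite(eta).all()
        assert r > 0.8
        # masked-cell recovery against the withheld truth
        miss = np.isnan(data.y)
        true_eta = truth["beta0"] + data.z @ truth["beta"] + truth["xi"]
        r_masked = np.corrcoef(eta[miss], true_eta[miss])[0, 1]
        assert r_masked > 0.8
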
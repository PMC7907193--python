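"""Bayesian separable spatiotemporal Gaussian model of intensity of space use.

The observed response (log(x+1)-transformed detection rate) at site s_i and
occasion t is modelled as

    y(s_i, t) = z(s_i, t) beta + xi(s_i, t) + eps(s_i, t)

where xi is a zero-mean Gaussian field with separable covariance:
Matern (smoothness nu = 1, range rho) across sites, first-order
autoregressive (coefficient a) across occasions with innovation marginal
variance sigma2_omega, so the stationary marginal variance is
sigma2_omega / (1 - a^2); eps is an iid Gaussian nugget with variance
sigma2_eps.  Inference is by a Metropolis-within-Gibbs sampler: conjugate
Gaussian block updates for beta and the latent field, a conjugate
inverse-gamma update for the nugget, and adaptive random-walk Metropolis on
(a, rho, sigma2_omega) after transforming them to the real line.  Missing
responses drop out of the likelihood and are predicted from the latent
field.  Model comparison uses the deviance information criterion with the
deviance conditioned on the latent field.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, special, stats
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Covariance building blocks


def matern1_correlation(dists: np.ndarray, rho: float) -> np.ndarray:
    """Matern correlation with smoothness nu = 1 and range rho.

    Uses the range convention rho = sqrt(8 * nu) / kappa, under which the
    correlation has dropped to about 0.13 at distance rho.  With nu = 1 the
    correlation is (kappa d) K_1(kappa d), equal to 1 at d = 0.
    """
    if rho <= 0:
        raise ValueError("Matern range must be positive")
    kappa = np.sqrt(8.0) / rho
    kd = kappa * np.asarray(dists, dtype=float)
    out = np.ones_like(kd)
    pos = kd > 0
    out[pos] = kd[pos] * special.kv(1, kd[pos])
    return out


def ar1_correlation(T: int, a: float) -> np.ndarray:
    """AR(1) correlation matrix a^|t - t'| over T occasions."""
    if not abs(a) < 1:
        raise ValueError("AR(1) coefficient must satisfy |a| < 1")
    lags = np.abs(np.subtract.outer(np.arange(T), np.arange(T)))
    return a ** lags


def _ar1_precision_scaled(T: int, a: float, sigma2_omega: float) -> np.ndarray:
    """Inverse of the AR(1) covariance (sigma2_omega/(1-a^2)) * a^|t-t'|.

    Tridiagonal: diag (1, 1+a^2, ..., 1+a^2, 1)/sigma2_omega, off-diagonal
    -a/sigma2_omega.
    """
    Q = np.zeros((T, T))
    idx = np.arange(T)
    Q[idx, idx] = 1.0 + a**2
    Q[0, 0] = Q[-1, -1] = 1.0
    Q[idx[:-1], idx[:-1] + 1] = -a
    Q[idx[:-1] + 1, idx[:-1]] = -a
    return Q / sigma2_omega


@dataclass(frozen=True)
class Hyperparameters:
    """a: AR(1) coefficient; rho: Matern range (m); sigma2_omega: innovation
    marginal variance; sigma2_eps: nugget variance."""

    a: float
    rho: float
    sigma2_omega: float
    sigma2_eps: float

    def __post_init__(self) -> None:
        if not abs(self.a) < 1:
            raise ValueError("stationarity requires |a| < 1")
        if self.rho <= 0 or self.sigma2_omega <= 0 or self.sigma2_eps <= 0:
            raise ValueError("range and variances must be positive")


def st_covariance(coords: np.ndarray, T: int, hp: Hyperparameters) -> np.ndarray:
    """Dense covariance of the latent-plus-nugget process over all S*T cells.

    Cells are ordered occasion-major (site index varies fastest), i.e. the
    vectorisation of the (S, T) field matrix by columns.
    """
    d = cdist(coords, coords)
    R_S = matern1_correlation(d, hp.rho)
    S_T = (hp.sigma2_omega / (1.0 - hp.a**2)) * ar1_correlation(T, hp.a)
    return np.kron(S_T, R_S) + hp.sigma2_eps * np.eye(len(coords) * T)


def st_loglik(
    y: np.ndarray,
    z: np.ndarray,
    beta: np.ndarray,
    hp: Hyperparameters,
    coords: np.ndarray,
) -> float:
    """Marginal Gaussian log-likelihood of the observed cells.

    ``y`` is the (S, T) transformed response with NaN for missing cells;
    ``z`` is (S, T, p) covariates and ``beta`` has length p + 1 (intercept
    first).  The latent field is integrated out analytically: observed cells
    are jointly Gaussian with mean Z beta and the separable covariance plus
    nugget, built by Kronecker product and subset to observed cells.
    """
    y = np.asarray(y, dtype=float)
    S, T = y.shape
    yv = y.T.ravel()
    obs = ~np.isnan(yv)
    if not obs.any():
        raise ValueError("need at least one observed response cell")
    Z = design_matrix(z)
    mu = Z @ np.asarray(beta, dtype=float)
    cov = st_covariance(np.asarray(coords, dtype=float), T, hp)
    cov_oo = cov[np.ix_(obs, obs)]
    resid = yv[obs] - mu[obs]
    cf = linalg.cho_factor(cov_oo, lower=True, check_finite=False)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    quad = resid @ linalg.cho_solve(cf, resid, check_finite=False)
    n = obs.sum()
    return float(-0.5 * (n * np.log(2.0 * np.pi) + logdet + quad))


# ---------------------------------------------------------------------------
# Dataset plumbing


def transform_response(rates: np.ndarray | pd.DataFrame) -> np.ndarray:
    """log(x + 1) transform of detection rates; missing cells stay missing."""
    r = np.asarray(rates, dtype=float)
    if np.any(r[np.isfinite(r)] < 0):
        raise ValueError("detection rates must be nonnegative")
    return np.log1p(r)


@dataclass(frozen=True)
class ScalingRecord:
    """Means and sds used to z-score covariates, kept for prediction time."""

    mean: tuple[float, ...]
    sd: tuple[float, ...]
    names: tuple[str, ...]

    def apply(self, z_raw: np.ndarray) -> np.ndarray:
        m = np.asarray(self.mean)
        s = np.asarray(self.sd)
        return (np.asarray(z_raw, dtype=float) - m) / s


def standardize_covariates(
    z_raw: np.ndarray,
    names: Sequence[str],
    obs_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, ScalingRecord]:
    """z-score each covariate over cells with an observed response.

    ``z_raw`` is (S, T, p); ``obs_mask`` is (S, T) (all cells if None).  The
    sample sd (ddof = 1) is used.  Constant columns cannot be scaled and are
    reported by name.
    """
    z = np.asarray(z_raw, dtype=float)
    S, T, p = z.shape
    if len(names) != p:
        raise ValueError("one name per covariate column required")
    mask = np.ones((S, T), bool) if obs_mask is None else np.asarray(obs_mask, bool)
    means, sds = [], []
    out = z.copy()
    for j, name in enumerate(names):
        vals = z[:, :, j][mask]
        m, s = float(np.mean(vals)), float(np.std(vals, ddof=1))
        if s == 0 or not np.isfinite(s):
            raise ValueError(f"covariate {name!r} is constant; cannot standardize")
        out[:, :, j] = (z[:, :, j] - m) / s
        means.append(m)
        sds.append(s)
    return out, ScalingRecord(tuple(means), tuple(sds), tuple(names))


@dataclass
class StDataset:
    """Model-ready data: transformed response, standardized covariates, coords."""

    coords: np.ndarray  # (S, 2) metres
    y: np.ndarray  # (S, T) transformed response, NaN = missing
    z: np.ndarray  # (S, T, p) standardized covariates
    covariate_names: tuple[str, ...]
    scaling: ScalingRecord | None = None
    site_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        S, T = self.y.shape
        if self.coords.shape != (S, 2):
            raise ValueError("coords must be (S, 2) matching the response rows")
        if self.z.shape[:2] != (S, T) or self.z.shape[2] != len(self.covariate_names):
            raise ValueError("covariate array must be (S, T, p) with p names")

    @property
    def shape(self) -> tuple[int, int]:
        return self.y.shape

    def subset_covariates(self, names: Sequence[str]) -> "StDataset":
        idx = [self.covariate_names.index(n) for n in names]
        return StDataset(
            self.coords, self.y, self.z[:, :, idx], tuple(names),
            scaling=self.scaling, site_ids=self.site_ids,
        )


def build_dataset(
    rates: np.ndarray | pd.DataFrame,
    z_raw: np.ndarray,
    coords: np.ndarray,
    names: Sequence[str],
    site_ids: Sequence[str] | None = None,
) -> StDataset:
    """Transform the response, z-score covariates and bundle an StDataset."""
    y = transform_response(rates)
    z, scaling = standardize_covariates(z_raw, names, obs_mask=~np.isnan(y))
    return StDataset(
        np.asarray(coords, dtype=float), y, z, tuple(names),
        scaling=scaling,
        site_ids=tuple(site_ids) if site_ids is not None else None,
    )


def design_matrix(z: np.ndarray) -> np.ndarray:
    """(S*T, 1+p) design with intercept, occasion-major cell order."""
    S, T, p = z.shape
    Z = z.transpose(1, 0, 2).reshape(S * T, p)
    return np.hstack([np.ones((S * T, 1)), Z])


# ---------------------------------------------------------------------------
# Priors and sampler settings


@dataclass(frozen=True)
class Priors:
    """Weakly informative defaults: flat-ish Gaussian on coefficients, vague
    gamma on precisions, shrinkage of the AR coefficient toward 0 on the
    Fisher-z scale, and a log-normal range centred on the median inter-site
    distance (set at fit time when None)."""

    beta_var: float = 1000.0
    eps_prec_shape: float = 1.0
    eps_prec_rate: float = 5e-5
    omega_prec_shape: float = 1.0
    omega_prec_rate: float = 5e-5
    a_z_sd: float = 1.5
    log_rho_mean: float | None = None
    log_rho_sd: float = 1.0


@dataclass(frozen=True)
class McmcSettings:
    iterations: int = 20_000
    burnin: int = 5_000
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burnin >= self.iterations:
            raise ValueError("burnin must be smaller than iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class PosteriorFit:
    """Posterior summaries, retained draws and diagnostics for one model."""

    summary: pd.DataFrame  # rows: intercept, betas, hyperparameters
    dic: dict  # {'dic', 'p_d', 'mean_deviance'}
    draws: dict  # beta (n, 1+p), a, rho, sigma2_omega, sigma2_eps (n,), xi (n, S, T)
    eta_mean: np.ndarray  # (S, T) posterior mean of z beta + xi
    covariate_names: tuple[str, ...]
    coords: np.ndarray
    converged: bool
    acceptance_rate: float
    seed: int
    scaling: ScalingRecord | None = None

    @property
    def beta_mean(self) -> np.ndarray:
        return self.draws["beta"].mean(axis=0)

    def significant(self) -> pd.Series:
        """Covariates whose 95% credible interval excludes zero."""
        s = self.summary
        return (s["q2.5"] > 0) | (s["q97.5"] < 0)


def _kde_mode(draws: np.ndarray) -> float:
    if np.ptp(draws) < 1e-12:
        return float(draws[0])
    kde = stats.gaussian_kde(draws)
    grid = np.linspace(draws.min(), draws.max(), 256)
    return float(grid[np.argmax(kde(grid))])


def _summarize(draws: np.ndarray) -> dict:
    q = np.percentile(draws, [2.5, 50, 97.5])
    return {
        "mean": float(draws.mean()),
        "sd": float(draws.std(ddof=1)),
        "q2.5": float(q[0]),
        "q50": float(q[1]),
        "q97.5": float(q[2]),
        "mode": _kde_mode(draws),
    }


def _split_rhat(x: np.ndarray) -> float:
    """Split-R-hat of one scalar chain (two halves as pseudo-chains)."""
    n = len(x) // 2
    if n < 2:
        return np.nan
    halves = np.stack([x[:n], x[n : 2 * n]])
    within = halves.var(axis=1, ddof=1).mean()
    between = n * halves.mean(axis=1).var(ddof=1)
    if within <= 0:
        return 1.0
    return float(np.sqrt((n - 1) / n + between / (n * within)))


def fit(
    data: StDataset,
    priors: Priors | None = None,
    mcmc: McmcSettings | None = None,
) -> PosteriorFit:
    """Metropolis-within-Gibbs inference for the spatiotemporal model.

    Deterministic given ``mcmc.seed``.  Random-walk proposal scales adapt
    toward a 30% acceptance rate during burn-in and are frozen afterwards.
    A split-R-hat above 1.1 on any coefficient sets ``converged = False``
    with a logged warning, never silently.
    """
    priors = priors or Priors()
    mcmc = mcmc or McmcSettings()
    rng = np.random.default_rng(mcmc.seed)

    S, T = data.shape
    N = S * T
    yv = data.y.T.ravel()
    obs = ~np.isnan(yv)
    n_obs = int(obs.sum())
    if n_obs == 0:
        raise ValueError("need at least one observed response cell")
    Z = design_matrix(data.z)
    p1 = Z.shape[1]
    y_fill = np.where(obs, yv, 0.0)

    d = cdist(data.coords, data.coords)
    med_d = float(np.median(d[np.triu_indices(S, 1)])) if S > 1 else 1.0
    log_rho_mean = priors.log_rho_mean if priors.log_rho_mean is not None else np.log(med_d)

    # --- initial state: OLS for beta, crude variance split for the rest
    ZtZ_obs = Z[obs].T @ Z[obs]
    beta = np.linalg.solve(ZtZ_obs + 1e-8 * np.eye(p1), Z[obs].T @ yv[obs])
    resid0 = yv[obs] - Z[obs] @ beta
    v0 = max(float(resid0.var()), 1e-6)
    sig2_eps = v0 / 2.0
    a = 0.5
    rho = med_d
    sig2_om = (v0 / 2.0) * (1.0 - a**2)
    xi = np.zeros(N)

    def spatial_chol(rho_: float):
        R = matern1_correlation(d, rho_)
        return linalg.cho_factor(R + 1e-10 * np.eye(S), lower=True, check_finite=False)

    cf_S = spatial_chol(rho)

    def field_logdensity(xi_mat: np.ndarray, a_: float, rho_: float, s2o_: float, cf_S_):
        """log N(xi; 0, Sigma_T kron R_S) via the small factor matrices."""
        S_T = (s2o_ / (1.0 - a_**2)) * ar1_correlation(T, a_)
        cf_T = linalg.cho_factor(S_T, lower=True, check_finite=False)
        logdet = 2.0 * S * np.sum(np.log(np.diag(cf_T[0]))) + 2.0 * T * np.sum(
            np.log(np.diag(cf_S_[0]))
        )
        # quad = tr(Sigma_T^-1 X' R_S^-1 X) with X the (S, T) field matrix
        RinvX = linalg.cho_solve(cf_S_, xi_mat, check_finite=False)
        TinvXt = linalg.cho_solve(cf_T, xi_mat.T, check_finite=False)
        quad = float(np.sum(RinvX * TinvXt.T))
        return -0.5 * (N * np.log(2.0 * np.pi) + logdet + quad)

    def hyper_logprior(u: np.ndarray) -> float:
        za, lr, lo = u
        lp = stats.norm.logpdf(za, 0.0, priors.a_z_sd)
        lp += stats.norm.logpdf(lr, log_rho_mean, priors.log_rho_sd)
        # gamma prior on the innovation precision, expressed on log-variance
        lp += -priors.omega_prec_shape * lo - priors.omega_prec_rate * np.exp(-lo)
        return float(lp)

    u = np.array([np.arctanh(a), np.log(rho), np.log(sig2_om)])
    step = np.array([0.3, 0.3, 0.3])
    cur_lp = field_logdensity(xi.reshape(T, S).T, a, rho, sig2_om, cf_S) + hyper_logprior(u)

    n_keep = (mcmc.iterations - mcmc.burnin) // mcmc.thin
    keep = {
        "beta": np.empty((n_keep, p1)),
        "a": np.empty(n_keep),
        "rho": np.empty(n_keep),
        "sigma2_omega": np.empty(n_keep),
        "sigma2_eps": np.empty(n_keep),
        "xi": np.empty((n_keep, S, T)),
    }
    k = 0
    n_prop = n_acc = 0
    Q_kron = None  # rebuilt lazily when hyperparameters move

    eye_p = np.eye(p1)
    for it in range(mcmc.iterations):
        # --- beta | xi, sig2_eps (Gaussian full conditional)
        prec = ZtZ_obs / sig2_eps + eye_p / priors.beta_var
        rhs = Z[obs].T @ (yv[obs] - xi[obs]) / sig2_eps
        cfb = linalg.cho_factor(prec, lower=True, check_finite=False)
        mean_b = linalg.cho_solve(cfb, rhs, check_finite=False)
        beta = mean_b + linalg.solve_triangular(
            cfb[0], rng.standard_normal(p1), lower=True, trans="T", check_finite=False
        )

        # --- xi | rest (joint Gaussian full conditional over all S*T cells)
        if Q_kron is None:
            Q_T = _ar1_precision_scaled(T, a, sig2_om)
            R_S_inv = linalg.cho_solve(cf_S, np.eye(S), check_finite=False)
            Q_kron = np.kron(Q_T, R_S_inv)
        P = Q_kron.copy()
        P[np.arange(N)[obs], np.arange(N)[obs]] += 1.0 / sig2_eps
        b = np.where(obs, (y_fill - Z @ beta) / sig2_eps, 0.0)
        cfp = linalg.cho_factor(P, lower=True, check_finite=False)
        mean_xi = linalg.cho_solve(cfp, b, check_finite=False)
        xi = mean_xi + linalg.solve_triangular(
            cfp[0], rng.standard_normal(N), lower=True, trans="T", check_finite=False
        )

        # --- sigma2_eps | rest (conjugate inverse gamma)
        r = yv[obs] - Z[obs] @ beta - xi[obs]
        shape = priors.eps_prec_shape + n_obs / 2.0
        rate = priors.eps_prec_rate + 0.5 * float(r @ r)
        sig2_eps = 1.0 / rng.gamma(shape, 1.0 / rate)

        # --- (a, rho, sigma2_omega) | xi (random-walk Metropolis, joint)
        xi_mat = xi.reshape(T, S).T
        cur_lp = field_logdensity(xi_mat, a, rho, sig2_om, cf_S) + hyper_logprior(u)
        u_prop = u + step * rng.standard_normal(3)
        a_p, rho_p, s2o_p = np.tanh(u_prop[0]), np.exp(u_prop[1]), np.exp(u_prop[2])
        try:
            cf_S_p = spatial_chol(rho_p)
            prop_lp = field_logdensity(xi_mat, a_p, rho_p, s2o_p, cf_S_p) + hyper_logprior(u_prop)
        except np.linalg.LinAlgError:
            prop_lp, cf_S_p = -np.inf, None
        n_prop += 1
        if np.log(rng.uniform()) < prop_lp - cur_lp:
            u, a, rho, sig2_om, cf_S = u_prop, a_p, rho_p, s2o_p, cf_S_p
            cur_lp = prop_lp
            n_acc += 1
            Q_kron = None
        if it < mcmc.burnin and (it + 1) % 50 == 0:
            rate_now = n_acc / max(n_prop, 1)
            step *= np.exp(0.5 * (rate_now - 0.3))
            n_prop = n_acc = 0

        if it >= mcmc.burnin and (it - mcmc.burnin) % mcmc.thin == 0 and k < n_keep:
            keep["beta"][k] = beta
            keep["a"][k] = a
            keep["rho"][k] = rho
            keep["sigma2_omega"][k] = sig2_om
            keep["sigma2_eps"][k] = sig2_eps
            keep["xi"][k] = xi.reshape(T, S).T
            k += 1

    acc_rate = n_acc / max(n_prop, 1)

    # --- summaries
    rows = {}
    names = ("intercept",) + tuple(data.covariate_names)
    for j, nm in enumerate(names):
        rows[nm] = _summarize(keep["beta"][:, j])
    for nm in ("a", "rho", "sigma2_omega", "sigma2_eps"):
        rows[nm] = _summarize(keep[nm])
    summary = pd.DataFrame.from_dict(rows, orient="index")

    rhats = [_split_rhat(keep["beta"][:, j]) for j in range(p1)]
    converged = bool(np.all(np.array(rhats) <= 1.1))
    if not converged:
        logger.warning("split-R-hat above 1.1 on coefficients: %s", np.round(rhats, 3))

    Z_all = Z
    eta_draws = keep["beta"] @ Z_all.T  # (n_keep, N)
    eta_mean = (
        eta_draws.mean(axis=0) + keep["xi"].transpose(0, 2, 1).reshape(n_keep, N).mean(axis=0)
    )
    eta_mean = eta_mean.reshape(T, S).T

    fit_obj = PosteriorFit(
        summary=summary,
        dic={},
        draws=keep,
        eta_mean=eta_mean,
        covariate_names=tuple(data.covariate_names),
        coords=data.coords.copy(),
        converged=converged,
        acceptance_rate=float(acc_rate),
        seed=mcmc.seed,
        scaling=data.scaling,
    )
    fit_obj.dic = dic(fit_obj, data)
    return fit_obj


# ---------------------------------------------------------------------------
# DIC and model selection


def dic(fit_result: PosteriorFit, data: StDataset) -> dict:
    """Deviance information criterion with deviance conditional on the field.

    D(theta) = -2 log p(y_obs | beta, xi, sigma2_eps); DIC = Dbar + p_D with
    p_D = Dbar - D(posterior means).  Conditioning on the latent field is the
    latent-scale DIC; alternative definitions integrate the field out.
    """
    draws = fit_result.draws
    if "beta" not in draws or len(draws["beta"]) == 0:
        raise ValueError("fit retains no posterior draws")
    S, T = data.shape
    yv = data.y.T.ravel()
    obs = ~np.isnan(yv)
    Z = design_matrix(data.z)
    n_keep = len(draws["beta"])

    def deviance(beta, xi_mat, s2e):
        mu = Z[obs] @ beta + xi_mat.T.ravel()[obs]
        r = yv[obs] - mu
        n = obs.sum()
        return n * np.log(2.0 * np.pi * s2e) + float(r @ r) / s2e

    devs = np.array(
        [
            deviance(draws["beta"][i], draws["xi"][i], draws["sigma2_eps"][i])
            for i in range(n_keep)
        ]
    )
    d_bar = float(devs.mean())
    d_at_mean = deviance(
        draws["beta"].mean(axis=0), draws["xi"].mean(axis=0), float(draws["sigma2_eps"].mean())
    )
    p_d = d_bar - d_at_mean
    return {"dic": d_bar + p_d, "p_d": p_d, "mean_deviance": d_bar}


def stepwise_dic(
    data: StDataset,
    full_covariates: Sequence[str] | None = None,
    mcmc: McmcSettings | None = None,
    priors: Priors | None = None,
    candidates: Sequence[Sequence[str]] | None = None,
) -> tuple[list[dict], dict]:
    """Backward DIC elimination (or evaluation of an explicit candidate list).

    Starting from the full covariate set, each step refits every drop-one
    model and removes the covariate whose removal most lowers DIC, stopping
    when no removal improves it.  Every evaluated model is logged with its
    DIC (failed fits are recorded with dic = inf, not fatal).  Returns
    (all evaluated models, best model record).
    """
    mcmc = mcmc or McmcSettings()
    evaluated: list[dict] = []

    def eval_model(names: Sequence[str]) -> dict:
        sub = data.subset_covariates(names) if len(names) else StDataset(
            data.coords, data.y, np.empty((*data.shape, 0)), (), scaling=None,
            site_ids=data.site_ids,
        )
        try:
            f = fit(sub, priors=priors, mcmc=mcmc)
            rec = {"covariates": tuple(names), "dic": f.dic["dic"], "fit": f}
        except Exception as e:  # propagate per-candidate, keep the search alive
            logger.warning("candidate %s failed: %s", names, e)
            rec = {"covariates": tuple(names), "dic": np.inf, "fit": None, "error": str(e)}
        evaluated.append(rec)
        return rec

    if candidates is not None:
        records = [eval_model(c) for c in candidates]
        best = min(records, key=lambda r: r["dic"])
        return evaluated, best

    current = list(full_covariates if full_covariates is not None else data.covariate_names)
    best = eval_model(current)
    while current:
        trials = [eval_model([c for c in current if c != drop]) for drop in current]
        challenger = min(trials, key=lambda r: r["dic"])
        if challenger["dic"] < best["dic"]:
            best = challenger
            current = list(challenger["covariates"])
        else:
            break
    return evaluated, best


def impute_covariate_via_model(
    aux_data: StDataset,
    mcmc: McmcSettings | None = None,
    priors: Priors | None = None,
    r_floor: float = 0.8,
) -> tuple[np.ndarray, float, PosteriorFit]:
    """Fill an auxiliary response at every site x occasion via its own model.

    Fits the spatiotemporal model to the auxiliary response (e.g. human
    detection rates on dist_village, dist_agriculture, dist_road) and
    returns the posterior mean of the full linear predictor
    eta(s, t) = z beta + xi at all S*T cells — observed cells get their
    fitted value, missing cells a model-based prediction — together with the
    Pearson correlation between eta-hat and the observed values (a fidelity
    check before using eta-hat as a covariate downstream), and the fit.
    """
    aux_fit = fit(aux_data, priors=priors, mcmc=mcmc)
    eta = aux_fit.eta_mean
    mask = ~np.isnan(aux_data.y)
    r = float(stats.pearsonr(eta[mask], aux_data.y[mask]).statistic)
    if r < r_floor:
        logger.warning(
            "imputation fidelity r = %.3f below floor %.2f; treat imputed covariate with care",
            r, r_floor,
        )
    return eta, r, aux_fit
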
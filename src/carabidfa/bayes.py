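"""Bayesian Gaussian linear models with credible intervals and PSIS-LOO.

The two Bayesian stages of the pipeline (head-width model, FA-environment
model) are Gaussian-likelihood linear models with Gaussian priors on all
coefficients.  Two interchangeable backends are provided:

``conjugate``
    The response is standardized and the model is the Normal-Inverse-Gamma
    conjugate family: ``beta | sigma^2 ~ N(0, sigma^2 * diag(tau^2))``,
    ``sigma^2 ~ Inv-Gamma(a0, b0)``.  Posterior draws are exact i.i.d.
    samples from the closed-form posterior, organised into chains for
    diagnostic bookkeeping.  Fast and deterministic given a seed.

``emcee``
    Affine-invariant ensemble MCMC on the same likelihood with fixed-scale
    ``Normal(0, tau)`` priors and a half-normal prior on sigma; walkers are
    grouped into chains.  Slower; useful as an independent check.

Group-level (random) effects enter as blocks of indicator columns with a
tighter prior scale, i.e. ridge-style partial pooling at a fixed scale.
Diagnostics — per-parameter R-hat and effective sample size, PSIS-LOO and
the share of observations with a reliable Pareto-k — come from ``arviz``.
An effect is called *significant* when its central 95% credible interval
excludes zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import arviz as az
import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PosteriorSummary", "fit_bayes_lm"]

PARETO_K_GOOD = 0.7


@dataclass
class PosteriorSummary:
    """Posterior coefficient summaries plus convergence / LOO diagnostics.

    ``table`` has one row per coefficient: posterior mean, sd, 2.5% / 97.5%
    credible bounds, R-hat, bulk ESS, the posterior probability of the
    dominant sign (``prob_direction``), and a ``significant`` flag (95%
    interval excludes zero).  Coefficients are on the scale the design was
    fitted on (standardized predictors unless disabled).
    """

    table: pd.DataFrame
    sigma_mean: float
    rhat_max: float
    converged: bool
    rhat_threshold: float
    elpd_loo: float
    elpd_loo_se: float
    p_loo: float
    pareto_k: np.ndarray = field(repr=False)
    pareto_k_good_pct: float = float("nan")
    n_obs: int = 0
    n_draws: int = 0
    backend: str = "conjugate"
    idata: az.InferenceData | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out.insert(0, "term", out.index)
        return out.reset_index(drop=True)


def _build_design(
    X: pd.DataFrame,
    groups: Mapping[str, pd.Series] | None,
    standardize: bool,
):
    """Design matrix [intercept | fixed | group indicators] and prior scales."""
    names = ["Intercept"]
    cols = [np.ones(len(X))]
    scales_x = {}
    for c in X.columns:
        v = np.asarray(X[c], float)
        sd = v.std(ddof=0)
        if standardize and sd > 0:
            v = (v - v.mean()) / sd
            scales_x[c] = sd
        else:
            scales_x[c] = 1.0
        names.append(c)
        cols.append(v)
    n_fixed = len(X.columns)
    group_slices = {}
    if groups:
        for gname, ser in groups.items():
            levels = pd.unique(np.asarray(ser))
            start = len(names)
            for lev in levels:
                names.append(f"{gname}[{lev}]")
                cols.append((np.asarray(ser) == lev).astype(float))
            group_slices[gname] = slice(start, len(names))
    M = np.column_stack(cols)
    return M, names, n_fixed, group_slices, scales_x


def _draws_conjugate(M, y, tau, a0, b0, n_chains, n_draws, rng):
    """Exact Normal-Inverse-Gamma posterior draws (beta, sigma)."""
    p = M.shape[1]
    lam0 = np.diag(1.0 / tau ** 2)
    lam_n = M.T @ M + lam0
    chol = np.linalg.cholesky(lam_n)
    mu_n = np.linalg.solve(lam_n, M.T @ y)
    a_n = a0 + len(y) / 2.0
    b_n = b0 + 0.5 * float(y @ y - mu_n @ lam_n @ mu_n)
    b_n = max(b_n, 1e-12)
    total = n_chains * n_draws
    sigma2 = 1.0 / rng.gamma(a_n, 1.0 / b_n, size=total)
    z = rng.standard_normal((total, p))
    # beta | sigma2 ~ N(mu_n, sigma2 * lam_n^{-1})
    beta = mu_n[None, :] + np.sqrt(sigma2)[:, None] * np.linalg.solve(
        chol.T, z.T).T
    return (beta.reshape(n_chains, n_draws, p),
            np.sqrt(sigma2).reshape(n_chains, n_draws))


def _draws_emcee(M, y, tau, sigma_scale, n_chains, n_draws, rng):
    import emcee

    n, p = M.shape

    def log_prob(theta):
        theta = np.atleast_2d(theta)
        beta, log_sigma = theta[:, :p], theta[:, p]
        sigma = np.exp(log_sigma)
        resid = y[None, :] - beta @ M.T
        ll = (-n * log_sigma - 0.5 * np.sum(resid ** 2, axis=1) / sigma ** 2)
        lp = (-0.5 * np.sum((beta / tau[None, :]) ** 2, axis=1)
              - 0.5 * (sigma / sigma_scale) ** 2 + log_sigma)  # half-normal + jacobian
        return ll + lp

    ndim = p + 1
    n_walkers = max(2 * ndim + 2, 4 * n_chains)
    n_walkers -= n_walkers % n_chains
    beta_hat, *_ = np.linalg.lstsq(M, y, rcond=None)
    resid_sd = max(np.std(y - M @ beta_hat), 1e-3)
    start = np.column_stack([
        beta_hat[None, :] + 0.1 * resid_sd * rng.standard_normal((n_walkers, p)),
        np.log(resid_sd) + 0.1 * rng.standard_normal((n_walkers, 1)),
    ])
    sampler = emcee.EnsembleSampler(n_walkers, ndim, log_prob, vectorize=True)
    steps_needed = int(np.ceil(n_draws * n_chains / n_walkers))
    sampler.random_state = np.random.RandomState(
        int(rng.integers(2 ** 31 - 1)))
    sampler.run_mcmc(start, 2 * steps_needed + 50, progress=False)
    chain = sampler.get_chain(discard=steps_needed + 50)  # (steps, walkers, dim)
    flat = chain.reshape(-1, ndim)[: n_chains * n_draws]
    beta = flat[:, :p].reshape(n_chains, n_draws, p)
    sigma = np.exp(flat[:, p]).reshape(n_chains, n_draws)
    return beta, sigma


def fit_bayes_lm(
    y: pd.Series | np.ndarray,
    X: pd.DataFrame,
    groups: Mapping[str, pd.Series] | None = None,
    prior_scale: float = 2.5,
    group_prior_scale: float = 1.0,
    chains: int = 4,
    iterations: int = 3000,
    seed: int = 0,
    backend: str = "conjugate",
    standardize: bool = True,
    rhat_threshold: float = 1.01,
) -> PosteriorSummary:
    """Fit a Bayesian Gaussian linear model of ``y`` on fixed effects ``X``
    with optional group-level intercepts.

    ``iterations`` mirrors the per-chain MCMC iteration count of the
    sampling configuration; half are treated as warm-up, so each of the
    ``chains`` chains contributes ``iterations // 2`` posterior draws.
    The response is internally standardized (restored nowhere: coefficient
    summaries are on the standardized-response scale, the convention for
    reporting comparable effect sizes across predictors).
    """
    y = np.asarray(y, float)
    if not len(y):
        raise ValueError("empty response")
    M, names, n_fixed, group_slices, _ = _build_design(X, groups, standardize)
    y_sd = y.std(ddof=0)
    y_c = (y - y.mean()) / y_sd if y_sd > 0 else y - y.mean()

    tau = np.full(M.shape[1], prior_scale)
    tau[0] = 10.0  # vague intercept
    for sl in group_slices.values():
        tau[sl] = group_prior_scale

    n_draws = max(iterations // 2, 50)
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    if backend == "conjugate":
        beta, sigma = _draws_conjugate(M, y_c, tau, a0=2.0, b0=0.5,
                                       n_chains=chains, n_draws=n_draws, rng=rng)
    elif backend == "emcee":
        beta, sigma = _draws_emcee(M, y_c, tau, sigma_scale=prior_scale,
                                   n_chains=chains, n_draws=n_draws, rng=rng)
    else:
        raise ValueError(f"unknown backend {backend!r}")

    # pointwise log-likelihood for LOO (cap stored draws to bound memory)
    keep = min(n_draws, 1000)
    mu = beta[:, :keep] @ M.T  # (chains, keep, n_obs)
    loglik = stats.norm.logpdf(y_c[None, None, :], mu,
                               sigma[:, :keep, None])

    posterior = {name: beta[:, :, j] for j, name in enumerate(names)}
    posterior["sigma"] = sigma
    idata = az.from_dict(posterior=posterior,
                         log_likelihood={"y": loglik},
                         observed_data={"y": y_c})

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat_ds = az.rhat(idata)
        ess_ds = az.ess(idata)
        loo_res = az.loo(idata, pointwise=True)

    rows = []
    for j, name in enumerate(names):
        d = beta[:, :, j].ravel()
        lo, hi = np.quantile(d, [0.025, 0.975])
        p_pos = float(np.mean(d > 0))
        rows.append({
            "mean": float(d.mean()),
            "sd": float(d.std(ddof=1)),
            "ci_2.5%": float(lo),
            "ci_97.5%": float(hi),
            "prob_direction": max(p_pos, 1 - p_pos),
            "significant": bool(lo > 0 or hi < 0),
            "rhat": float(rhat_ds[name].values),
            "ess_bulk": float(ess_ds[name].values),
            "kind": ("fixed" if j <= n_fixed else "group"),
        })
    table = pd.DataFrame(rows, index=names)
    rhat_max = float(np.nanmax(table["rhat"]))
    converged = rhat_max <= rhat_threshold
    if not converged:
        warnings.warn(
            f"max R-hat {rhat_max:.3f} exceeds {rhat_threshold}; consider "
            "more iterations — results emitted flagged", stacklevel=2)

    k = np.asarray(loo_res.pareto_k)
    return PosteriorSummary(
        table=table,
        sigma_mean=float(sigma.mean()),
        rhat_max=rhat_max,
        converged=converged,
        rhat_threshold=rhat_threshold,
        elpd_loo=float(loo_res.elpd_loo),
        elpd_loo_se=float(loo_res.se),
        p_loo=float(loo_res.p_loo),
        pareto_k=k,
        pareto_k_good_pct=100.0 * float(np.mean(k <= PARETO_K_GOOD)),
        n_obs=len(y),
        n_draws=int(beta.shape[0] * beta.shape[1]),
        backend=backend,
        idata=idata,
    )
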
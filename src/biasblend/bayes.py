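"""Bayesian hierarchical additive-bias models and their MCMC machinery.

The measurement model for a prevalence estimate ``y_ij`` from source j in
area i is

    y_ij     ~ Normal(theta_i + delta_ij, sigma_ij^2)   (sigma known)
    delta_ij ~ Normal(mu_j, tau_j^2)

with vague priors on the source bias means mu_j and bias SDs tau_j.  The
area levels theta_i and the bias means are confounded (adding a constant
to all theta and subtracting it from all mu leaves the likelihood
unchanged), so the posterior is identified after sampling by recentring
every retained draw so that the area mean equals an externally supplied
regional anchor prevalence — the redundant-parameterization device.

Three model families are provided:

* :class:`AdditiveBiasModel` — independent per-source biases, with
  variants: identification through one source declared unbiased instead
  of an anchor, exchangeable bias SDs under a shared half-normal, or a
  single common bias SD.
* :class:`CorrelatedBiasModel` — bias vectors multivariate normal across
  sources within an area, covariance given a scaled inverse-Wishart
  prior (or fixed to a supplied correlation structure).
* :class:`TrendBiasModel` — area-specific linear time trends with fixed
  intercepts (levels in 2005) and exchangeable random slopes; the time
  covariate is x_j = 2005 - year_j.

Sampling uses a blocked Gibbs scheme: all location parameters are drawn
exactly from their joint Gaussian conditional on the marginal form (bias
terms integrated out), variance parameters move by univariate slice
sampling or conjugate truncated inverse-gamma draws, and the cell-level
biases are imputed for reporting and DIC.  A fully hierarchical
conjugate Gibbs backend is available as an internal cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import arviz as az
import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.base import BaseEstimator

from ._mcmc import draw_mvn_precision, sample_trunc_invgamma, slice_sample
from .table import EstimateTable, validate_table

REFERENCE_YEAR = 2005


class ConvergenceWarning(UserWarning):
    """MCMC diagnostics exceeded their thresholds."""


# ---------------------------------------------------------------------------
# configuration containers
# ---------------------------------------------------------------------------

@dataclass
class PriorConfig:
    """Prior hyperparameters, all on the percent scale.

    Defaults follow the vague choices used throughout: Normal(0, 100^2)
    for bias means, Uniform(0, 100) for bias SDs and hyper-SDs, and for
    the correlated model an inverse-Wishart with identity scale and
    S + 1 degrees of freedom behind lognormal(0, 1) scale factors.
    """

    mu_prior_sd: float = 100.0
    tau_upper: float = 100.0
    theta_bounds: tuple = (0.0, 100.0)
    sigma_tau_upper: float = 100.0
    wishart_df: Optional[int] = None  # defaults to S + 1 at fit time
    xi_prior_sd: float = 1.0
    slope_mu_prior_sd: float = 100.0
    slope_sd_upper: float = 100.0
    anchor_sd: Optional[float] = None  # uncertain-anchor option, off by default

    def __post_init__(self):
        for name in ("mu_prior_sd", "tau_upper", "sigma_tau_upper",
                     "xi_prior_sd", "slope_mu_prior_sd", "slope_sd_upper"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.theta_bounds
        if not (0.0 <= lo < hi <= 100.0):
            raise ValueError("theta_bounds must lie within (0, 100]")


@dataclass
class McmcConfig:
    """Chain settings and convergence thresholds."""

    n_chains: int = 2
    n_iter: int = 3000
    n_burnin: int = 750
    thin: int = 1
    seed: int = 0
    rhat_threshold: float = 1.05
    mcse_fraction_threshold: float = 0.03

    def __post_init__(self):
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if self.n_iter <= self.n_burnin:
            raise ValueError("n_iter must exceed n_burnin")


@dataclass
class PosteriorSummary:
    """Identified draws, summaries and diagnostics for one fitted model."""

    model: str
    anchor: Optional[float]
    area_labels: list
    source_labels: list
    draws: dict
    summary: pd.DataFrame
    dic: dict
    ssr: float
    ssr_sd: float
    convergence: dict
    table_fingerprint: str
    source_year: Optional[np.ndarray] = None

    def _mean(self, key):
        v = self.draws[key]
        return v.reshape(-1, *v.shape[2:]).mean(axis=0)

    @property
    def theta_mean(self) -> np.ndarray:
        key = "alpha" if "alpha" in self.draws else "theta"
        return self._mean(key)

    @property
    def mu_mean(self) -> np.ndarray:
        return self._mean("mu")

    @property
    def tau_mean(self) -> np.ndarray:
        return self._mean("tau")

    def quantiles(self, key, qs=(0.025, 0.975)):
        v = self.draws[key]
        flat = v.reshape(-1, *v.shape[2:])
        return np.quantile(flat, qs, axis=0)

    @property
    def converged(self) -> bool:
        return bool(self.convergence.get("converged", False))


# ---------------------------------------------------------------------------
# spec-level primitive operations
# ---------------------------------------------------------------------------

def log_joint_model1(state: dict, table: EstimateTable, priors: PriorConfig = None,
                     components: bool = False):
    """Log joint density of the additive-bias model at one parameter state.

    ``state`` holds arrays ``theta`` (A,), ``mu`` (S,), ``tau`` (S,) and
    ``delta`` (A, S).  Bias SDs outside (0, tau_upper) give ``-inf`` (by
    contract, not an exception).  With ``components=True`` a dict with
    ``data``, ``bias``, ``prior`` and ``total`` terms is returned.
    """
    priors = priors or PriorConfig()
    theta = np.asarray(state["theta"], float)
    mu = np.asarray(state["mu"], float)
    tau = np.asarray(state["tau"], float)
    delta = np.asarray(state["delta"], float)
    m = table.present
    if np.any(tau <= 0) or np.any(tau >= priors.tau_upper):
        out = {"data": -np.inf, "bias": -np.inf, "prior": -np.inf,
               "total": -np.inf}
        return out if components else -np.inf
    data = float(
        stats.norm.logpdf(table.y[m], (theta[:, None] + delta)[m], table.se[m]).sum()
    )
    tau_grid = np.broadcast_to(tau[None, :], delta.shape)
    mu_grid = np.broadcast_to(mu[None, :], delta.shape)
    bias = float(stats.norm.logpdf(delta[m], mu_grid[m], tau_grid[m]).sum())
    prior = float(
        stats.norm.logpdf(mu, 0.0, priors.mu_prior_sd).sum()
        - len(tau) * np.log(priors.tau_upper)
    )
    total = data + bias + prior
    if components:
        return {"data": data, "bias": bias, "prior": prior, "total": total}
    return total


def recenter_draws(draws: dict, anchor) -> dict:
    """Identify raw draws by shifting each one to the anchor constraint.

    Per draw the shift ``phi = mean(theta) - anchor`` is subtracted from
    every area level and added to every bias mean and bias term, leaving
    all fitted cell means (hence the likelihood) invariant.  ``anchor``
    may be a scalar or an array broadcastable over (chains, draws) for
    the uncertain-anchor option.  Returns a new dict; inputs untouched.
    """
    key = "alpha" if "alpha" in draws else "theta"
    out = {k: np.array(v) for k, v in draws.items()}
    phi = out[key].mean(axis=-1) - anchor  # (chains, draws)
    out[key] = out[key] - phi[..., None]
    if "mu" in out:
        out["mu"] = out["mu"] + phi[..., None]
    if "delta" in out:
        out["delta"] = out["delta"] + phi[..., None, None]
    return out


def recenter_trend_draws(draws: dict, x: np.ndarray) -> dict:
    """Identify the slope direction of time-trend draws.

    Because the time covariate is constant within a source, a common
    slope shift can be traded against the source bias means
    (``beta_i + c``, ``mu_j - c x_j`` leaves the likelihood invariant).
    The identified representation attributes no linear-in-time component
    to the biases: per draw, the least-squares slope ``c`` of ``mu_j``
    on ``x_j`` is moved into the area slopes and their mean.
    """
    out = {k: np.array(v) for k, v in draws.items()}
    xc = x - x.mean()
    ssx = (xc ** 2).sum()
    if ssx <= 0:
        return out
    mu = out["mu"]
    c = ((mu - mu.mean(axis=-1, keepdims=True)) * xc).sum(axis=-1) / ssx
    out["mu"] = mu - c[..., None] * x
    out["beta"] = out["beta"] + c[..., None]
    out["mu_beta"] = out["mu_beta"] + c
    if "delta" in out:
        out["delta"] = out["delta"] - c[..., None, None] * x[None, None, None, :]
    return out


def compute_dic(draws: dict, table: EstimateTable) -> dict:
    """Deviance information criterion at the cell-mean focus.

    The deviance is ``-2 sum log Normal(y_ij | m_ij, sigma_ij^2)`` over
    present cells, with ``m_ij`` the fitted cell mean (area level plus
    bias, plus trend terms when present), taken from ``draws["cell_mean"]``.
    ``pD = Dbar - D(mean cell means)`` and ``DIC = Dbar + pD``.
    """
    cm = draws["cell_mean"]
    flat = cm.reshape(-1, *cm.shape[2:])
    if flat.shape[0] < 2:
        raise ValueError("DIC requires at least 2 retained draws")
    m = table.present
    y = table.y[m]
    s2 = table.se2[m]
    const = np.log(2.0 * np.pi * s2).sum()

    def dev(cell_means):
        return const + (((y - cell_means[m]) ** 2) / s2).sum()

    devs = np.array([dev(flat[s]) for s in range(flat.shape[0])])
    dbar = float(devs.mean())
    dhat = float(dev(flat.mean(axis=0)))
    pd_ = dbar - dhat
    return {"Dbar": dbar, "pD": pd_, "DIC": dbar + pd_}


# ---------------------------------------------------------------------------
# summaries and convergence diagnostics
# ---------------------------------------------------------------------------

def _param_names(key, shape, area_labels, source_labels):
    if len(shape) == 0:
        return [key]
    if len(shape) == 1:
        labels = (area_labels if shape[0] == len(area_labels)
                  and key in ("theta", "alpha", "beta") else source_labels)
        if len(labels) != shape[0]:
            labels = [str(i) for i in range(shape[0])]
        return [f"{key}[{l}]" for l in labels]
    if len(shape) == 2:
        if key in ("rho", "Sigma"):
            return [f"{key}[{a},{b}]" for a in source_labels
                    for b in source_labels]
        return [f"{key}[{a},{b}]" for a in area_labels for b in source_labels]
    raise ValueError(shape)


def _summarize(draws: dict, keys, area_labels, source_labels, mcmc: McmcConfig):
    rows = []
    flagged = []
    max_rhat = 0.0
    max_mcse_frac = 0.0
    for key in keys:
        v = draws[key]
        ds = az.convert_to_dataset({key: v})
        rhat = np.asarray(az.rhat(ds)[key]).reshape(-1)
        mcse = np.asarray(az.mcse(ds, method="mean")[key]).reshape(-1)
        ess = np.asarray(az.ess(ds)[key]).reshape(-1)
        flat = v.reshape(-1, *v.shape[2:]).reshape(v.shape[0] * v.shape[1], -1)
        mean = flat.mean(axis=0)
        sd = flat.std(axis=0, ddof=1)
        q025 = np.quantile(flat, 0.025, axis=0)
        q975 = np.quantile(flat, 0.975, axis=0)
        names = _param_names(key, v.shape[2:], area_labels, source_labels)
        for i, name in enumerate(names):
            frac = mcse[i] / sd[i] if sd[i] > 1e-12 else 0.0
            rh = rhat[i] if np.isfinite(rhat[i]) else 1.0
            rows.append({
                "parameter": name, "mean": mean[i], "sd": sd[i],
                "q2.5": q025[i], "q97.5": q975[i],
                "rhat": rh, "ess": ess[i], "mcse": mcse[i],
            })
            bad = rh > mcmc.rhat_threshold or frac > mcmc.mcse_fraction_threshold
            if bad and sd[i] > 1e-12:
                flagged.append(name)
            max_rhat = max(max_rhat, rh if sd[i] > 1e-12 else 1.0)
            max_mcse_frac = max(max_mcse_frac, frac)
    summary = pd.DataFrame(rows)
    convergence = {
        "max_rhat": max_rhat,
        "max_mcse_fraction": max_mcse_frac,
        "flagged": flagged,
        "converged": not flagged,
        "rhat_threshold": mcmc.rhat_threshold,
        "mcse_fraction_threshold": mcmc.mcse_fraction_threshold,
    }
    return summary, convergence


def _ssr_draws(y, se2, present, theta, mu, tau, trend=None):
    """Per-draw sum of squared standardized residuals (marginal scale)."""
    resid = y[None, None] - theta[..., None] - mu[..., None, :]
    if trend is not None:
        resid = resid - trend
    v = se2[None, None] + tau[..., None, :] ** 2
    r2 = np.where(present[None, None], resid ** 2 / v, 0.0)
    return r2.sum(axis=(-2, -1))


def _finalize(model, table, anchor, draws, mcmc, extra_keys=(), source_year=None):
    """Recentre, summarize, compute DIC/SSR and assemble a PosteriorSummary."""
    loc_key = "alpha" if "alpha" in draws else "theta"
    if anchor is None:
        stored_anchor = None
    else:
        stored_anchor = float(anchor) if np.ndim(anchor) == 0 else float(np.mean(anchor))
    if "beta" in draws:
        draws = recenter_trend_draws(
            draws, (REFERENCE_YEAR - source_year.astype(float)))
    if anchor is not None:
        draws = recenter_draws(draws, anchor)
    trend = None
    if "beta" in draws:
        x = (REFERENCE_YEAR - source_year.astype(float))[None, None, None, :]
        trend = draws["beta"][..., None] * x
    draws["cell_mean"] = draws[loc_key][..., None] + draws["delta"] + (
        trend if trend is not None else 0.0
    )
    ssr = _ssr_draws(table.y, table.se2, table.present,
                     draws[loc_key], draws["mu"], draws["tau"], trend)
    draws["ssr"] = ssr
    dic = compute_dic(draws, table)
    keys = [loc_key, "mu", "tau", "delta", *extra_keys]
    summary, conv = _summarize(draws, keys, table.area_labels,
                               table.source_labels, mcmc)
    if not conv["converged"]:
        warnings.warn(
            f"{model}: convergence diagnostics flagged "
            f"{len(conv['flagged'])} parameter(s) "
            f"(max rhat {conv['max_rhat']:.3f}, "
            f"max MCSE fraction {conv['max_mcse_fraction']:.3f})",
            ConvergenceWarning, stacklevel=3,
        )
    return PosteriorSummary(
        model=model, anchor=stored_anchor,
        area_labels=list(table.area_labels),
        source_labels=list(table.source_labels),
        draws=draws, summary=summary, dic=dic,
        ssr=float(ssr.mean()), ssr_sd=float(ssr.std(ddof=1)),
        convergence=conv, table_fingerprint=table.fingerprint(),
        source_year=source_year,
    )


# ---------------------------------------------------------------------------
# additive model: collapsed blocked Gibbs
# ---------------------------------------------------------------------------

def _draw_locations_additive(y, se2, present, tau2, mu_prec, rng,
                             anchored_idx=None, theta_bounds=None):
    """Exact joint draw of (theta, mu) from the marginal Gaussian model."""
    A, S = y.shape
    W = np.where(present, 1.0 / (se2 + tau2[None, :]), 0.0)
    mu_cols = [j for j in range(S) if j != anchored_idx]
    k = A + len(mu_cols)
    P = np.zeros((k, k))
    idx = np.arange(A)
    P[idx, idx] = W.sum(axis=1)
    col_w = W.sum(axis=0)
    Wy = W * y
    b = np.empty(k)
    b[:A] = Wy.sum(axis=1)
    for pos, j in enumerate(mu_cols):
        P[A + pos, A + pos] = col_w[j] + mu_prec
        P[:A, A + pos] = W[:, j]
        P[A + pos, :A] = W[:, j]
        b[A + pos] = Wy[:, j].sum()
    for attempt in range(100):
        gamma, _ = draw_mvn_precision(P, b, rng)
        theta = gamma[:A]
        if theta_bounds is None:
            break
        lo, hi = theta_bounds
        if np.all((theta > lo) & (theta < hi)):
            break
    else:
        theta = np.clip(gamma[:A], theta_bounds[0] + 1e-9, theta_bounds[1] - 1e-9)
    mu = np.zeros(S)
    mu[mu_cols] = gamma[A:]
    return theta, mu


def _slice_tau_independent(tau, resid, se2, present, rng, upper, hn_var=None,
                           n_passes=1):
    S = tau.shape[0]
    for j in range(S):
        mask = present[:, j]
        r = resid[mask, j]
        s2 = se2[mask, j]

        def logf(t):
            v = s2 + t * t
            val = -0.5 * (np.log(v).sum() + (r * r / v).sum())
            if hn_var is not None:
                val -= 0.5 * t * t / hn_var
            return val

        for _ in range(n_passes):
            tau[j] = slice_sample(tau[j], logf, 0.0, upper, rng)
    return tau


def _chain_additive(y, se2, present, priors, tau_model, anchored_idx,
                    n_iter, n_burnin, thin, rng):
    A, S = y.shape
    mu_prec = 1.0 / priors.mu_prior_sd ** 2
    tau = rng.uniform(0.5, 1.5, size=S)
    sigma_tau2 = 1.0
    bounds = priors.theta_bounds if anchored_idx is not None else None
    keep_theta, keep_mu, keep_tau, keep_delta, keep_st = [], [], [], [], []
    for it in range(n_iter):
        tau2 = tau ** 2
        theta, mu = _draw_locations_additive(
            y, se2, present, tau2, mu_prec, rng, anchored_idx, bounds)
        resid = y - theta[:, None] - mu[None, :]
        if tau_model == "equal":
            r = resid[present]
            s2 = se2[present]

            def logf(t):
                v = s2 + t * t
                return -0.5 * (np.log(v).sum() + (r * r / v).sum())

            t = slice_sample(tau[0], logf, 0.0, priors.tau_upper, rng)
            tau = np.full(S, t)
        elif tau_model == "exchangeable":
            tau = _slice_tau_independent(tau, resid, se2, present, rng,
                                         priors.tau_upper, hn_var=sigma_tau2)
            sigma_tau2 = sample_trunc_invgamma(
                (S - 1) / 2.0, (tau ** 2).sum() / 2.0,
                priors.sigma_tau_upper ** 2, rng)
        else:
            tau = _slice_tau_independent(tau, resid, se2, present, rng,
                                         priors.tau_upper)
        if it >= n_burnin and (it - n_burnin) % thin == 0:
            tau2 = tau ** 2
            vd = 1.0 / (1.0 / se2 + 1.0 / tau2[None, :])
            md = vd * ((y - theta[:, None]) / se2 + mu[None, :] / tau2[None, :])
            delta = md + np.sqrt(vd) * rng.standard_normal((A, S))
            prior_delta = mu[None, :] + tau[None, :] * rng.standard_normal((A, S))
            delta = np.where(present, delta, prior_delta)
            keep_theta.append(theta)
            keep_mu.append(mu)
            keep_tau.append(tau.copy())
            keep_delta.append(delta)
            keep_st.append(np.sqrt(sigma_tau2))
    out = {
        "theta": np.array(keep_theta),
        "mu": np.array(keep_mu),
        "tau": np.array(keep_tau),
        "delta": np.array(keep_delta),
    }
    if tau_model == "exchangeable":
        out["sigma_tau"] = np.array(keep_st)
    return out


def _chain_additive_hierarchical(y, se2, present, priors, n_iter, n_burnin,
                                 thin, rng):
    """Fully hierarchical conjugate Gibbs on the non-marginalized model.

    Internal cross-check backend for the plain additive model: updates
    theta | delta, delta | theta mu tau, mu | delta tau and tau | delta mu
    from their exact conditionals.
    """
    A, S = y.shape
    mu_prec = 1.0 / priors.mu_prior_sd ** 2
    W0 = np.where(present, 1.0 / se2, 0.0)
    theta = np.nanmean(np.where(present, y, np.nan), axis=1)
    mu = np.zeros(S)
    tau2 = rng.uniform(0.5, 1.5, size=S) ** 2
    delta = np.zeros((A, S))
    keep = {"theta": [], "mu": [], "tau": [], "delta": []}
    n_j = present.sum(axis=0)
    for it in range(n_iter):
        prec_t = W0.sum(axis=1)
        mean_t = (W0 * (y - delta)).sum(axis=1) / prec_t
        theta = mean_t + rng.standard_normal(A) / np.sqrt(prec_t)
        vd = 1.0 / (1.0 / se2 + 1.0 / tau2[None, :])
        md = vd * ((y - theta[:, None]) / se2 + mu[None, :] / tau2[None, :])
        delta = md + np.sqrt(vd) * rng.standard_normal((A, S))
        prior_delta = mu[None, :] + np.sqrt(tau2)[None, :] * \
            rng.standard_normal((A, S))
        delta = np.where(present, delta, prior_delta)
        prec_m = n_j / tau2 + mu_prec
        mean_m = np.where(present, delta, 0.0).sum(axis=0) / tau2 / prec_m
        mu = mean_m + rng.standard_normal(S) / np.sqrt(prec_m)
        for j in range(S):
            ss = ((delta[present[:, j], j] - mu[j]) ** 2).sum()
            tau2[j] = sample_trunc_invgamma(
                (n_j[j] - 1) / 2.0, ss / 2.0, priors.tau_upper ** 2, rng)
        if it >= n_burnin and (it - n_burnin) % thin == 0:
            keep["theta"].append(theta.copy())
            keep["mu"].append(mu.copy())
            keep["tau"].append(np.sqrt(tau2))
            keep["delta"].append(delta.copy())
    return {k: np.array(v) for k, v in keep.items()}


# ---------------------------------------------------------------------------
# correlated-bias model
# ---------------------------------------------------------------------------

def _draw_locations_mvn(y, se2, present, Sigma, mu_prec, rng):
    """Joint (theta, mu) draw with full between-source bias covariance."""
    A, S = y.shape
    k = A + S
    P = np.zeros((k, k))
    b = np.zeros(k)
    if present.all():
        Cs = np.tile(Sigma, (A, 1, 1))
        Cs[:, np.arange(S), np.arange(S)] += se2
        Ks = np.linalg.inv(Cs)
        row = Ks.sum(axis=1)                       # (A, S): 1'K_i
        P[np.arange(A), np.arange(A)] = row.sum(axis=1)
        P[:A, A:] = row
        P[A:, :A] = row.T
        P[A:, A:] = Ks.sum(axis=0)
        Ky = np.einsum("ast,at->as", Ks, y)
        b[:A] = Ky.sum(axis=1)
        b[A:] = Ky.sum(axis=0)
    else:
        for i in range(A):
            idx = np.flatnonzero(present[i])
            C = Sigma[np.ix_(idx, idx)].copy()
            C[np.arange(len(idx)), np.arange(len(idx))] += se2[i, idx]
            K = np.linalg.inv(C)
            r = K.sum(axis=0)
            P[i, i] = r.sum()
            P[i, A + idx] = r
            P[A + idx, i] = r
            P[np.ix_(A + idx, A + idx)] += K
            Ky = K @ y[i, idx]
            b[i] = Ky.sum()
            b[A + idx] += Ky
    P[A:, A:][np.arange(S), np.arange(S)] += mu_prec
    gamma, _ = draw_mvn_precision(P, b, rng)
    return gamma[:A], gamma[A:]


def _draw_delta_mvn(y, se2, present, theta, mu, Sigma, rng):
    """Impute bias vectors given locations and covariance."""
    A, S = y.shape
    Sinv = np.linalg.inv(Sigma)
    delta = np.empty((A, S))
    if present.all():
        Ps = np.tile(Sinv, (A, 1, 1))
        Ps[:, np.arange(S), np.arange(S)] += 1.0 / se2
        bs = (Sinv @ mu)[None, :] + (y - theta[:, None]) / se2
        Ls = np.linalg.cholesky(Ps)
        mean = np.linalg.solve(Ps, bs[..., None])[..., 0]
        z = rng.standard_normal((A, S))
        pert = np.linalg.solve(np.transpose(Ls, (0, 2, 1)), z[..., None])[..., 0]
        return mean + pert
    from scipy.linalg import cho_solve, solve_triangular
    for i in range(A):
        idx = np.flatnonzero(present[i])
        P = Sinv.copy()
        P[np.ix_(idx, idx)] += np.diag(1.0 / se2[i, idx])
        bvec = Sinv @ mu
        bvec[idx] += (y[i, idx] - theta[i]) / se2[i, idx]
        L = np.linalg.cholesky(P)
        mean = cho_solve((L, True), bvec)
        d = mean + solve_triangular(L.T, rng.standard_normal(S), lower=False)
        delta[i] = d
    return delta


def _marginal_ll_mvn(resid, se2, present, Sigma, uniform_se=False):
    """Marginal log likelihood (biases integrated out) up to a constant.

    ``resid`` are the location residuals y - theta - mu; each area
    contributes a multivariate normal with covariance D_i + Sigma over
    its present cells.  When every area shares the same sampling SDs
    (``uniform_se``) a single S x S factorization serves all areas.
    """
    A, S = resid.shape
    if uniform_se:
        C = Sigma + np.diag(se2[0])
        try:
            L = np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            return -np.inf
        logdet = 2.0 * np.log(np.diag(L)).sum()
        sol = linalg.cho_solve((L, True), resid.T)
        return -0.5 * (A * logdet + (resid.T * sol).sum())
    if present.all():
        Cs = np.tile(Sigma, (A, 1, 1))
        Cs[:, np.arange(S), np.arange(S)] += se2
        sign, logdet = np.linalg.slogdet(Cs)
        if np.any(sign <= 0):
            return -np.inf
        sol = np.linalg.solve(Cs, resid[..., None])[..., 0]
        return -0.5 * (logdet.sum() + (resid * sol).sum())
    val = 0.0
    for i in range(A):
        idx = np.flatnonzero(present[i])
        C = Sigma[np.ix_(idx, idx)].copy()
        C[np.arange(len(idx)), np.arange(len(idx))] += se2[i, idx]
        sign, ld = np.linalg.slogdet(C)
        if sign <= 0:
            return -np.inf
        r = resid[i, idx]
        val += -0.5 * (ld + r @ np.linalg.solve(C, r))
    return val


def _draw_delta_uniform(y, se2_row, theta, mu, Sigma, rng):
    """Bias imputation when every area shares the same sampling SDs."""
    A, S = y.shape[0], len(mu)
    Sinv = np.linalg.inv(Sigma)
    P = Sinv + np.diag(1.0 / se2_row)
    Lp = np.linalg.cholesky(P)
    b = (Sinv @ mu)[None, :] + (y - theta[:, None]) / se2_row[None, :]
    mean = linalg.cho_solve((Lp, True), b.T).T
    z = rng.standard_normal((S, A))
    pert = linalg.solve_triangular(Lp.T, z, lower=False).T
    return mean + pert


def _chain_mvn_wishart(y, se2, present, priors, n_iter, n_burnin, thin, rng):
    """Hybrid sampler for the scaled-inverse-Wishart covariance model.

    Per sweep: exact joint (theta, mu) draw with the biases integrated
    out; marginal slice updates of the scale factors xi against the
    bias-marginal likelihood; then several bias-imputation /
    inverse-Wishart sub-sweeps for the correlation base Q.  The marginal
    xi moves carry the overall covariance scale (the slow direction of
    plain data augmentation when sampling SDs rival the bias SDs), while
    the conjugate sub-sweeps move the whole correlation structure
    jointly.
    """
    A, S = y.shape
    mu_prec = 1.0 / priors.mu_prior_sd ** 2
    df0 = priors.wishart_df if priors.wishart_df is not None else S + 1
    xi = np.exp(rng.uniform(-0.5, 0.5, size=S))
    Q = np.eye(S)
    uniform_se = bool(present.all() and np.all(se2 == se2[0]))
    n_sub = 12
    keep = {"theta": [], "mu": [], "tau": [], "delta": [], "Sigma": [],
            "rho": []}
    for it in range(n_iter):
        Sigma = (xi[:, None] * Q) * xi[None, :]
        theta, mu = _draw_locations_mvn(y, se2, present, Sigma, mu_prec, rng)
        resid = y - theta[:, None] - mu[None, :]

        for j in range(S):
            def logf_xi(u):
                xx = xi.copy()
                xx[j] = np.exp(u)
                Sg = (xx[:, None] * Q) * xx[None, :]
                return (_marginal_ll_mvn(resid, se2, present, Sg, uniform_se)
                        - 0.5 * (u / priors.xi_prior_sd) ** 2)

            xi[j] = np.exp(slice_sample(np.log(xi[j]), logf_xi, -15.0, 15.0,
                                        rng, width=0.4))

        for _ in range(n_sub):
            Sigma = (xi[:, None] * Q) * xi[None, :]
            if uniform_se:
                delta = _draw_delta_uniform(y, se2[0], theta, mu, Sigma, rng)
            else:
                delta = _draw_delta_mvn(y, se2, present, theta, mu, Sigma,
                                        rng)
            eta = (delta - mu[None, :]) / xi[None, :]
            scale = np.eye(S) + eta.T @ eta
            Q = stats.invwishart.rvs(df=df0 + A, scale=scale,
                                     random_state=rng)

        if it >= n_burnin and (it - n_burnin) % thin == 0:
            Sigma = (xi[:, None] * Q) * xi[None, :]
            sd = np.sqrt(np.diag(Sigma))
            keep["theta"].append(theta)
            keep["mu"].append(mu)
            keep["tau"].append(sd)
            keep["delta"].append(delta)
            keep["Sigma"].append(Sigma)
            keep["rho"].append(Sigma / np.outer(sd, sd))
    return {k: np.array(v) for k, v in keep.items()}


def _chain_mvn_fixed_corr(y, se2, present, corr, priors, n_iter, n_burnin,
                          thin, rng):
    """Correlated-bias chain with the correlation matrix held fixed;
    per-source bias SDs keep their bounded-uniform priors."""
    A, S = y.shape
    mu_prec = 1.0 / priors.mu_prior_sd ** 2
    tau = rng.uniform(0.5, 1.5, size=S)
    keep = {"theta": [], "mu": [], "tau": [], "delta": [], "Sigma": [],
            "rho": []}
    jitter = 1e-10 * np.eye(S)

    def sigma_of(t):
        return np.outer(t, t) * corr + jitter

    for it in range(n_iter):
        Sigma = sigma_of(tau)
        theta, mu = _draw_locations_mvn(y, se2, present, Sigma, mu_prec, rng)
        resid = y - theta[:, None] - mu[None, :]
        for j in range(S):
            def logf(t):
                tt = tau.copy()
                tt[j] = t
                Sig = sigma_of(tt)
                if present.all():
                    Cs = np.tile(Sig, (A, 1, 1))
                    Cs[:, np.arange(S), np.arange(S)] += se2
                    sign, logdet = np.linalg.slogdet(Cs)
                    sol = np.linalg.solve(Cs, resid[..., None])[..., 0]
                    quad = (resid * sol).sum()
                    return -0.5 * (logdet.sum() + quad)
                val = 0.0
                for i in range(A):
                    idx = np.flatnonzero(present[i])
                    C = Sig[np.ix_(idx, idx)].copy()
                    C[np.arange(len(idx)), np.arange(len(idx))] += se2[i, idx]
                    sign, ld = np.linalg.slogdet(C)
                    r = resid[i, idx]
                    val += -0.5 * (ld + r @ np.linalg.solve(C, r))
                return val

            tau[j] = slice_sample(tau[j], logf, 1e-6, priors.tau_upper, rng)
        Sigma = sigma_of(tau)
        delta = _draw_delta_mvn(y, se2, present, theta, mu, Sigma, rng)
        if it >= n_burnin and (it - n_burnin) % thin == 0:
            keep["theta"].append(theta)
            keep["mu"].append(mu)
            keep["tau"].append(tau.copy())
            keep["delta"].append(delta)
            keep["Sigma"].append(Sigma)
            keep["rho"].append(corr.copy())
    return {k: np.array(v) for k, v in keep.items()}


# ---------------------------------------------------------------------------
# time-trend model
# ---------------------------------------------------------------------------

def _draw_locations_trend(y, se2, present, tau2, x, sb2, mu_prec,
                          slope_mu_prec, rng):
    """Joint draw of (alpha, beta, mu, mu_beta) given variance parameters."""
    A, S = y.shape
    W = np.where(present, 1.0 / (se2 + tau2[None, :]), 0.0)
    k = 2 * A + S + 1
    P = np.zeros((k, k))
    b = np.zeros(k)
    ia = np.arange(A)
    Wx = W * x[None, :]
    Wxx = Wx * x[None, :]
    P[ia, ia] = W.sum(axis=1)
    P[ia, A + ia] = Wx.sum(axis=1)
    P[A + ia, ia] = Wx.sum(axis=1)
    P[A + ia, A + ia] = Wxx.sum(axis=1) + 1.0 / sb2
    P[:A, 2 * A:2 * A + S] = W
    P[2 * A:2 * A + S, :A] = W.T
    P[A:2 * A, 2 * A:2 * A + S] = Wx
    P[2 * A:2 * A + S, A:2 * A] = Wx.T
    js = np.arange(S)
    P[2 * A + js, 2 * A + js] = W.sum(axis=0) + mu_prec
    P[A + ia, k - 1] = -1.0 / sb2
    P[k - 1, A + ia] = -1.0 / sb2
    P[k - 1, k - 1] = A / sb2 + slope_mu_prec
    Wy = W * y
    b[:A] = Wy.sum(axis=1)
    b[A:2 * A] = (Wx * y).sum(axis=1)
    b[2 * A:2 * A + S] = Wy.sum(axis=0)
    gamma, _ = draw_mvn_precision(P, b, rng)
    return gamma[:A], gamma[A:2 * A], gamma[2 * A:2 * A + S], gamma[k - 1]


def _chain_trend(y, se2, present, x, priors, n_iter, n_burnin, thin, rng):
    A, S = y.shape
    mu_prec = 1.0 / priors.mu_prior_sd ** 2
    slope_mu_prec = 1.0 / priors.slope_mu_prior_sd ** 2
    tau = rng.uniform(0.5, 1.5, size=S)
    sb2 = 0.05 ** 2 + rng.uniform(0.0, 0.05) ** 2
    keep = {"alpha": [], "beta": [], "mu": [], "mu_beta": [],
            "sigma_beta": [], "tau": [], "delta": []}
    for it in range(n_iter):
        alpha, beta, mu, mu_beta = _draw_locations_trend(
            y, se2, present, tau ** 2, x, sb2, mu_prec, slope_mu_prec, rng)
        fitted = alpha[:, None] + beta[:, None] * x[None, :]
        resid = y - fitted - mu[None, :]
        tau = _slice_tau_independent(tau, resid, se2, present, rng,
                                     priors.tau_upper)
        ss = ((beta - mu_beta) ** 2).sum()
        sb2 = sample_trunc_invgamma((A - 1) / 2.0, ss / 2.0,
                                    priors.slope_sd_upper ** 2, rng)
        if it >= n_burnin and (it - n_burnin) % thin == 0:
            tau2 = tau ** 2
            vd = 1.0 / (1.0 / se2 + 1.0 / tau2[None, :])
            md = vd * ((y - fitted) / se2 + mu[None, :] / tau2[None, :])
            delta = md + np.sqrt(vd) * rng.standard_normal((A, S))
            prior_delta = mu[None, :] + tau[None, :] * rng.standard_normal((A, S))
            delta = np.where(present, delta, prior_delta)
            keep["alpha"].append(alpha)
            keep["beta"].append(beta)
            keep["mu"].append(mu)
            keep["mu_beta"].append(mu_beta)
            keep["sigma_beta"].append(np.sqrt(sb2))
            keep["tau"].append(tau.copy())
            keep["delta"].append(delta)
    return {k: np.array(v) for k, v in keep.items()}


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def _spawn_rngs(seed, n):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _run_chains(chain_fn, mcmc: McmcConfig):
    rngs = _spawn_rngs(mcmc.seed, mcmc.n_chains)
    chains = [chain_fn(r) for r in rngs]
    return {k: np.stack([c[k] for c in chains]) for k in chains[0]}


def _effective_anchor(anchor, priors, mcmc, shape):
    """Constant anchor, or per-draw anchors under the uncertain option."""
    if priors.anchor_sd is None:
        return anchor
    rng = np.random.default_rng(np.random.SeedSequence(mcmc.seed).spawn(
        mcmc.n_chains + 1)[-1])
    return anchor + priors.anchor_sd * rng.standard_normal(shape)


class _BayesEstimatorMixin:
    def _prep(self, table: EstimateTable):
        validate_table(table).raise_for_errors()
        priors = self.priors or PriorConfig()
        mcmc = self.mcmc or McmcConfig()
        return table.y, table.se2, table.present, priors, mcmc

    def _set_fitted(self, posterior: PosteriorSummary):
        self.posterior_ = posterior
        self.theta_ = posterior.theta_mean
        self.mu_ = posterior.mu_mean
        self.tau_ = posterior.tau_mean
        self.dic_ = posterior.dic
        self.summary_ = posterior.summary
        self.converged_ = posterior.converged
        self.n_features_in_ = len(posterior.source_labels)
        return self


class AdditiveBiasModel(BaseEstimator, _BayesEstimatorMixin):
    """Independent additive-bias model and its identification variants.

    Parameters
    ----------
    anchor : float
        Regional mean prevalence (percent) pinning the area average.
    anchored_source : str, optional
        Identify instead by declaring this source mean-unbiased
        (``mu_j* = 0``) with area levels bounded in ``theta_bounds``;
        the anchor is then unused.
    tau_model : {"independent", "exchangeable", "equal"}
        Bias-SD structure: free bounded-uniform per source, shared
        half-normal with uniform hyper-SD, or one common SD.
    sampler : {"collapsed", "hierarchical"}
        Blocked marginal sampler (default) or the conjugate sampler on
        the non-marginalized hierarchical form (plain model only).
    """

    def __init__(self, anchor=23.0, anchored_source=None,
                 tau_model="independent", sampler="collapsed",
                 priors=None, mcmc=None):
        self.anchor = anchor
        self.anchored_source = anchored_source
        self.tau_model = tau_model
        self.sampler = sampler
        self.priors = priors
        self.mcmc = mcmc

    def fit(self, X: EstimateTable, y=None):
        table = X
        yv, se2, present, priors, mcmc = self._prep(table)
        if self.tau_model not in ("independent", "exchangeable", "equal"):
            raise ValueError(f"unknown tau_model {self.tau_model!r}")
        if self.sampler not in ("collapsed", "hierarchical"):
            raise ValueError(f"unknown sampler {self.sampler!r}")
        anchored_idx = None
        if self.anchored_source is not None:
            if self.anchored_source not in table.source_labels:
                raise ValueError(
                    f"unknown source label {self.anchored_source!r}")
            anchored_idx = table.source_labels.index(self.anchored_source)
        if self.sampler == "hierarchical":
            if anchored_idx is not None or self.tau_model != "independent":
                raise ValueError(
                    "hierarchical backend supports the plain model only")
            chain_fn = lambda r: _chain_additive_hierarchical(
                yv, se2, present, priors, mcmc.n_iter, mcmc.n_burnin,
                mcmc.thin, r)
        else:
            chain_fn = lambda r: _chain_additive(
                yv, se2, present, priors, self.tau_model, anchored_idx,
                mcmc.n_iter, mcmc.n_burnin, mcmc.thin, r)
        draws = _run_chains(chain_fn, mcmc)
        extra = ("sigma_tau",) if self.tau_model == "exchangeable" else ()
        if anchored_idx is None:
            anchor = _effective_anchor(self.anchor, priors, mcmc,
                                       draws["theta"].shape[:2])
            tag = {"independent": "model1",
                   "exchangeable": "model1-exch-tau",
                   "equal": "model1-equal-tau"}[self.tau_model]
        else:
            anchor = None
            tag = f"model1-anchored-{self.anchored_source}"
        post = _finalize(tag, table, anchor, draws, mcmc, extra_keys=extra)
        if anchored_idx is None and np.ndim(anchor) == 0:
            # hard constraint: every retained draw averages to the anchor
            assert np.allclose(post.draws["theta"].mean(axis=-1), anchor,
                               atol=1e-9)
        return self._set_fitted(post)


class CorrelatedBiasModel(BaseEstimator, _BayesEstimatorMixin):
    """Multivariate additive-bias model across sources within an area.

    ``correlation=None`` places a scaled inverse-Wishart prior on the
    bias covariance (inverse-Wishart base with identity scale and
    ``S + 1`` degrees of freedom, lognormal scale factors); a fixed
    correlation matrix may be supplied instead, in which case only the
    per-source bias SDs are estimated.
    """

    def __init__(self, anchor=23.0, correlation=None, priors=None, mcmc=None):
        self.anchor = anchor
        self.correlation = correlation
        self.priors = priors
        self.mcmc = mcmc

    def fit(self, X: EstimateTable, y=None):
        table = X
        yv, se2, present, priors, mcmc = self._prep(table)
        S = table.n_sources
        if S < 2:
            raise ValueError("correlated model needs at least 2 sources")
        if self.correlation is None:
            chain_fn = lambda r: _chain_mvn_wishart(
                yv, se2, present, priors, mcmc.n_iter, mcmc.n_burnin,
                mcmc.thin, r)
            tag = "model2"
        else:
            corr = np.asarray(self.correlation, dtype=float)
            if corr.shape != (S, S):
                raise ValueError("correlation must be S x S")
            chain_fn = lambda r: _chain_mvn_fixed_corr(
                yv, se2, present, corr, priors, mcmc.n_iter, mcmc.n_burnin,
                mcmc.thin, r)
            tag = "model2-fixed-corr"
        draws = _run_chains(chain_fn, mcmc)
        anchor = _effective_anchor(self.anchor, priors, mcmc,
                                   draws["theta"].shape[:2])
        post = _finalize(tag, table, anchor, draws, mcmc, extra_keys=("rho",))
        self.rho_ = post._mean("rho")
        self.Sigma_ = post._mean("Sigma")
        return self._set_fitted(post)


class TrendBiasModel(BaseEstimator, _BayesEstimatorMixin):
    """Linear time-trend model with fixed intercepts and random slopes.

    The anchor constrains the mean of the intercepts, i.e. the regional
    level in the reference year 2005; the time covariate is
    ``x_j = 2005 - year_j`` (so the calendar-time slope is ``-beta_i``).
    """

    def __init__(self, anchor=23.0, allow_degenerate_years=False,
                 priors=None, mcmc=None):
        self.anchor = anchor
        self.allow_degenerate_years = allow_degenerate_years
        self.priors = priors
        self.mcmc = mcmc

    def fit(self, X: EstimateTable, y=None):
        table = X
        yv, se2, present, priors, mcmc = self._prep(table)
        if table.source_year is None:
            raise ValueError("time-trend model requires source years")
        x = REFERENCE_YEAR - table.source_year.astype(float)
        if np.unique(x).size < 2:
            msg = ("all sources share one survey year: area slopes are "
                   "unidentifiable (slope posterior equals its prior)")
            if not self.allow_degenerate_years:
                raise ValueError(msg)
            warnings.warn(msg, UserWarning, stacklevel=2)
        chain_fn = lambda r: _chain_trend(
            yv, se2, present, x, priors, mcmc.n_iter, mcmc.n_burnin,
            mcmc.thin, r)
        draws = _run_chains(chain_fn, mcmc)
        anchor = _effective_anchor(self.anchor, priors, mcmc,
                                   draws["alpha"].shape[:2])
        post = _finalize("model3", table, anchor, draws, mcmc,
                         extra_keys=("mu_beta", "sigma_beta"),
                         source_year=table.source_year)
        self._set_fitted(post)
        self.alpha_ = post._mean("alpha")
        self.beta_ = post._mean("beta")
        self.mu_beta_ = float(post._mean("mu_beta"))
        self.sigma_beta_ = float(post._mean("sigma_beta"))
        return self

    def predict(self, year: int) -> pd.DataFrame:
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "posterior_")
        return predict_prevalence(self.posterior_, year)


def predict_prevalence(posterior: PosteriorSummary, year: int) -> pd.DataFrame:
    """Per-area predictive prevalence and rank distribution for a year.

    Evaluates ``alpha_i + beta_i * (2005 - year)`` per retained draw and
    summarizes means, central 95% intervals and ranking uncertainty
    (rank 1 = highest prevalence).  The league table is sorted by
    predictive mean, highest first.
    """
    if "beta" not in posterior.draws:
        raise ValueError("posterior lacks slope draws; fit the trend model")
    x = float(REFERENCE_YEAR - year)
    alpha = posterior.draws["alpha"]
    beta = posterior.draws["beta"]
    pred = (alpha + beta * x).reshape(-1, alpha.shape[-1])
    ranks = np.argsort(np.argsort(-pred, axis=1), axis=1) + 1
    df = pd.DataFrame({
        "area": posterior.area_labels,
        "mean": pred.mean(axis=0),
        "q2.5": np.quantile(pred, 0.025, axis=0),
        "q97.5": np.quantile(pred, 0.975, axis=0),
        "rank_mean": ranks.mean(axis=0),
        "rank_q2.5": np.quantile(ranks, 0.025, axis=0),
        "rank_q97.5": np.quantile(ranks, 0.975, axis=0),
    })
    return df.sort_values("mean", ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def fit_model1(table, anchor=23.0, priors=None, mcmc=None,
               sampler="collapsed") -> PosteriorSummary:
    """Fit the basic additive-bias model with the anchor constraint."""
    est = AdditiveBiasModel(anchor=anchor, priors=priors, mcmc=mcmc,
                            sampler=sampler)
    return est.fit(table).posterior_


def fit_model1_variant(table, variant, source=None, priors=None,
                       mcmc=None) -> PosteriorSummary:
    """Fit an identification/shrinkage variant of the additive model.

    ``variant`` is one of ``"anchored_source"`` (requires ``source``),
    ``"exchangeable_tau"`` or ``"equal_tau"``.
    """
    if variant == "anchored_source":
        if source is None:
            raise ValueError("anchored_source variant needs a source label")
        est = AdditiveBiasModel(anchored_source=source, priors=priors,
                                mcmc=mcmc)
    elif variant == "exchangeable_tau":
        est = AdditiveBiasModel(tau_model="exchangeable", priors=priors,
                                mcmc=mcmc)
    elif variant == "equal_tau":
        est = AdditiveBiasModel(tau_model="equal", priors=priors, mcmc=mcmc)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return est.fit(table).posterior_


def fit_model2(table, anchor=23.0, priors=None, mcmc=None,
               correlation=None) -> PosteriorSummary:
    """Fit the correlated-bias model (scaled inverse-Wishart covariance)."""
    est = CorrelatedBiasModel(anchor=anchor, correlation=correlation,
                              priors=priors, mcmc=mcmc)
    return est.fit(table).posterior_


def fit_model3(table, anchor=23.0, priors=None, mcmc=None,
               allow_degenerate_years=False) -> PosteriorSummary:
    """Fit the linear time-trend model."""
    est = TrendBiasModel(anchor=anchor,
                         allow_degenerate_years=allow_degenerate_years,
                         priors=priors, mcmc=mcmc)
    return est.fit(table).posterior_
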
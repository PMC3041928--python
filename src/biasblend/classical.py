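"""Classical counterparts: iterative weighted ANOVA and a REML mixed model.

Both methods work on the marginal two-way additive model

    y_ij ~ Normal(theta_i + mu_j, sigma_ij^2 + tau_j^2),

with the known sampling variances sigma_ij^2 fixed, the anchor pinning
mean(theta) and the per-source bias variances tau_j^2 estimated either by
alternating a weighted two-way ANOVA with a DerSimonian-Laird moment step
(the iterative algorithm) or by maximizing the REML criterion directly.
The DL step's own uncertainty is ignored, as is conventional; this is the
classical fit's known limitation relative to the Bayesian models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator

from .table import EstimateTable, validate_table


class SingularDesignError(ValueError):
    """Disconnected area/source layout: the two-way fit is not unique."""


@dataclass
class ClassicalFit:
    """Point estimates from a classical fit of the additive model."""

    theta_hat: np.ndarray
    theta_se: np.ndarray
    mu_hat: np.ndarray
    mu_se: np.ndarray
    tau2_hat: np.ndarray
    d: np.ndarray
    n_iterations: int
    converged: bool
    mse_factor: float
    method: str
    anchor: float
    area_labels: list
    source_labels: list
    weights: np.ndarray = None
    criterion_trace: list = None


def _constrained_wls(y, w, present, anchor):
    """Weighted two-way fit with the mean-of-theta constraint eliminated.

    Parameterizes theta_i = anchor + c_i with c_A = -sum(c_1..c_{A-1}),
    giving a full-rank design when the area/source incidence graph is
    connected.  Returns estimates and the unit-scale covariance
    (weights are treated as reciprocal variances).
    """
    A, S = y.shape
    rows = np.flatnonzero(present.ravel())
    ii, jj = np.divmod(rows, S)
    n = len(rows)
    k = (A - 1) + S
    X = np.zeros((n, k))
    for r in range(n):
        i = ii[r]
        if i < A - 1:
            X[r, i] = 1.0
        else:
            X[r, :A - 1] = -1.0
        X[r, A - 1 + jj[r]] = 1.0
    sw = np.sqrt(w[ii, jj])
    Xw = X * sw[:, None]
    yw = (y[ii, jj] - anchor) * sw
    XtX = Xw.T @ Xw
    try:
        cov = np.linalg.inv(XtX)
    except np.linalg.LinAlgError as exc:
        raise SingularDesignError(
            "two-way design is singular (disconnected areas/sources)"
        ) from exc
    cond = np.linalg.cond(XtX)
    if cond > 1e10:
        raise SingularDesignError(
            f"two-way design is numerically singular (cond {cond:.2e})")
    beta = cov @ (Xw.T @ yw)
    c = beta[:A - 1]
    theta = np.empty(A)
    theta[:A - 1] = anchor + c
    theta[A - 1] = anchor - c.sum()
    mu = beta[A - 1:]
    # map covariance of the free parameters onto theta
    T = np.zeros((A, A - 1))
    T[:A - 1] = np.eye(A - 1)
    T[A - 1] = -1.0
    cov_c = cov[:A - 1, :A - 1]
    theta_se = np.sqrt(np.clip(np.diag(T @ cov_c @ T.T), 0.0, None))
    mu_se = np.sqrt(np.clip(np.diag(cov[A - 1:, A - 1:]), 0.0, None))
    return theta, mu, theta_se, mu_se


def weighted_two_way_anova(table: EstimateTable, weights, anchor):
    """Constrained weighted two-way ANOVA of prevalences by area and source.

    Minimizes ``sum w_ij (y_ij - theta_i - mu_j)^2`` over present cells
    subject to ``mean(theta) = anchor``; equivalent to the constrained
    weighted least-squares solution of the additive model.
    """
    weights = np.asarray(weights, dtype=float)
    if np.any(weights[table.present] <= 0):
        raise ValueError("weights must be positive on present cells")
    theta, mu, _, _ = _constrained_wls(table.y, weights, table.present, anchor)
    return theta, mu


def dl_moment_estimator(d, v):
    """DerSimonian-Laird moment estimator of a between-area variance.

    With weights ``w = 1/v``, pooled mean ``dbar`` and heterogeneity
    ``Q = sum w (d - dbar)^2``::

        tau2 = max(0, (Q - (k - 1)) / (sum w - sum w^2 / sum w))
    """
    d = np.asarray(d, dtype=float)
    v = np.asarray(v, dtype=float)
    k = len(d)
    if k < 2:
        raise ValueError("need at least 2 deviations for the moment estimator")
    if np.any(v <= 0):
        raise ValueError("variances must be positive")
    w = 1.0 / v
    dbar = (w * d).sum() / w.sum()
    q = (w * (d - dbar) ** 2).sum()
    denom = w.sum() - (w ** 2).sum() / w.sum()
    if denom <= 0:
        return 0.0
    return float(max(0.0, (q - (k - 1)) / denom))


def _mse_factor(y, theta, mu, w, present, n_params):
    resid = y - theta[:, None] - mu[None, :]
    n = int(present.sum())
    dof = n - n_params
    if dof <= 0:
        raise ValueError(
            f"non-positive degrees of freedom ({n} cells, {n_params} parameters)")
    mse = float((w[present] * resid[present] ** 2).sum() / dof)
    return np.sqrt(mse)


def mse_adjust(fit: ClassicalFit, table: EstimateTable,
               floor_1: bool = False) -> ClassicalFit:
    """Rescale reported SEs by the root mean-square error of the fit.

    When the weights are reciprocals of the true marginal variances the
    weighted MSE is 1 in expectation, so the factor calibrates the SEs
    against residual over- or under-dispersion.  The denominator uses
    ``N - A - S + 1`` degrees of freedom (two-way additive model with one
    identification constraint).  With ``floor_1`` the factor never
    shrinks SEs.
    """
    A, S = table.n_areas, table.n_sources
    factor = _mse_factor(table.y, fit.theta_hat, fit.mu_hat, fit.weights,
                         table.present, A + S - 1)
    if factor == 0.0:
        warnings.warn(
            "residual-free fit: MSE adjustment collapses all SEs to zero",
            UserWarning, stacklevel=2)
    if floor_1:
        factor = max(1.0, factor)
    return replace(
        fit,
        theta_se=fit.theta_se * factor,
        mu_se=fit.mu_se * factor,
        mse_factor=float(factor),
    )


def iterative_anova_fit(table: EstimateTable, anchor=23.0, tol=1e-8,
                        max_iter=100, mse_floor_1=False,
                        accelerate=True) -> ClassicalFit:
    """Alternating weighted-ANOVA / moment-estimator algorithm.

    Starting from ``tau2 = 0``: (1) weighted two-way ANOVA with weights
    ``1/(sigma_ij^2 + tau_j^2)``, the anchor constraint built in as a
    shift; (2) per-source deviations ``d_ij = y_ij - theta_i`` with
    variance ``sigma_ij^2`` feed the DerSimonian-Laird estimator of
    ``tau_j^2``; (3) iterate until ``max |change in tau2| < tol``; then
    the SEs get the multiplicative MSE adjustment.

    The plain alternation is linearly convergent with a data-dependent
    rate that can approach 0.9, so tight tolerances can need many tens
    of sweeps; with ``accelerate`` a depth-1 Anderson mixing step is
    applied, which roughly halves the sweep count while leaving the
    fixed point unchanged.  Each counted iteration performs exactly one
    ANOVA + moment-estimator sweep.
    """
    validate_table(table).raise_for_errors()
    y, se2, present = table.y, table.se2, table.present
    A, S = table.n_areas, table.n_sources
    tau2 = np.zeros(S)
    theta = mu = theta_se = mu_se = None
    converged = False
    n_it = 0
    d = np.full((A, S), np.nan)
    prev_z = prev_f = None

    def sweep(t2):
        w = np.where(present, 1.0 / (se2 + t2[None, :]), 0.0)
        th, m, th_se, m_se = _constrained_wls(y, w, present, anchor)
        dev = y - th[:, None]
        out = np.empty(S)
        for j in range(S):
            mask = present[:, j]
            out[j] = dl_moment_estimator(dev[mask, j], se2[mask, j])
        return out, th, m, th_se, m_se, dev

    for n_it in range(1, max_iter + 1):
        new_tau2, theta, mu, theta_se, mu_se, d = sweep(tau2)
        f = new_tau2 - tau2
        if np.abs(f).max() < tol:
            tau2 = new_tau2
            converged = True
            break
        if accelerate and prev_f is not None:
            df = f - prev_f
            dz = tau2 - prev_z
            denom = df @ df
            gamma = (f @ df) / denom if denom > 1e-300 else 0.0
            nxt = tau2 + f - gamma * (dz + df)
        else:
            nxt = new_tau2
        prev_z, prev_f = tau2, f
        tau2 = np.clip(nxt, 0.0, None)
    w = np.where(present, 1.0 / (se2 + tau2[None, :]), 0.0)
    theta, mu, theta_se, mu_se = _constrained_wls(y, w, present, anchor)
    d = y - theta[:, None]
    fit = ClassicalFit(
        theta_hat=theta, theta_se=theta_se, mu_hat=mu, mu_se=mu_se,
        tau2_hat=tau2, d=np.where(present, d, np.nan),
        n_iterations=n_it, converged=converged, mse_factor=1.0,
        method="iterative_anova", anchor=anchor,
        area_labels=list(table.area_labels),
        source_labels=list(table.source_labels), weights=w,
    )
    return mse_adjust(fit, table, floor_1=mse_floor_1)


def reml_criterion(table: EstimateTable, tau, anchor=23.0):
    """Restricted log-likelihood of the marginal model at bias SDs ``tau``.

    Constant terms not involving ``tau`` are dropped; the fixed effects
    are profiled out by GLS on the constraint-eliminated design.
    """
    tau = np.asarray(tau, dtype=float)
    y, se2, present = table.y, table.se2, table.present
    A, S = table.n_areas, table.n_sources
    V = se2 + (tau ** 2)[None, :]
    w = np.where(present, 1.0 / V, 0.0)
    rows = np.flatnonzero(present.ravel())
    ii, jj = np.divmod(rows, S)
    k = (A - 1) + S
    X = np.zeros((len(rows), k))
    for r in range(len(rows)):
        i = ii[r]
        if i < A - 1:
            X[r, i] = 1.0
        else:
            X[r, :A - 1] = -1.0
        X[r, A - 1 + jj[r]] = 1.0
    wv = w[ii, jj]
    yv = y[ii, jj] - anchor
    XtWX = X.T @ (X * wv[:, None])
    XtWy = X.T @ (wv * yv)
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError as exc:
        raise SingularDesignError("singular design in REML evaluation") from exc
    resid = yv - X @ beta
    sign, logdet_xx = np.linalg.slogdet(XtWX)
    if sign <= 0:
        raise SingularDesignError("singular design in REML evaluation")
    logdet_v = np.log(V[ii, jj]).sum()
    quad = (wv * resid ** 2).sum()
    return -0.5 * (logdet_v + logdet_xx + quad)


def fit_mixed_model(table: EstimateTable, anchor=23.0) -> ClassicalFit:
    """REML fit of the mixed model with known within-cell variances.

    Maximizes :func:`reml_criterion` over ``tau_j >= 0`` (multi-start
    L-BFGS-B), then solves the GLS problem at the optimum for point
    estimates and SEs under the same anchor identification.
    """
    validate_table(table).raise_for_errors()
    S = table.n_sources
    trace = []

    def neg(tau):
        val = -reml_criterion(table, tau, anchor)
        trace.append((tau.copy(), -val))
        return val

    best = None
    for start in (np.full(S, 0.5), np.full(S, 1.5)):
        res = optimize.minimize(
            neg, start, method="L-BFGS-B",
            bounds=[(0.0, 50.0)] * S,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
        )
        if best is None or res.fun < best.fun:
            best = res
    if not best.success and "ABNORMAL" in str(best.message):
        raise RuntimeError(
            f"REML optimizer failed: {best.message}; trace length {len(trace)}")
    tau = np.abs(best.x)
    tau2 = tau ** 2
    w = np.where(table.present, 1.0 / (table.se2 + tau2[None, :]), 0.0)
    theta, mu, theta_se, mu_se = _constrained_wls(
        table.y, w, table.present, anchor)
    d = np.where(table.present, table.y - theta[:, None], np.nan)
    return ClassicalFit(
        theta_hat=theta, theta_se=theta_se, mu_hat=mu, mu_se=mu_se,
        tau2_hat=tau2, d=d, n_iterations=int(best.nit),
        converged=bool(best.success), mse_factor=1.0,
        method="reml_mixed", anchor=anchor,
        area_labels=list(table.area_labels),
        source_labels=list(table.source_labels), weights=w,
        criterion_trace=trace,
    )


class IterativeAnova(BaseEstimator):
    """Estimator wrapper around :func:`iterative_anova_fit`."""

    def __init__(self, anchor=23.0, tol=1e-8, max_iter=100, mse_floor_1=False):
        self.anchor = anchor
        self.tol = tol
        self.max_iter = max_iter
        self.mse_floor_1 = mse_floor_1

    def fit(self, X: EstimateTable, y=None):
        fit = iterative_anova_fit(X, self.anchor, self.tol, self.max_iter,
                                  self.mse_floor_1)
        self.result_ = fit
        self.theta_ = fit.theta_hat
        self.mu_ = fit.mu_hat
        self.tau2_ = fit.tau2_hat
        self.n_iter_ = fit.n_iterations
        self.converged_ = fit.converged
        return self


class MixedEffectsModel(BaseEstimator):
    """Estimator wrapper around :func:`fit_mixed_model` (REML)."""

    def __init__(self, anchor=23.0):
        self.anchor = anchor

    def fit(self, X: EstimateTable, y=None):
        fit = fit_mixed_model(X, self.anchor)
        self.result_ = fit
        self.theta_ = fit.theta_hat
        self.mu_ = fit.mu_hat
        self.tau2_ = fit.tau2_hat
        self.converged_ = fit.converged
        return self
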
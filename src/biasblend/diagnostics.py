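"""Pooling weights, bias-adjusted estimates, residuals, model comparison.

These operations apply to any fit that yields per-source bias means and
SDs: with Bayesian fits the posterior means are plugged in (and weight
uncertainty can be propagated per draw); with classical fits the point
estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .table import EstimateTable, validate_table


@dataclass
class WeightTable:
    """Per-cell pooling weights and their per-source averages."""

    w: np.ndarray
    w_bar: np.ndarray
    area_labels: list
    source_labels: list


@dataclass
class ResidualReport:
    """Standardized residuals of an additive fit and their sum of squares.

    ``ssr`` is compared with a chi-square on ``df`` (= number of present
    cells) degrees of freedom.  The reference is approximate: residuals
    are not independent after fitting, so ``compatible`` is a qualitative
    flag, not a test.
    """

    r: np.ndarray
    ssr: float
    df: int
    reference: str
    compatible: bool


def pooling_weights(se, tau, present=None, area_labels=None,
                    source_labels=None) -> WeightTable:
    """Inverse-marginal-variance pooling weights.

    ``w_ij = (sigma_ij^2 + tau_j^2)^-1 / sum_k (sigma_ik^2 + tau_k^2)^-1``
    over the present cells of each area; ``w_bar_j`` averages over areas.
    """
    se = np.atleast_2d(np.asarray(se, dtype=float))
    tau = np.asarray(tau, dtype=float)
    A, S = se.shape
    if present is None:
        present = np.ones((A, S), dtype=bool)
    if np.any(se[present] <= 0):
        raise ValueError("sampling SDs must be positive")
    if np.any(tau < 0):
        raise ValueError("bias SDs must be non-negative")
    inv = np.where(present, 1.0 / (se ** 2 + (tau ** 2)[None, :]), 0.0)
    row = inv.sum(axis=1)
    if np.any(row <= 0):
        bad = np.flatnonzero(row <= 0)
        raise ValueError(f"area(s) {bad.tolist()} have no present cells")
    w = inv / row[:, None]
    w_bar = np.array([
        w[present[:, j], j].mean() if present[:, j].any() else np.nan
        for j in range(S)
    ])
    return WeightTable(
        w=w, w_bar=w_bar,
        area_labels=area_labels or [f"area{i}" for i in range(A)],
        source_labels=source_labels or [f"src{j}" for j in range(S)],
    )


def pooling_weights_from_posterior(table: EstimateTable, posterior,
                                   qs=(0.025, 0.975)) -> pd.DataFrame:
    """Posterior summaries of the per-source average pooling weights.

    Evaluates the weights per retained draw of the bias SDs and
    summarizes the across-area averages, giving credible intervals for
    each source's share of the pooled analysis.
    """
    tau_draws = posterior.draws["tau"]
    flat = tau_draws.reshape(-1, tau_draws.shape[-1])
    wbars = np.empty((flat.shape[0], table.n_sources))
    inv_base = table.se2
    for s in range(flat.shape[0]):
        inv = np.where(table.present,
                       1.0 / (inv_base + (flat[s] ** 2)[None, :]), 0.0)
        w = inv / inv.sum(axis=1)[:, None]
        wbars[s] = [
            w[table.present[:, j], j].mean() for j in range(table.n_sources)
        ]
    return pd.DataFrame({
        "source": table.source_labels,
        "w_bar_mean": wbars.mean(axis=0),
        "w_bar_q2.5": np.quantile(wbars, qs[0], axis=0),
        "w_bar_q97.5": np.quantile(wbars, qs[1], axis=0),
    })


def bias_adjusted_estimates(table: EstimateTable, mu_hat,
                            tau_hat) -> EstimateTable:
    """Shift each source's estimates by its mean bias, widen the SEs.

    Adjusted point = ``y_ij - mu_hat_j``; adjusted SE =
    ``sqrt(sigma_ij^2 + tau_hat_j^2)``.  The returned table is flagged
    ``adjusted``.
    """
    mu_hat = np.asarray(mu_hat, dtype=float)
    tau_hat = np.asarray(tau_hat, dtype=float)
    if mu_hat.shape != (table.n_sources,) or tau_hat.shape != (table.n_sources,):
        raise ValueError("need one mu_hat and tau_hat per source")
    out = table.copy()
    out.y = table.y - mu_hat[None, :]
    out.se = np.sqrt(table.se2 + (tau_hat ** 2)[None, :])
    out.adjusted = True
    return out


def standardized_residuals(table: EstimateTable, theta_hat, mu_hat,
                           tau_hat) -> ResidualReport:
    """Residuals ``(y - theta - mu) / sqrt(sigma^2 + tau^2)`` and their SSR.

    The sum of squares is referred to a chi-square with one degree of
    freedom per present cell; for Bayesian fits evaluated at posterior
    means this point-based SSR runs below the cell count by roughly the
    number of fitted location parameters (the per-draw posterior SSR,
    recorded on the fit itself, is the calibrated quantity).
    """
    theta_hat = np.asarray(theta_hat, dtype=float)
    mu_hat = np.asarray(mu_hat, dtype=float)
    tau_hat = np.asarray(tau_hat, dtype=float)
    resid = table.y - theta_hat[:, None] - mu_hat[None, :]
    denom = np.sqrt(table.se2 + (tau_hat ** 2)[None, :])
    r = np.where(table.present, resid / denom, np.nan)
    ssr = float(np.nansum(np.where(table.present, r ** 2, 0.0)))
    df = int(table.present.sum())
    lo, hi = stats.chi2.ppf([0.025, 0.975], df)
    compatible = bool(lo <= ssr <= hi)
    ref = (f"chi-square on {df} df (mean {df}, central 95% "
           f"[{lo:.1f}, {hi:.1f}]): "
           + ("compatible" if compatible else "incompatible"))
    return ResidualReport(r=r, ssr=ssr, df=df, reference=ref,
                          compatible=compatible)


def compare_models(fits) -> pd.DataFrame:
    """DIC comparison table for fits of the same table and focus.

    Differences of at most about 2 are flagged as not distinguishable.
    """
    if len(fits) < 1:
        raise ValueError("nothing to compare")
    fps = {f.table_fingerprint for f in fits}
    if len(fps) != 1:
        raise ValueError("fits come from different tables; DIC not comparable")
    rows = []
    best = min(f.dic["DIC"] for f in fits)
    for f in fits:
        delta = f.dic["DIC"] - best
        rows.append({
            "model": f.model,
            "Dbar": f.dic["Dbar"],
            "pD": f.dic["pD"],
            "DIC": f.dic["DIC"],
            "delta_DIC": delta,
            "verdict": "not distinguishable" if delta <= 2.0 else "worse",
        })
    df = pd.DataFrame(rows).sort_values("DIC").reset_index(drop=True)
    if (df["delta_DIC"] > 2.0).any():
        df.loc[0, "verdict"] = "preferred"
    else:
        df.loc[0, "verdict"] = "not distinguishable"
    return df
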
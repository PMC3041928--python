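"""Synthetic multi-source prevalence data with known truth.

The generator inverts the additive-bias measurement model: true area
prevalences theta_i are drawn around a regional anchor and recentred so
their mean equals the anchor exactly; each source j contributes an
additive bias delta_ij with source-specific mean mu_j and SD tau_j
(optionally correlated across sources within an area); and the observed
estimate adds known sampling noise with SD sigma_ij.

Default settings emulate the structure of the motivating application:
48 local authorities, seven sources (three commercial yearly waves, one
tobacco-expenditure-derived source, one ward-level synthetic-estimation
source and two health-survey synthetic-estimation waves), a regional
anchor of 23% and per-source nominal sample sizes under which the
commercial sources look more precise than the health-survey ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .table import EstimateTable, validate_table

DEFAULT_SOURCE_LABELS = ("ASH02", "Acx03", "Acx04", "Acx05", "CACI05", "HP02", "HP05")
DEFAULT_SOURCE_YEARS = (2001, 2003, 2004, 2005, 2005, 2001, 2004)
#: per-source mean biases (percentage points): the ward-level synthetic
#: source overestimates, the commercial waves underestimate, the
#: health-survey waves are nearly unbiased.
DEFAULT_MU = (2.5, -2.5, -2.0, -1.5, 0.5, 0.0, 0.3)
#: per-source bias SDs (percentage points), spanning the 0.5-2 range.
DEFAULT_TAU = (1.2, 1.0, 1.5, 0.8, 0.6, 0.9, 1.1)
#: nominal sample sizes: commercial sources have seemingly larger samples
#: and therefore smaller stated SEs than the health-survey sources.
DEFAULT_SAMPLE_SIZES = (8000, 5000, 5000, 5000, 4000, 700, 700)


@dataclass
class SimConfig:
    """Generating parameters for a synthetic estimate table.

    Per-cell sampling SDs come either from per-source nominal sample
    sizes (``se = sqrt(p (100 - p) / n)`` with ``p = anchor``; the
    default) or uniformly from ``se_range``.
    """

    n_areas: int = 48
    n_sources: int = 7
    anchor: float = 23.0
    theta_sd: float = 3.0
    mu: tuple = None
    tau: tuple = None
    correlation: np.ndarray = None
    sample_sizes: tuple = None
    se_range: tuple = None
    source_labels: tuple = None
    source_years: tuple = None
    slope_mean: float = -0.08
    slope_sd: float = 0.14
    seed: int = 0

    def resolved(self):
        """Concrete arrays for every generating parameter."""
        S = self.n_sources
        if self.source_labels is not None:
            labels = tuple(str(s) for s in self.source_labels)
        elif S == len(DEFAULT_SOURCE_LABELS):
            labels = DEFAULT_SOURCE_LABELS
        else:
            labels = tuple(f"src{j + 1}" for j in range(S))
        if self.source_years is not None:
            years = np.asarray(self.source_years, dtype=int)
        elif S == len(DEFAULT_SOURCE_YEARS):
            years = np.asarray(DEFAULT_SOURCE_YEARS, dtype=int)
        else:
            years = None
        if self.mu is not None:
            mu = np.asarray(self.mu, dtype=float)
        elif S == len(DEFAULT_MU):
            mu = np.asarray(DEFAULT_MU, dtype=float)
        else:
            mu = np.linspace(-3.0, 3.0, S)
        if self.tau is not None:
            tau = np.asarray(self.tau, dtype=float)
        elif S == len(DEFAULT_TAU):
            tau = np.asarray(DEFAULT_TAU, dtype=float)
        else:
            tau = np.linspace(0.5, 2.0, S)
        if self.correlation is not None:
            corr = np.asarray(self.correlation, dtype=float)
        else:
            corr = np.eye(S)
        if self.sample_sizes is not None:
            sizes = np.asarray(self.sample_sizes, dtype=float)
        elif self.se_range is None and S == len(DEFAULT_SAMPLE_SIZES):
            sizes = np.asarray(DEFAULT_SAMPLE_SIZES, dtype=float)
        elif self.se_range is None:
            sizes = np.full(S, 2000.0)
        else:
            sizes = None
        self._check(mu, tau, corr)
        return labels, years, mu, tau, corr, sizes

    def _check(self, mu, tau, corr):
        S = self.n_sources
        if not (0.0 < self.anchor < 100.0):
            raise ValueError("anchor must lie strictly inside (0, 100)")
        if mu.shape != (S,) or tau.shape != (S,):
            raise ValueError("mu and tau must have one entry per source")
        if np.any(tau < 0):
            raise ValueError("tau entries must be non-negative")
        if corr.shape != (S, S):
            raise ValueError("correlation must be S x S")
        if not np.allclose(corr, corr.T, atol=1e-10):
            raise ValueError("correlation must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
            raise ValueError("correlation must have unit diagonal")
        w = np.linalg.eigvalsh(corr)
        if w.min() < -1e-8:
            raise ValueError("correlation matrix is not positive semi-definite")

    @classmethod
    def from_file(cls, path) -> "SimConfig":
        """Load a config from YAML or JSON mirroring the field names."""
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


@dataclass
class TruthRecord:
    """Latent generating quantities retained for recovery tests."""

    theta: np.ndarray
    mu: np.ndarray
    tau: np.ndarray
    correlation: np.ndarray
    deltas: np.ndarray
    alpha: np.ndarray = None
    beta: np.ndarray = None
    slope_mean: float = None
    slope_sd: float = None

    def to_json(self, path) -> None:
        out = {}
        for k, v in asdict(self).items():
            out[k] = v.tolist() if isinstance(v, np.ndarray) else v
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(out, fh, indent=1)


def _rng_streams(seed, n=5):
    """Independent per-component generators derived from one seed.

    Ordering: theta, biases, sampling SDs, observation noise, slopes.
    Component streams keep area-level draws unchanged when source-level
    settings change.
    """
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(c) for c in children]


def simulate_correlated_biases(mu, tau, correlation, n_areas, seed):
    """Draw an (A, S) bias matrix with rows i.i.d. MVN(mu, T C T).

    ``T = diag(tau)``.  Positive semi-definite correlation matrices are
    accepted (a symmetric square root is used), so perfectly correlated
    or zero-variance sources are handled exactly; an indefinite matrix
    raises ``ValueError``.  ``seed`` may be an int or a Generator.
    """
    mu = np.asarray(mu, dtype=float)
    tau = np.asarray(tau, dtype=float)
    corr = np.asarray(correlation, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau entries must be non-negative")
    w = np.linalg.eigvalsh(corr)
    if w.min() < -1e-8:
        raise ValueError("correlation matrix is not positive semi-definite")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cov = np.outer(tau, tau) * corr
    evals, evecs = np.linalg.eigh(cov)
    root = (evecs * np.sqrt(np.clip(evals, 0.0, None))) @ evecs.T
    z = rng.standard_normal((int(n_areas), len(mu)))
    return mu[None, :] + z @ root


def _draw_se(cfg: SimConfig, sizes, rng, A, S):
    if cfg.se_range is not None:
        lo, hi = cfg.se_range
        return rng.uniform(lo, hi, size=(A, S))
    p = cfg.anchor
    se_src = np.sqrt(p * (100.0 - p) / sizes)
    # burn a draw so switching se modes does not shift the noise stream
    rng.uniform(size=(A, S))
    return np.tile(se_src, (A, 1))


def simulate_dataset(config: SimConfig):
    """Generate a static (no-trend) dataset and its :class:`TruthRecord`.

    theta_i are drawn Normal(anchor, theta_sd^2) then recentred so their
    mean equals the anchor exactly, mirroring the hard identification
    constraint the models use; delta rows follow the configured bias
    distribution; y adds Normal sampling noise with the known SDs.
    """
    labels, years, mu, tau, corr, sizes = config.resolved()
    A, S = config.n_areas, config.n_sources
    r_theta, r_bias, r_se, r_noise, _ = _rng_streams(config.seed)
    theta = config.anchor + config.theta_sd * r_theta.standard_normal(A)
    theta += config.anchor - theta.mean()
    deltas = simulate_correlated_biases(mu, tau, corr, A, r_bias)
    se = _draw_se(config, sizes, r_se, A, S)
    y = theta[:, None] + deltas + se * r_noise.standard_normal((A, S))
    table = EstimateTable(
        [f"area{i + 1:02d}" for i in range(A)], list(labels), y, se,
        source_year=years,
    )
    validate_table(table).raise_for_errors()
    truth = TruthRecord(theta, mu, tau, corr, deltas)
    return table, truth


def simulate_time_trend_dataset(config: SimConfig):
    """Generate a dataset with area-specific linear time trends.

    Intercepts alpha_i (the level in 2005) are recentred to the anchor;
    slopes beta_i ~ Normal(slope_mean, slope_sd^2); the time covariate is
    x_j = 2005 - year_j, so y_ij ~ Normal(alpha_i + beta_i x_j +
    delta_ij, sigma_ij^2).
    """
    labels, years, mu, tau, corr, sizes = config.resolved()
    if years is None:
        raise ValueError("source_years required for time-trend generation")
    A, S = config.n_areas, config.n_sources
    r_theta, r_bias, r_se, r_noise, r_slope = _rng_streams(config.seed)
    alpha = config.anchor + config.theta_sd * r_theta.standard_normal(A)
    alpha += config.anchor - alpha.mean()
    beta = config.slope_mean + config.slope_sd * r_slope.standard_normal(A)
    x = 2005.0 - years.astype(float)
    xc = x - x.mean()
    ssx = (xc ** 2).sum()
    if ssx > 0:
        # express the bias means in the identified representation used by
        # the trend model: no linear-in-time component in the biases (any
        # such component is indistinguishable from a common area slope)
        mu = mu - ((mu - mu.mean()) * xc).sum() / ssx * x
    deltas = simulate_correlated_biases(mu, tau, corr, A, r_bias)
    se = _draw_se(config, sizes, r_se, A, S)
    x = 2005.0 - years.astype(float)
    y = (
        alpha[:, None]
        + beta[:, None] * x[None, :]
        + deltas
        + se * r_noise.standard_normal((A, S))
    )
    table = EstimateTable(
        [f"area{i + 1:02d}" for i in range(A)], list(labels), y, se,
        source_year=years,
    )
    validate_table(table).raise_for_errors()
    truth = TruthRecord(
        alpha, mu, tau, corr, deltas,
        alpha=alpha, beta=beta,
        slope_mean=config.slope_mean, slope_sd=config.slope_sd,
    )
    return table, truth
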
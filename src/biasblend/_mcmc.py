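"""Shared MCMC primitives: slice sampling, conjugate truncated draws,
precision-form Gaussian draws.

These are deliberately simple, dependency-free building blocks; the model
structure itself lives in :mod:`biasblend.bayes`.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg, stats


def slice_sample(x0, logf, lower, upper, rng, width=0.25, max_expand=200):
    """One univariate slice-sampling update (stepping out + shrinkage).

    Parameters
    ----------
    x0 : float
        Current value, must satisfy ``lower < x0 < upper`` and have
        finite log density.
    logf : callable
        Log density up to a constant.
    lower, upper : float
        Hard support bounds.
    """
    fx = logf(x0)
    if not np.isfinite(fx):
        raise ValueError("slice_sample requires a finite log density at x0")
    logu = fx + np.log(rng.random())
    left = x0 - width * rng.random()
    right = left + width
    n = 0
    while left > lower and logf(left) > logu and n < max_expand:
        left -= width
        n += 1
    while right < upper and logf(right) > logu and n < max_expand:
        right += width
        n += 1
    left = max(left, lower)
    right = min(right, upper)
    while True:
        x1 = rng.uniform(left, right)
        if logf(x1) >= logu:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1


def sample_trunc_invgamma(shape, rate, v_upper, rng):
    """Draw v ~ InverseGamma(shape, rate) restricted to (0, v_upper].

    Used for conditional posteriors of variance parameters whose SD has a
    bounded-uniform prior.  Uses the inverse-CDF of the Gamma draw of 1/v.
    """
    rate = max(float(rate), 1e-300)
    gdist = stats.gamma(a=shape, scale=1.0 / rate)
    u_min = 1.0 / v_upper
    f_lo = gdist.cdf(u_min)
    if f_lo > 1.0 - 1e-12:
        # essentially all conditional mass sits above the truncation point
        return float(v_upper)
    u = gdist.ppf(rng.uniform(f_lo, 1.0))
    return float(1.0 / max(u, u_min))


def draw_mvn_precision(P, b, rng):
    """Draw from N(P^{-1} b, P^{-1}) given precision matrix P.

    Returns ``(draw, mean)``.
    """
    L = np.linalg.cholesky(P)
    m = linalg.cho_solve((L, True), b)
    z = rng.standard_normal(len(b))
    draw = m + linalg.solve_triangular(L.T, z, lower=False)
    return draw, m
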
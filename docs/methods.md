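# Methods

## The problem

Several survey providers publish prevalence estimates (say, of smoking)
for the same set of small areas — UK local authorities in the motivating
application — as aggregate point estimates with 95% confidence
intervals.  The sources differ in survey year, sample size and, above
all, in unknown methodology-driven bias: commercial consumer surveys and
model-based ("synthetic") estimates can be shifted and over- or
under-dispersed relative to the truth.  Individual-level records are not
available, so the only usable data are the published (area, source)
estimates.  `biasblend` pools them while *modelling* each source's bias
instead of discarding suspect sources.

## Measurement model

For area `i = 1..A` and source `j = 1..S`,

    y_ij     ~ Normal(theta_i + delta_ij, sigma_ij^2)
    delta_ij ~ Normal(mu_j, tau_j^2)

* `y_ij` — published prevalence estimate, in percent;
* `sigma_ij` — its sampling SD, treated as known, recovered from the
  published interval as width / 3.92;
* `theta_i` — the true area prevalence;
* `delta_ij` — the total additive bias of source j in area i, assumed
  exchangeable across areas within a source, with mean bias `mu_j` and
  bias SD `tau_j`.

Adding a constant to every `theta_i` and subtracting it from every
`mu_j` leaves the likelihood unchanged, so the level is pinned by an
external **anchor**: a regional mean prevalence `a` (23% in the
motivating data, from a large national survey) imposed as
`mean(theta) = a`.  Identification is applied per retained MCMC draw by
shifting (`theta -= phi`, `mu += phi`, `delta += phi` with
`phi = mean(theta) - a`), which preserves every fitted cell mean — the
redundant-parameterization device.  An *uncertain* anchor
(`a ~ Normal(23, 1.1^2)`) is available via `PriorConfig.anchor_sd`;
because the likelihood is invariant in the shift direction this is
implemented exactly by recentring each draw to an anchor value drawn
from that prior.  It is off by default.

Priors are vague and explicit: `mu_j ~ Normal(0, 100^2)`,
`tau_j ~ Uniform(0, 100)`, area levels flat during sampling.  Variants:

* **anchored source** — identification through one source declared
  mean-unbiased (`mu_j* = 0`) with `theta_i ~ Uniform(0, 100)` and no
  regional anchor;
* **exchangeable bias SDs** — `tau_j ~ HalfNormal(sigma_tau)`,
  `sigma_tau ~ Uniform(0, 100)`, borrowing strength across sources;
* **equal bias SDs** — a single shared `tau`.

### Correlated biases

Sources built from the same underlying survey or methodology are not
independent witnesses.  The correlated model makes the bias vector of
each area multivariate normal, `delta_i. ~ MVN(mu, Sigma)`, with a
scaled inverse-Wishart prior `Sigma = diag(xi) Q diag(xi)`,
`Q ~ InvWishart(S + 1, I)`, `xi_j ~ LogNormal(0, 1)`.  Reported
correlations are `rho_kj = Sigma_kj / sqrt(Sigma_kk Sigma_jj)`.

**Identification caveat.**  Because the area levels are free fixed
effects, profiling them removes the within-area mean direction from the
likelihood: `Sigma` and `Sigma + c 11'` fit the data identically (all
covariances, including the `tau_j^2` diagonal, can shift together by a
common `c`).  The common level of the correlations is therefore
prior-identified, and correlation intervals are intrinsically wide —
detection of a correlated pair rests on its covariance being elevated
*relative* to the other pairs.  In practice a pair is detectable at
`A = 48` areas when its bias SDs are large relative to its stated
sampling SDs (exactly the "overprecise" sources for which correlation
is suspected in the first place); a 0.9 correlation between two sources
with bias SDs around 0.6 of a percentage point is genuinely not
resolvable at this size.

### Time trends

With per-source mid-survey years, each area gets a linear trajectory:

    y_ij ~ Normal(alpha_i + beta_i x_j + delta_ij, sigma_ij^2),
    x_j = 2005 - year_j,    beta_i ~ Normal(mu_beta, sigma_beta^2)

with fixed intercepts `alpha_i` (the level in the reference year 2005,
anchored as above) and exchangeable random slopes.  Note the covariate
convention: `x` counts years *before* 2005, so the calendar-time slope
is `-beta_i`; a reported mean slope `mu_beta = -0.08` means prevalence
*rising* by 0.08 per calendar year under this convention.  The two are
easy to conflate and the sign should always be checked against a
plotted trajectory.

A second identification step is needed here: because `x` is constant
within a source, a common slope shift can be traded against the source
bias means (`beta_i + c`, `mu_j - c x_j`).  The identified
representation attributes **no linear-in-year component to the
biases**: per draw, the least-squares slope of `mu_j` on `x_j` is moved
into the slopes and their mean.  The synthetic generator emits its
truth in the same representation, so recovery tests compare like with
like.  Forecasts for year `Y` evaluate `alpha_i + beta_i (2005 - Y)`
per draw; under the convention above this is the latent trend with all
time structure attributed to true prevalence.  Predictive league tables
report per-area means, central 95% intervals and the full rank
distribution.

## Sampling

No probabilistic-programming engine is used; the models are sampled by
blocked Gibbs schemes written against the marginal (bias-integrated)
form of each model:

1. **Locations** `(theta, mu)` — or `(alpha, beta, mu, mu_beta)` for the
   trend model — are drawn *exactly* from their joint Gaussian
   conditional given the variance parameters (a precision-form Cholesky
   draw; the two-way layout makes the normal equations cheap to
   assemble).
2. **Bias SDs** `tau_j` move by univariate slice sampling on the
   marginal likelihood; hyper-variances (`sigma_tau`, `sigma_beta`) have
   exact truncated-inverse-gamma conditionals.
3. **Biases** `delta_ij` are imputed from their Gaussian conditional for
   retained draws only (they are needed for reporting and DIC, not for
   mixing).
4. For the correlated model, the scale factors `xi_j` are slice-sampled
   against the bias-marginal likelihood (this carries the overall
   covariance scale, the direction plain data augmentation moves
   slowest), and the inverse-Wishart base `Q` takes several
   bias-imputation/conjugate-update sub-sweeps per iteration.

Because step 1 is an exact joint draw, the sampler has no random-walk
behaviour in the high-dimensional location block, and far shorter
chains suffice than the 10⁴–10⁵-iteration burn-ins that
general-purpose Gibbs samplers historically needed on these models.
Defaults are 2 chains × 3000 iterations (750 burn-in), which brings
every parameter's Monte Carlo SE under 3% of its posterior SD at the
study size (48 × 7); tests use shorter chains and rely on the honest
convergence flag.  Convergence is reported per parameter (split R-hat
and MCSE via ArviZ); exceeding the thresholds (R-hat 1.05, MCSE 3% of
SD) produces a *flagged* result and a `ConvergenceWarning`, never a
silent success.  A fully hierarchical conjugate Gibbs backend
(`sampler="hierarchical"`) exists as an internal cross-check that the
marginal and hierarchical forms of the model agree; an ensemble-sampler
cross-check runs in the test suite.

Chain seeds derive from a single `McmcConfig.seed` via
`numpy.random.SeedSequence` spawning.

## Model assessment

* **DIC** at the cell-mean focus (`theta_i + delta_ij`, plus trend
  terms): `Dbar + pD` with `pD = Dbar - D(posterior-mean cell means)`.
  Comparable only across models with the same focus on the same table
  (enforced via a table fingerprint); differences under about 2 are
  flagged indistinguishable.
* **Standardized residuals** `(y - theta - mu)/sqrt(sigma^2 + tau^2)`
  and their sum of squares (SSR), referred to a chi-square with one
  degree of freedom per cell.  Two flavours exist and differ
  systematically: the *per-draw posterior mean* SSR (recorded on every
  Bayesian fit) is the calibrated quantity — for a well-specified
  linear-Gaussian model its expectation equals the cell count, because
  the reduction from fitting location parameters is exactly offset by
  their posterior variability.  SSR evaluated at point estimates (the
  generic `standardized_residuals` report, the only option for
  classical fits) runs below the cell count by roughly the number of
  fitted location parameters and is reported with that caveat.
* **Pooling weights** `w_ij ∝ 1/(sigma_ij^2 + tau_j^2)`, normalized
  within area, with per-source across-area averages; with Bayesian fits
  the weights are evaluated per retained draw and summarized with
  credible intervals.
* **Bias-adjusted estimates** `y_ij - mu_hat_j` with SE
  `sqrt(sigma_ij^2 + tau_hat_j^2)` expose the half-way stage between
  raw estimates and the pooled answer.

## Classical counterpart

The marginal model `y_ij ~ Normal(theta_i + mu_j, sigma_ij^2 + tau_j^2)`
is also fitted two classical ways:

* **Iterative weighted ANOVA** — alternate (a) a constrained weighted
  two-way fit with weights `1/(sigma^2 + tau^2)` (the anchor constraint
  is eliminated exactly by reparameterization, equivalent to the shift
  identification) and (b) a DerSimonian–Laird moment estimate of each
  `tau_j^2` from the per-source deviations `d_ij = y_ij - theta_hat_i`
  with variances `sigma_ij^2`, starting from `tau^2 = 0`; finally the
  SEs are multiplied by the root weighted MSE on
  `N - A - S + 1` degrees of freedom.  Convergence is declared when
  `max |change in tau^2| < 1e-8`.  The alternation is linearly
  convergent with data-dependent rate (observed 0.4–0.9), so a depth-1
  Anderson mixing step is applied by default — it roughly halves the
  sweep count (typically 12–30 at the default tolerance) and provably
  leaves the fixed point unchanged; estimates stabilize to well under
  0.01 percentage points within about ten sweeps.
* **REML mixed model** — direct maximization of the restricted
  likelihood over `tau_j >= 0` (multistart L-BFGS-B) with GLS for the
  fixed effects, the within-cell variances fixed and known.

Known limitations of the classical route: the DL step's uncertainty in
`tau_hat^2` is ignored (SEs come from the constrained-GLS covariance at
the converged weights), and the `tau^2 = 0` start can self-trap when
one source's stated SEs are far smaller than everyone else's — that
source then dominates the first weighted fit, its own deviations
collapse, and the moment estimator keeps returning zero for it, a
self-consistent but degenerate fixed point.  The REML fit (multistart)
and the Bayesian models do not share this failure mode; when the two
classical fits disagree noticeably, trust the REML/Bayesian answer.
The correlated-bias structure is not offered classically.

## Synthetic data

The generator inverts the measurement model with known truth, defaulting
to the study geometry: 48 areas, 7 sources, anchor 23%, between-area SD
3 percentage points (a fixture choice — the real between-area spread is
not published), per-source mean biases `(2.5, -2.5, -2.0, -1.5, 0.5,
0.0, 0.3)` and bias SDs `(1.2, 1.0, 1.5, 0.8, 0.6, 0.9, 1.1)` emulating
a ward-level synthetic source that overestimates, commercial waves that
underestimate, and nearly unbiased health-survey waves.  Sampling SDs
default to `sqrt(p(100-p)/n_j)` at `p = anchor` with nominal sample
sizes `(8000, 5000, 5000, 5000, 4000, 700, 700)` — the commercial
sources look more precise than the health-survey ones, as in the real
data.  True area levels are recentred so their mean equals the anchor
*exactly*, and trend truth is emitted in the identified (no bias-trend)
representation, making anchor- and slope-recovery tests sharp.  Trend
defaults: mean slope −0.08 per unit `x`, slope SD 0.14, survey years
2001–2005.  A single seed drives separate per-component substreams, so
changing source-level settings does not perturb the area-level draws.

What the generator does *not* emulate: binomial sampling error near the
0/100 boundaries (noise is Gaussian with known SD, as the model
assumes), non-normal or proportional (multiplicative) biases,
spatially correlated area effects, and misreported sampling SDs (tests
probe that robustness by editing the stated SEs directly).  Passing
recovery tests therefore certify the estimation machinery under the
model's own assumptions, not the assumptions themselves.

## Numerical notes

* Degenerate CI widths raise; asymmetric intervals (beyond 0.1 pp) are
  flagged but converted with the same width/3.92 rule.
* A source with fewer than two present cells is a validation *error*
  (its bias variance is unidentifiable); a disconnected area/source
  incidence graph raises `SingularDesignError`.
* Truncated inverse-gamma draws use the inverse-CDF of the Gamma draw of
  the reciprocal; when the conditional mass above the truncation point
  underflows, the bound is returned.
* The DL estimator is truncated at zero; its translation invariance and
  `c^2` homogeneity (under joint rescaling of deviations and variances)
  are property-tested.
* All-equal survey years make the trend slopes unidentifiable: rejected
  by default, permitted with `allow_degenerate_years=True` for the
  reduction-to-static check (the slope posterior is then its prior).
* Problem sizes in the test and acceptance runs (48 × 7 tables; 5–20
  replicates; 2 chains of 1200–2500 iterations) were chosen so each
  recovery check has Monte Carlo error comfortably below the property
  being asserted while the whole suite stays quick to run.
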
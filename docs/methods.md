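# Methods

## The models

`carmap` fits Poisson log-linear relative-risk models to areal count panels
(counts `O_it` for areas `i = 1..n` and periods `t = 1..T`, with expected
counts `E_it` from internal standardization):

    O_it ~ Poisson(E_it * exp(eta_it))

Three nested structures for the log relative risk `eta` are provided.

**Pure spatial (BYM convolution).** One period;
`eta_i = mu + phi_i + theta_i`, with `theta_i ~ N(0, sigma_theta^2)` iid
(unstructured heterogeneity) and `phi` an intrinsic conditional
autoregressive (ICAR) field: conditionally,

    phi_i | phi_{-i} ~ N( mean of neighbours' phi, sigma_phi^2 / n_i ),

`n_i` the neighbour count.  The implied joint density is the improper
pairwise-difference form `exp(-sum_{i~j}(phi_i - phi_j)^2 / (2 sigma_phi^2))`,
flat along constant shifts; identifiability is restored by a sum-to-zero
constraint on `phi` so that `mu` carries the overall level.

**Autoregressive spatio-temporal.** Every period gets its own pair of
fields, a temporal trend `alpha_t` (first-order random walk with standard
deviation `sigma_alpha`, constrained to sum to zero), and the spatio-temporal
residual is coupled across periods through an autoregression with
correlation `rho`:

    eta_i1 = mu + alpha_1 + (1 - rho^2)^(-1/2) (phi_i1 + theta_i1)
    eta_it = mu + alpha_t + rho (eta_i(t-1) - mu - alpha_(t-1)) + phi_it + theta_it

The `(1 - rho^2)^(-1/2)` first-period scaling makes the residual field
time-stationary: its prior variance is constant in `t` (verified by Monte
Carlo in the test suite).

**Quarterly seasonal.** As above at trimester resolution with fixed seasonal
effects `beta_q(t)`, `q(t) = ((t-1) mod 4) + 1`, coded against a reference
cell: `beta_4 = 0` and `beta_1..beta_3` free (corner-point coding, so each
`beta_q` is a log rate ratio against the fourth trimester).  A simplified
variant pins `rho = 0`; comparing the two by DIC quantifies what the
space-time interaction buys.

*A deliberate structural choice:* in the seasonal recursion the
autoregression acts on the residual after removing the **full** fixed part
`mu + alpha_(t-1) + beta_q(t-1)`.  The alternative — propagating the
seasonal offset through `rho` — would make the effective seasonal amplitude
a geometric mixture `beta_q + rho beta_(q-1) + ...`, entangling `beta` with
`rho`; removing the full fixed part keeps `beta_q` interpretable as the
period-`q` log rate ratio.  The simulator and the sampler use the same
recursion, so this choice is internally consistent throughout.

**Priors.** `mu` improper flat; `rho ~ U(-1, 1)`;
`sigma_alpha, sigma_phi, sigma_theta ~ U(0, 1)` on the standard-deviation
scale; `beta_k ~ N(0, 10,000)`.  The uniform-on-(0,1) sigma priors are part
of the model family being implemented, appropriate for relative-risk scales
where log-risks beyond +-2 are implausible; they are not a general-purpose
recommendation.

## Expected counts and descriptives

Internal standardization: `E_i = pop_i * total events / total population`,
divided evenly over periods (`global` mode, the default), or per-period
(`per_period` mode) where each period's `E` column is standardized against
that period's own total.  Populations are published once for the whole study
span, so per-period departures from a constant expectation are left to
`alpha_t`; both modes satisfy `sum(E) = sum(O)` exactly.  The standardized
ratio `O/E` (SMR) and the count descriptives (totals, extremes, means,
zero-cell fraction) reproduce the arithmetic of the motivating study's
summary table.

## Sampler

A single-site adaptive random-walk Metropolis-within-Gibbs engine
(`carmap.mcmc`), default protocol 3 chains x 50,000 iterations with 10,000
burn-in; the desk-scale configuration used in all shipped experiments is
3 x 5,000 with 1,000 burn-in.

- `rho` is updated on the `atanh` scale and the sigmas on the logit of
  their (0, 1) support, with exact Jacobian terms, so no stored draw can
  violate the prior support.
- `theta` updates are proposed for all areas of a period simultaneously
  (conditionally independent given `phi`); `phi` updates are vectorised
  over colour classes of a proper vertex colouring, within which areas are
  non-adjacent and hence conditionally independent under the ICAR prior.
- A proposal at period `t` perturbs `eta` at all later periods with
  geometric weights `rho^(s-t)`; likelihood deltas are computed over that
  tail, truncated where the weight underflows (1e-12).
- Proposal scales adapt per site during burn-in toward 0.44 acceptance
  (Robbins-Monro with decay exponent 0.6) and are frozen afterwards.
- The sigma full conditionals use the proper rank terms:
  `sigma_phi^(-T(n-1))` for the constrained ICAR on a connected graph,
  `sigma_theta^(-nT)`, `sigma_alpha^(-(T-1))` for the constrained RW1.
- Constraints: `alpha` is re-centred every sweep with its mean transferred
  to `mu` (an exact invariant move in every variant).  `phi` columns are
  re-centred every sweep; in the pure spatial variant the discarded mean is
  likewise absorbed into `mu` exactly, while in the spatio-temporal
  variants the re-centring is applied plainly — the long-standing
  WinBUGS/GeoBUGS convention for sum-to-zero ICAR constraints, whose
  per-sweep perturbation is O(sigma_phi / sqrt(n)) and is not detectable in
  the conjugate and recovery oracles at the scales tested.
- The deviance trace stores the full `-2 log p(O | eta)` (factorial
  constants included) every iteration; the likelihood used for sampling
  drops constants.

A `prior_only` switch disables the likelihood entirely; sampling the prior
this way reproduces the U(0,1) sigma moments and the U(-1,1) rho moments,
a whole-engine validity check included in the test suite.

Degenerate fits with `sigma_phi = sigma_theta = 0` pinned reduce to a
fixed-effects Poisson model whose posterior of `exp(mu)` is
`Gamma(sum O, rate sum E)` in closed form — the sharpest available oracle
for the sampler, asserted to Monte-Carlo tolerance.

## Diagnostics

Classic (non-split, non-rank-normalised) Brooks-Gelman-Rubin potential
scale reduction factor, matching the diagnostic generation of the original
analysis; a `split=True` flag gives the modern split variant.  Effective
sample size uses FFT autocorrelations with Geyer initial-positive-sequence
truncation, floored at 1 (constant chains return the floor with a warning);
for AR(1) chains it reproduces `n(1-r)/(1+r)` within 10%.

## DIC

`DIC = mean deviance + p_D` with `p_D = mean deviance - deviance at the
posterior mean of eta` — the deviance focus at the latent level, the
convention under which WinBUGS-era disease-mapping DICs were reported.  With
only fixed effects, `p_D` approaches the free parameter count; on data
simulated with strong autocorrelation (`rho = 0.903`) the autoregressive
quarterly model beats its `rho = 0` simplification consistently across
replicates.

## Trend classification

The per-area trajectory classes (increasing / decreasing / persistently
high / none) are not given a rule in the source analysis; the rule here is:
with block-level RR defined as the posterior draw's mean RR over a period
block (default: first year vs last year), an area is *increasing* if
P(RR_last > RR_first) >= 0.9, *decreasing* if P(RR_last < RR_first) >= 0.9,
*persistently high* if P(RR > 1) >= 0.9 in every block, else unclassified.
Ties count toward neither direction.  The 0.9 threshold and year blocks are
defaults, both exposed as arguments.

## Synthetic-data generator

The generator emulates the published shape of the motivating panel
(suicide-related emergency calls per Valencia census block group,
2010-2016), which is confidential:

- 552 areas (a 24 x 23 rook lattice stands in for the city's adjacency,
  which is unpublished; any externally supplied GAL file can be used
  instead — the package never infers contiguity from geometry);
- populations in [630, 2845]: plain uniform via `gen_populations`, or a
  two-component uniform mixture `w U[630, 1334] + (1-w) U[1334, 2845]` with
  `w` solved so the mean equals the published 1334 (the `valencia` presets);
- expected counts `E_it = pop_i * (6537 / 736,580) / T` — the published
  event total and city population, split evenly over periods;
- generative parameters defaulting to the posterior point estimates
  published for each model variant, so recovery experiments test the
  estimator at the study's own operating point;
- the `desk` presets scale the lattice to 15 x 15 (225 areas) with the same
  per-person rate, the problem size used by the shipped recovery
  experiments and chosen so a full 3-chain desk fit completes in minutes.

The quarterly `valencia` preset reproduces the high zero-cell fraction of
the real panel (about 0.69 against the published "up to 70.4%"; the test
suite guards a loose 50-85% band).

What the generator does **not** emulate: the real city's geometry and
adjacency, geocoding error, within-quarter timing, covariate-driven risk
(deprivation, demography), and any departure of the true call process from
the Poisson/BYM family.  Passing recovery tests therefore demonstrates that
the estimator recovers the data-generating process *of this model family*
at realistic scales — not that the family is adequate for any particular
real dataset.

## Numerical choices and degenerate inputs

- Disconnected graphs and zero-neighbour areas are rejected outright;
  islands silently change the ICAR model, so they are an error, not a
  repair.  GAL asymmetry is an error under `strict=True` (default) and is
  symmetrised otherwise.
- ICAR sampling is exact, via the eigenbasis of the graph Laplacian
  restricted to its non-null space (cached per graph).
- Out-of-support parameter states give `log_posterior = -inf` rather than
  raising, so samplers can reject uniformly.
- States with a sigma pinned to 0 drop the corresponding field and its
  prior block entirely.
- A non-finite deviance aborts the run naming chain and iteration.
- Latent-field draws are thinned automatically to at most ~500 stored
  field draws per chain to bound memory; scalar draws are kept at full
  resolution.

## Known limitations

- The plain per-sweep re-centring of `phi` in the spatio-temporal variants
  is the standard approximation, not an exact MCMC move (see above).
- Single-site random-walk updates mix slowly for strongly coupled blocks
  (notably `sigma_phi` with its field under the centred parametrisation);
  the desk protocol is calibrated for the shipped experiments, and longer
  chains are advisable for weakly informed fields.
- `sigma_phi` and `sigma_theta` are weakly separated in BYM-type models at
  small expected counts; recovery experiments show this as upward bias in
  `sigma_phi` at desk scale while `rho`, `beta` and `sigma_theta` recover
  cleanly.
- No covariate terms: the models are intercept-plus-random-effects only.
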
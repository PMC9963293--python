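# Methods

`streamcom` implements a theory-and-inference chain for asking whether the
intentional release of captive-bred fish (stock enhancement) stabilises or
destabilises the receiving stream community.  It has two halves: a
stochastic multi-species Ricker simulator used for theory experiments, and
three hierarchical Bayesian models that mirror how the same question is
asked of long-term monitoring data.  Everything runs on synthetic data with
known ground truth; no external data are required.

## 1. Community model with intentional release

Densities of `S` competing species follow a discrete-time Ricker map.  The
enhanced species (index 0) receives `R` captive-bred individuals per step:

    N_{i,t+1} = (N_{i,t} + phi_i R)
                * exp[ r_i (1 - (alpha_{i1} R + sum_j alpha_{ij} N_{j,t}) / K_i) ]
                * exp(eps_{i,t}),         eps ~ Normal(0, sigma_eps^2)

with `phi_i = f_R` for the enhanced species and 0 otherwise.  Released fish
therefore compete in their release year regardless of their fitness `f_R`,
but contribute offspring only in proportion to it.  `alpha_ii = 1` fixes the
density scale; coexistence of competitors (`alpha < 1`) produces
*overyielding*: the summed equilibrium density `2K/(1+alpha)` of a symmetric
pair exceeds a single species' `K`.  Release is externally controlled — not
density-regulated — which is the mechanism by which it can erode that
overyielding and inflate the temporal coefficient of variation (CV) of total
community density.

Simulation protocol (the defaults of `SimProtocol`): 1,500 steps = 100
initialization steps without release + 400 burn-in steps with release +
1,000 saved steps used for summaries.  The 10-species design additionally
reseeds each species with Poisson(5) individuals every 10 steps *during
initialization only* (reseeding during the release phase would mask the
extinctions the analysis records) and applies an absorbing extinction
threshold of 0.01.  Summary statistics (CV, temporal mean, temporal SD,
sample-SD convention with `n-1`) are computed for the whole community, the
enhanced species, and the summed unenhanced species; persistence counts
species strictly above 0.01 at every saved step.  Densities above 1e12 mark
a replicate as diverged; diverged replicates are flagged and excluded from
summaries.

Scenario designs: the two-species grid crosses 20 growth rates on
[0.5, 3.5] x 20 carrying capacities on [50, 500] x sigma_eps in {0, 0.5} x
alpha in {0.25, 0.5} (1,600 scenarios; 400 (r, K) combinations); the
10-species design crosses r1 in {0.5, 1.5, 2.5, 3.5} x mean competition
in {0.25, 0.5} x K in {100, 400} x f_R in {0.5, 1} (32 scenarios) with
random communities (`r_i ~ Unif(0.5, 2.5)` for unenhanced species,
`alpha_ij ~ Exp(mean abar)` off-diagonal).  Release levels are evenly
spaced on [0, 500], endpoints included.

The acceptance checks run this design scaled down (150 + 150 + 300 steps,
100 replicates, R in {0, 250, 500}), a size chosen so the qualitative
regimes are unambiguous while a full run stays in seconds.  Replicates are
*paired* across release levels (same community draw and noise stream) so
the release contrast is within-community; a sign test on CV(R=500) >
CV(R=0) then has high power at 100 replicates.

## 2. Density-reconstruction state-space model

Monitoring counts are comparable across sites only after removing
observation error and imputing unsampled years.  Per species group
(enhanced = the stocked salmon; unenhanced = everything else pooled):

    observation:  N_st ~ Poisson(lambda_st * A_st)
                  lambda_st = n_st exp(eps_obs_st) + psi * beta_s * Fry_wt
    process:      ln n_st = xi1_s + xi2_s ln n'_{s,t-1} + eps_state_st
                  ln n'_{s,t-1} = sum_{q=1..Q} w_q(tau) ln n_{s,t-q}

with `w_q = tau^q / sum tau^q` (geometric-lag AR; Q = 3 matching the 1-3 y
life span of the study species), `(xi1_s, xi2_s) ~ MVN(theta_xi, Omega_xi)`
across sites, `beta_s >= 0 ~ Normal(theta_beta, sigma_beta^2)` truncated
(released fry can only add to catch), and `psi = 1` only for the enhanced
group.  Fry releases are in million fish.

Priors: Normal(0, 10^2) on location hyper-parameters, half-Cauchy(0, 5) on
SDs, Beta(1, 1) on tau, uniform correlation in Omega_xi, and Normal(0, 2^2)
on the first Q log-densities.  The last is deliberately tighter than
"uninformative": +-3 sd already spans e-6 to e+6 fish per m^2, and a wider
prior lets unobserved lead-in years wander enough to corrupt the derived
site CVs.

Sampling is adaptive Metropolis-within-Gibbs with three structural moves
that the posterior geometry requires:

* latent log-densities are updated by **exact Gaussian Gibbs** holding
  `V = ln n + eps_obs` fixed at observed cells (the Poisson likelihood sees
  only `V`, so given `V` the conditional of `ln n` is Gaussian); columns
  more than `Q` apart are conditionally independent and are updated as
  vectorised blocks;
* a scaling move `(eps_obs, sigma_obs) -> (c eps_obs, c sigma_obs)`
  traverses the funnel between the observation-error field and its SD;
* an analogous scaling move couples the `(xi1, xi2)` deviations with their
  hyper-SDs.

`(xi1_s, xi2_s)` have conjugate bivariate-normal Gibbs updates; everything
else is adaptive random-walk Metropolis (Robbins-Monro adaptation toward
0.44 acceptance, frozen after warmup).  Convergence is flagged by
rank-normalised split R-hat < 1.1 (arviz) over the hyper-parameters and
site-level parameters; non-converged fits refuse to feed downstream stages
unless forced.  The sampler was cross-validated against JAGS (the classic
Gibbs engine for such models) on an identical dataset: posterior quantiles
of tau, the xi hyper-means and the hyper-SDs agreed to ~0.05.

Model adequacy uses a posterior-predictive (Bayesian) P-value with a
chi-squared discrepancy `sum (y - E)^2 / E`, `E = lambda * A`, comparing
replicated to observed counts per kept draw; ~0.5 indicates adequate fit.
Site summaries (temporal CV, mean, SD per group, with the whole community
as the sum of the two groups' posterior-median density series) are computed
from median reconstructed densities over all calendar years, imputed years
included.

**Known limitation — AR attenuation.**  With 21-year series the marginal
posterior of the AR hyper-mean `theta_xi2` centers well below the
generating value (roughly 0.25 when the truth is 0.5 under annual
observation), and under 1-3 y observation gaps it concentrates near zero:
the data cannot separate lagged density dependence from inflated process
noise once latent-state uncertainty is accounted for.  This is a property
of the model-design combination, not of the sampler (JAGS reproduces it).
Consequently the frequentist coverage of credible intervals for the xi
hyper-means at a fixed generating truth falls below nominal at this series
length; tau, theta_beta and the latent densities themselves are unaffected
in the ranges exercised here.  Reconstructed density series — the input to
the downstream regression — are insensitive to this, because the fitted
process simply reallocates variance between `xi2` and `sigma_state`.

## 3. Latent effective-release regression

Site-level responses (taxonomic richness; temporal mean and SD of whole-
community density) are regressed on the *effective release* and five site
covariates (log watershed area, temperature, precipitation, forest
fraction, number of observation years), all standardized.  Watershed totals
`R_w` (yearly average of fry + juvenile + smolt) are known, but their split
across sites is not: a latent simplex `eta_w` over the `S_w` sites plus one
unsurveyed slot (flat Dirichlet prior) defines `R'_s = eta_{w,s} R_w`,
estimated jointly with the regression.  `R'` enters the linear predictors
scaled by its cross-site SD per draw so its coefficient is comparable to
the other standardized predictors (a config switch disables this).

Richness is Poisson with a lognormal overdispersion term; (ln mean, ln SD)
are bivariate normal with covariance `Omega_y`.  Watershed intercepts
follow a second hierarchy driven by ocean productivity and SD elevation.
Because `ln CV = ln SD - ln mean`, every CV coefficient is the per-draw
difference of the SD- and mean-model coefficients — computed exactly from
aligned draws, never refit.  Zero-release watersheds contribute no
likelihood information about their `eta_w` (the posterior stays at the
prior) and are handled without special-casing.

## 4. Sparse interaction-matrix fit

For sites with long series and no stocking, a multi-species Ricker
state-space model estimates pairwise competition:

    ln n_{i,t} = ln n_{i,t-1} + r_i - sum_j alpha'_ij n_{j,t-1} + eps_state

with Poisson-lognormal observation as above.  `alpha'_ij` has interaction
scale (`alpha'_ii = r_i / K_i`); reported coefficients are the per-draw
ratios `alpha_ij = alpha'_ij / alpha'_ii` (diagonal exactly 1), directly
comparable to the theory model's `alpha`.  Sparsity comes from
spike-and-slab half-normal priors (slab variance 1, spike variance 0.01,
Bernoulli inclusion with probability 0.9 for intraspecific and 0.5 for
interspecific elements — both configurable).  Process errors are correlated
across species through D latent factors with multiplicative-gamma loadings
(shape hyper-parameters (2, 3), a conventional choice), giving
`Omega_eps = Delta^T Delta + diag(sigma_pi^2)`; only `Omega_eps` is
reported, since the loadings themselves are rotation/sign indeterminate.
`D = 2` by default.  Taxa must occur (count > 0) in strictly more than four
years at the fitted site; sites need at least 17 observed years; sites are
fitted independently.

Conjugacy is exploited: `r_i` (Normal(1, 1) prior — growth rates above
~2.5 are rarely observed in nature) and `alpha'_ij` (truncated normal)
have exact Gibbs updates, as do the inclusion indicators, factors,
loadings and their gamma hyper-priors; latent states use even/odd-column
Metropolis blocks plus the same compensated-shift and funnel-scaling moves
as the density model.

The recovery harness fits `D = 0` — the generating model for the
two-species truth — because with two species a two-factor covariance is
saturated and can absorb the interaction signal itself.  At 40-year series
the intrinsic per-replicate uncertainty of a rescaled `alpha` is ~0.15-0.2
(nearly independent of K and sigma_pi, since both rescale signal and noise
together), so recovery is validated on *rank order* of the coupled pair
(0.6 vs 0.3) and on shrinkage of true-zero couplings, not on tight
magnitude windows.

## 5. Synthetic-data generator

The generator emulates the monitoring design the models assume: 31
watersheds x ~3 sites, calendar years 1999-2019 (21 years), observation
gaps drawn from {1: 0.5, 2: 0.3, 3: 0.2}, sampling areas ~Normal(175, 60)
m^2 floored at 20, watershed-aggregated releases up to 0.24 million fry per
year (constant with +-10% jitter; stage ratios fry : juvenile : smolt =
1 : 0.09 : 0.41) with a quarter of watersheds release-free.  State-space
truth: theta_xi = (-0.8, 0.5) (stationary density ~0.2 fish/m^2), tau
= 0.6, sigma_state = 0.3, sigma_obs = 0.2, theta_beta = 1.0.  Regression
truth uses the destabilizing pattern (release coefficients -0.4 on ln mean,
-0.1 on ln SD, hence +0.3 on ln CV; -0.2 on richness).  Covariates are
drawn independently; real monitoring covariates are correlated, so
recovery results here do not speak to collinearity-induced difficulties.
Recovery harnesses deviate from the survey defaults only where the check
demands information the survey design cannot give (annual observation and
release jitter 0.3 for coefficient recovery — a deliberately informative
validation design, like a power analysis run at favourable conditions).

What passing tests show: the estimators recover what they are
mathematically able to recover at these sample sizes, the derived
quantities obey their exact identities, and the posterior-predictive check
is calibrated when the model is true.  What they do not show: robustness to
ecological misspecification (size structure, movement, correlated
covariates, non-Poisson sampling), which no synthetic self-test can
establish.

## 6. Problem sizes and numerical conventions

Default MCMC settings are 4 chains; tests and the acceptance script use 2
chains with shorter, thinned runs at reduced data sizes (6-20 sites; the
sizes are stated in each harness) — chosen so the full suite completes on a
single CPU while each check retains its statistical meaning.  Tie-breaks
and degenerate inputs: a zero group mean reports CV as undefined rather
than infinite; a draw with a numerically zero intraspecific coefficient is
excluded (and counted) from rescaled-alpha summaries; zero-variance
predictors are rejected by name; proposals outside a parameter's support
count as rejections.  All CSV output is UTF-8 with "NA" for missing values;
densities are fish per m^2 and releases million fish throughout.
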
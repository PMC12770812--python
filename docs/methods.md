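# Methods

This note documents the model the package implements, the choices made
where the design was genuinely open, and what the synthetic studies can
and cannot establish.

## The population model

Two nest-box populations of a short-lived migratory passerine are
tracked with a pre-breeding census.  Each site's female population is
structured into local recruits (age 1, locally born), adults (age >= 2)
and immigrants (age 1, outside origin).  Writing `phi` for apparent
survival (true survival times site fidelity), `kappa` for clutch size,
`zeta` for the per-egg probability of producing a fledgling and `omega`
for the expected immigrant inflow, the female process at each site is

    N_rec[t+1] ~ Poisson( 0.5 * phi_juv[t] * sum_a N_a[t] kappa_a[t] zeta_a[t] )
    N_ad[t+1]  ~ Binomial( N_rec[t] + N_ad[t] + N_im[t], phi_ad[t] )
    N_im[t+1]  ~ Poisson( omega )

with an even fledgling sex ratio.  Males follow the same equations with
male survival rates acting on the female-produced fledgling pool.
Immigrants are treated as one-year-old natal dispersers.

Three data streams inform the model jointly:

* **Capture–recapture.**  Stage-structured Cormack–Jolly–Seber model on
  m-arrays (releases by occasion x first recaptures), one juvenile-release
  and one adult-release array per sex and site, multinomial likelihood.
* **Productivity.**  Population-level totals per female stage class:
  eggs `c ~ Poisson(kappa b)` given broods `b`, fledglings
  `f ~ Binomial(c, zeta)`.
* **Counts.**  Occupied nest boxes per sex and site,
  `log y ~ Normal(log N, tau^2)` — the latent total is the lognormal
  median.  The printed notation "lognormal(N, tau)" is ambiguous; the
  median-N reading is the conventional state-space choice and is what we
  implement.

Survival, recapture and fledging probabilities live on the logit scale,
clutch size on the log scale, each as a sex/stage/site mean plus normal
year effects; covariates enter as fixed slopes shared across sexes and
sites, one slope per stage.  Clutch size carries no covariates, and
recapture carries year effects but no covariates.  The fledging year
effects are correlated across the three female stage classes through a
parameter-expanded Cholesky factorization: a unit-lower-triangular
factor scaled by positive expansion scalars, applied to standard-normal
innovations per site and year.  The implied 3x3 covariance is shared
across sites.

### The two-age recapture convention

The likelihood distinguishes juvenile from adult recapture probability.
We use the standard two-age construction: a bird marked as a nestling is
detected at its first possible reencounter (age 1, a first-year breeder)
with the juvenile recapture probability and afterwards with the adult
one; survival is juvenile over the first interval and adult thereafter.
This is history-independent, keeps both recapture parameters identified,
and is applied identically in the simulator and the likelihood.

## Priors

Vaguely informative and fully configurable (`PriorConfig`): link-scale
means Normal(0, 1.5^2) (logit) and Normal(log 6, 1) (log clutch size);
year-effect and observation SDs Uniform(0, 5); covariate slopes
Normal(0, 1.5^2); log immigration expectation Normal(0, 2^2); expansion
scalars half-Normal(0, 1) with standard-normal factor off-diagonals;
initial abundances per stage Uniform(0, 3 x first count).

## Posterior computation

Sampling is by adaptive Metropolis-within-Gibbs (numba-compiled),
single-site random-walk proposals with per-parameter step sizes adapted
during burn-in toward 0.44 acceptance.  Latent abundances are
continuous: the Poisson and binomial process pmfs are extended off the
integers through the gamma function, so every conditional density is
well defined for real-valued states.  Posterior states are therefore
real numbers and should be rounded if integer abundances are reported —
a deliberate relaxation of the discrete process.  Two latent-state moves
are interleaved: single-cell random walks and a joint multiplicative
rescaling of one sex-site-year's three stages (log-scale proposal with
its Jacobian), without which the trajectory cannot drift relative to the
counts and the observation SD mixes poorly.

The jitted kernel's joint density is checked in the test suite against
an independent numpy implementation of every likelihood term, to
1e-12.  Default chain settings are field-scale (3 chains of 100,000, 10,000
burn-in, every 5th kept); every experiment
below states the much shorter settings it actually uses.  Convergence is
monitored with a rank-normalized split Gelman-Rubin statistic
(threshold 1.3, cross-checked against arviz), absolute fit with
posterior predictive p-values: Freeman-Tukey discrepancies for counts
and m-array cells, deviance for productivity (the discrepancy
functions are this package's explicit choices).

Initialization tracks the data (latent states from interpolated counts,
means from pooled ratios) with per-chain jitter; a non-finite joint
density triggers re-initialization up to a bounded number of attempts.

Known mixing limitation: with all data streams removed (a prior-recovery
exercise), parameters entangled with the latent process — the
immigration expectation above all — decorrelate very slowly; the
prior-recovery test therefore checks the parameters whose conditionals
are prior-only, at random-walk Monte-Carlo tolerances.

## Covariate machinery

Breeding-season windows are anchored on each site-year's mean nest
initiation date: nest-initiation/incubation = 14 days before that date
plus 6 laying and 14 incubation days (34 days); hatchling = the next 16
days; post-fledging = from 10 days after the hatchling window to
August 31 (the start of the post-fledging window is not sharply
defined biologically; both the gap and the end date are configuration
constants).
The "summer" window behind the adult-fledging temperature covariate is
likewise configurable and defaults to May 1 – August 31.  Temperature
covariates average daily values in the window (means of daily means,
minima or maxima), precipitation accumulates.  All covariates are
z-standardized across years (sample SD); pairs with |Pearson r| > 0.50
are barred from co-occurring in one model.  Mast years enter as a raw
0/1 indicator plus a one-year lag; missing covariate years are not
imputed — a model attaching a covariate requires it complete over the
study span.

## Covariate selection

Each candidate covariate is tested in its own single-covariate model
(stage-specific slopes on its target rate).  A slope is retained when
its 85% equal-tailed credible interval excludes zero; retained
covariates are combined into the final model (slopes re-estimated
jointly), with the correlation screen enforced at assembly.  Equal-tailed
intervals are used throughout — simpler and more reproducible than
highest-density intervals, and the conventional reading of a credible
interval in this setting.  Candidate fits get deterministic
per-candidate seeds derived from the master seed.

## Transient LTRE

Realized growth `lambda_t` is the ratio of successive latent female
totals.  Sensitivities are the analytical derivatives of the one-step
expectation projection evaluated at each year's realized states and
rates (transient, not asymptotic):

    d lambda / d phi_juv = 0.5 sum_a N_a kappa_a zeta_a / N_tot
    d lambda / d phi_ad  = 1
    d lambda / d kappa_a = 0.5 phi_juv N_a zeta_a / N_tot
    d lambda / d zeta_a  = 0.5 phi_juv N_a kappa_a / N_tot
    d lambda / d inflow  = 1 / N_tot

Per posterior draw, the first-order contribution of component `x` is
`c_x,t = mean_t(s_x) * (x_t - mean_t(x))` and its share of
`Var(lambda)` is `Cov(c_x, lambda) / Var(lambda)` — a covariance-ratio
formulation; the exact estimator variants of the originating
variance-decomposition literature are not reproduced beyond this.
Each rate's share is split into per-covariate parts via the chain rule
on the link scale (derivative of the inverse link at the mean linear
predictor, times the fitted slope, times the centred covariate) with the
residual defined as the remainder, so the parts add up exactly and the
linearization error lands in the residual.  Contributions are computed
against `lambda_t` (not its log).  Components cover female survival
(juvenile, adult), clutch size and fledging per stage class, and the
realized immigrant inflow; the headline survival-versus-fecundity split
is renormalized over survival + fecundity only (so the two headline
shares sum to 100%), while the raw component table keeps
immigration.  Time-averaged sensitivities are also exported normalized
to sum to one across the eight demographic rates.

## Synthetic data: what it emulates and what it does not

The generator draws a ground truth from configured ranges chosen to
mimic demographic estimates reported for Swiss nest-box populations
of this species
(juvenile apparent survival ~0.10–0.22, adult ~0.45–0.55, clutches of
5.4–5.9 eggs with very small year-to-year variation, fledging ~0.6–0.8
with large correlated year effects, 1–4 immigrants per sex and year,
count error SD 0.05–0.12, 13–27 breeding females per site).  It then
simulates the latent process with full demographic stochasticity and,
on top of it, individual birds: every marked bird lives and is detected
according to the same rates the likelihood uses, so capture histories,
m-arrays, and the CJS likelihood are mutually consistent by
construction.  Roughly 6,000–7,000 marked individuals accrue over 40
years, matching the scale of the field study.  The mark-recapture,
productivity and count streams are simulated conditionally independent
given the rates — exactly the independence the joint likelihood
assumes; real data share individuals across streams and therefore
violate it mildly.  Covariates are iid standard normals (re-standardized
exactly), the mast indicator Bernoulli(0.25); no density dependence, no
polygyny, no trend, no weather autocorrelation.  Passing recovery tests
therefore demonstrate correctness of the estimation machinery under the
model's own assumptions, not robustness to their violation.

Extinction mid-series is flagged, emitted as structural zeros, and the
dataset is still returned (counts for extinct sex-site-years become
missing, since a lognormal count of zero birds is undefined).

## Problem sizes used by the shipped experiments

Chosen once, as the package's own trade-off between Monte-Carlo error
and turnaround:

* parameter recovery: 20 independent two-site, 40-year studies; 2
  chains x 3,000 iterations (1,000 burn-in, thin 2) each; pooled 95%
  CRI coverage over the 26 identified means per study.
* selection power: 10 studies with a planted juvenile-survival slope of
  -0.3 plus three null covariates; 1 chain x 2,000 iterations per
  candidate model.
* decomposition checks run on constructed rate series (no MCMC), where
  the expected shares are exact.
* the acceptance script fits the base model with 3 chains x 6,000 and a
  two-candidate selection demonstration with 2 chains x 2,500.

## Known limitations

* Latent abundances are continuous relaxations; reported states are not
  forced to integers.
* The random-walk sampler needs the year-rescaling move to mix the
  count-error SD; immigration expectations remain the slowest-mixing
  block and benefit from longer chains than the shipped defaults for
  tests.
* Single-covariate screening inherits the usual multiplicity behaviour
  of the 85% rule (roughly 15% of null slopes retained by design).
* Male abundance informs only the male count series; all productivity is
  female-based.
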
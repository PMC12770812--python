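# piedfly

An integrated population model (IPM) for two nest-box populations of a
short-lived migratory passerine (the European pied flycatcher is the
motivating system), with stepwise environmental-covariate selection and
a transient life-table response experiment (LTRE) that decomposes the
variance of the realized population growth rate.

**Who it is for.**  Population ecologists who have (i) individual
capture histories, (ii) per-nest productivity records, and (iii) annual
counts of occupied nest boxes for one or more sites, and who want to
estimate demographic rates and abundance jointly, test which
environmental covariates act on which rate, and quantify how much each
rate — and each covariate acting through it — contributes to variation
in population growth.

## The model

With a pre-breeding census, females at each site split into recruits
(age 1, local), adults (>= 2) and immigrants (age 1, immigrant):

    N_rec,t+1 ~ Poisson( 0.5 φ_juv,t Σ_a N_a,t κ_a,t ζ_a,t )
    N_ad,t+1  ~ Binomial( N_rec,t + N_ad,t + N_im,t , φ_ad,t )
    N_im,t+1  ~ Poisson( ω )

(males analogous, acting on the female-produced fledgling pool).  The
joint likelihood combines a stage-structured Cormack–Jolly–Seber
m-array model for apparent survival φ and recapture p, Poisson/binomial
likelihoods for clutch size κ and fledging probability ζ (with
correlated year effects across female stage classes), and a lognormal
state-space model for the counts, `log y ~ N(log N, τ²)`.  Rates sit on
logit/log scales with normal year effects and optional covariate slopes
β per stage; a covariate is retained when its 85% credible interval
excludes zero.  The transient LTRE evaluates analytical sensitivities
∂λ_t/∂x at realized annual states and attributes Var(λ) to components
via Cov(c_x, λ)/Var(λ), then splits each component into per-covariate
and residual parts.  See `docs/methods.md` for the full treatment.

Inference is by an adaptive Metropolis-within-Gibbs sampler compiled
with numba; the expensive experiments below run in minutes on one core.

## Worked example

```python
from piedfly import synthetic, ingest, inference, ltre

truth = synthetic.make_truth(seed=11)          # 2 sites, 40 years
ds = synthetic.simulate_dataset(truth, seed=12)
data = ingest.IPMData(
    marrays=ingest.build_marrays(ds.captures),
    nests=ds.nests, counts=ds.counts,
    covariates={k: v.values for k, v in ds.covariates.items()},
)
cfg = inference.MCMCConfig(chains=2, iterations=3000, burn_in=1000, thin=2)
draws = inference.fit(inference.ModelSpec(), data, cfg, seed=5)

lam = ltre.geometric_mean_lambda(ltre.realized_lambda(draws)).mean(axis=0)
print("geometric-mean growth:", lam.round(3))
print(ltre.decompose(draws, covariates=data.covariates).headline_split())
```

which printed, for this seed:

    geometric-mean growth: [1.    0.999]
         site  survival_pct  fecundity_pct
    0  site_a     90.987724       9.012276
    1  site_b     62.400969      37.599031

i.e. both simulated populations are stationary (λ ≈ 1.0), and most of
the year-to-year variance in realized growth flows through apparent
survival rather than fecundity — the same qualitative structure the
model family was built to expose.  (Exact digits vary with seeds and
chain settings; the decomposition here is a short-chain illustration.)

The same pipeline runs from the shell:

    piedfly all --config config.yaml --out results/

with `simulate / fit / select / ltre` available as individual stages
(artifacts: posterior summaries, R-hat table, posterior predictive
p-values, selection report, LTRE share/sensitivity tables, JSON
manifests).

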
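# occudyn

Bayesian multi-season (dynamic) occupancy modeling for camera-trap
surveys — from raw timestamped trigger events to model-averaged seasonal
occupancy trajectories.

`occudyn` is aimed at wildlife ecologists running repeated camera-trap
surveys (e.g. seasonal monitoring of mesocarnivores on a site grid) who
want to estimate how species' space use changes between seasons while
accounting for imperfect detection, and to compare and average candidate
covariate models in a fully Bayesian workflow.

## The model

Sites i = 1..N are surveyed over primary periods (seasons) t = 1..T, each
with K short secondary occasions (default thirteen 5-day blocks).  The
latent occupancy state z[i,t] evolves as

    z[i,1]   ~ Bernoulli(φ1_i)
    z[i,t+1] ~ Bernoulli( z[i,t] (1 − ε[i,t]) + (1 − z[i,t]) γ[i,t] )

with colonization γ, extinction ε, and detections
y[i,t,k] | z[i,t] = 1 ~ Bernoulli(p[i,t,k]) (no false positives).
Occupancy after the first season is derived,
φ[t+1] = φ[t](1−ε[t]) + (1−φ[t])γ[t].  All four parameters take
logit-linear covariate effects with Logistic(0,1) priors; the site-level
marginal likelihood integrates the latent states exactly with a two-state
forward recursion (missing occasions are marginalized).

On top of single-model inference (MAP + adaptive-Metropolis MCMC with
split-chain R̂ diagnostics), the package implements the model-selection
layer used in practice: PSIS-LOO scores with Pareto-k̂ reliability
screening (discard at k̂ > 0.7), elpd ranking, and — when candidate
models predict similarly (elpd gaps < 4) — stacking-based model
averaging, including the characteristic averaged credible intervals with
an endpoint at exactly zero for covariates carried by only part of the
model weight.

Because raw survey data of this kind are rarely public, a first-class
synthetic-data module simulates the whole design (60 sites, four 65-day
seasons, covariates matched to published summary moments, camera dropout,
bursty trigger events) so every stage is testable end to end with known
truth.  See `docs/methods.md` for the full model description and design
choices.

## Worked example

```python
import occudyn as od

# simulate the default survey design with known generating parameters
design, covs, truth = od.scenario_study_default(seed=1)
z = od.simulate_dynamics(design, truth, covs, seed=2)
history, covs = od.simulate_detections(z, truth, covs, design, seed=3)

print(od.naive_occupancy(history).round(3).to_dict())
# {'W20': 0.55, 'D21': 0.533, 'W21': 0.65, 'D22': 0.533}

model = od.DynamicOccupancyModel(history, covs, truth.model_spec())
res = model.fit(n_chains=3, n_iter=3000, n_burn=1000, seed=4)
print(res.summaries.round(2)[["mean", "sd", "q2.5", "q97.5", "significant"]].head(6))
#                   mean    sd  q2.5  q97.5  significant
# phi1[Intercept]   0.22  0.26 -0.30   0.71        False
# phi1[TPROD]       0.33  0.28 -0.20   0.88        False
# gamma[Intercept] -0.98  0.31 -1.67  -0.37         True
# gamma[NDVI]       0.65  0.31  0.10   1.29         True
# eps[Intercept]   -1.45  0.29 -2.08  -0.93         True
# eps[Graz]         0.75  0.28  0.21   1.34         True
```

The summary rows are posterior means, SDs and 95% credible intervals of
the logit-scale coefficients; `significant` flags intervals that exclude
zero.  Here the generating values (γ intercept −0.85 with NDVI slope 0.6,
ε intercept −1.4 with grazing slope 0.25, …) are recovered within their
intervals at 60 sites.  `res.seasonal_occupancy_summary()` gives the
derived mean occupancy per season with credible intervals, and
`res.loo()` the PSIS-LOO score used for ranking.

The full two-stage pipeline (detection structure first, then state
covariates, ranking, stacking and averaging) runs from a config:

```sh
occudyn run --config configs/demo.yaml
```

or programmatically via `od.run_full({...})`, producing per-species
coefficient tables, seasonal occupancy trajectories, rankings, weights
and diagnostics as CSV/JSON.

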
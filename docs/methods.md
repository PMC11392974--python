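# Methods

## The model

`occudyn` fits dynamic (multi-season) site-occupancy models to camera-trap
detection histories.  A survey consists of N sites observed over T primary
periods ("seasons") between which the occupancy state may change, each
season holding K secondary occasions (default thirteen 5-day blocks)
during which the state is assumed closed.  The latent state z[i,t] ∈ {0,1}
follows

- z[i,1] ~ Bernoulli(φ1_i)                      (first-season occupancy)
- z[i,t+1] | z[i,t]=0 ~ Bernoulli(γ[i,t])        (colonization)
- z[i,t+1] | z[i,t]=1 ~ Bernoulli(1 − ε[i,t])    (extinction)

and detections y[i,t,k] | z[i,t]=1 ~ Bernoulli(p[i,t,k]) with no false
positives.  This is the original dynamic parameterization in which
occupancy after the first season is derived recursively,
φ[t+1] = φ[t](1−ε[t]) + (1−φ[t])γ[t], rather than parameterized directly.
For mobile mesocarnivores surveyed on a 1-km grid these probabilities
describe seasonal *space use* rather than demographic presence/absence.

All four parameters carry logit-linear covariate effects.  Continuous
covariates are standardized (sample SD, `ddof=1`); categorical covariates
are reference-coded (first level is the reference: season W20, camera-view
feature "none").  Season-site covariates attached to the transition
t → t+1 use by default the value measured for the interval leading into
season t+1 ("next" alignment) — forestry interventions are recorded before
each survey season and grazing pressure accumulates over the preceding
interval — with a `transition_season="current"` switch for the other
convention.

The marginal likelihood of a site's history integrates the latent states
exactly by a two-state forward recursion with per-season rescaling.
Missing occasions (effort < 1 day) contribute a factor of one, i.e. they
are marginalized, and a fully missing season keeps the site in the
likelihood through its other seasons.  Probabilities of exactly 0 or 1 are
handled by the natural limits (an impossible history has log-likelihood
−∞), never by clipping.  The recursion is validated against brute-force
enumeration of all latent sequences to 1e−10 and sums to one over all
2^(T·K) histories.

## Detection histories from raw events

Camera triggers arrive in bursts; events of the same site and species are
thinned to *independent* events at least 30 minutes apart, measured from
the last **retained** event (sliding anchor, the common camera-trap
convention; events exactly at the boundary are kept).  Retained events are
binned into half-open 5-day occasions anchored at each season's start.
Per-occasion effort counts deployment-covered days (a day counts when at
least 12 h of it are under deployment); occasions with less than one
active day are missing by the effort rule.  Naive occupancy — the
proportion of surveyed sites with at least one detection — uses only
sites with at least one non-missing occasion in the denominator.

Species rarely detected in the dry season can be analysed on the wet
seasons only (`subset_seasons`); standardization is computed after
subsetting, over exactly the values that enter the model.

## Priors, MCMC and diagnostics

All intercepts and slopes carry standard Logistic(0,1) priors, a weakly
informative choice on the logit scale (density 1/4 at zero; Gamma(1,1) is
reserved for random-effect SDs, though no default candidate model includes
random effects).  The production run configuration is 3 chains × 15,000
iterations with 5,000 burn-in; demos and tests use reduced budgets
(3 × 3,000, burn-in 1,000) and are validated against deterministic
oracles, not run length.

The sampler is a Laplace-preconditioned random-walk Metropolis: chains
start from the posterior mode (L-BFGS with the prior included) plus
N(0, 0.1) jitter, the proposal covariance is the inverse Hessian at the
mode (eigenvalues floored at 1e−3 of the largest so flat directions
cannot blow up the proposal), and a single step-size factor adapts toward
the 0.234 acceptance target during burn-in only, keeping the retained
chain Markovian.  A run of eight consecutive zero-acceptance tuning
windows raises an error suggesting reparameterization.  The per-site
log-likelihood vector is stored at every retained draw for
cross-validation.  Convergence uses split-chain Gelman–Rubin R̂ with the
conventional R̂ < 1.1 threshold; an effect is "significant" when its 95%
credible interval (2.5–97.5 percentiles) excludes zero.

## Model comparison and averaging

Candidate models are scored by PSIS-LOO with the site as the
cross-validation unit.  The generalized-Pareto tail fit uses the
empirical-Bayes profile method of Zhang & Stephens (2009) on the largest
min(0.2·S, 3√S) importance ratios strictly above their order-statistic
threshold (strict exceedance matters with Metropolis chains, whose
repeated draws create ties); smoothed weights are truncated at
mean(w)·S^(3/4).  Reliability rules follow the standard k̂ reading: every
site k̂ < 0.5 is annotated high-accuracy, any site k̂ > 0.7 discards the
model from ranking.  When all surviving models sit within 4 elpd units of
the best, they are averaged by stacking: simplex weights maximize the
summed leave-one-out log score, optimized through a softmax
reparameterization with five deterministic multistarts; models with
identical pointwise scores share their weight equally.

Averaged posteriors are mixtures: each draw picks a model by weight, then
a uniform retained draw; coefficients absent from the selected model
contribute exactly zero.  This spike-at-zero is why averaged credible
intervals can have an endpoint of exactly 0 whenever the models carrying a
covariate hold less than 95% of the stacking weight.  Model-averaged
seasonal occupancy pushes every mixture draw through the occupancy
recursion of its own model, averages over sites, and summarizes those
draws; averaging over sites before summarizing over draws (rather than
the reverse) keeps the trajectory a proper posterior functional.

## Two-stage candidate structure

Stage 1 fixes the detection structure: six specs (null, Season, and
Season plus one of Shrubs, Feat, Alt, Effort) fitted with constant state
parameters; the highest-elpd non-discarded model wins outright, even
within 4 units of the runner-up, since a single detection structure is
carried forward.  Stage 2 crosses the first-season-occupancy choice
({none} ∪ {D_Rip, D_Excl, MINV, TPROD}) with the dynamics choice
({none} ∪ γ:{NDVI, NDVIstdv} ∪ ε:{Graz, ForInterv}), 25 specs, with at
most one covariate per parameter and never covariates on γ and ε in the
same model — a guard against overparameterization at 60 sites.  Allowing
a φ1 covariate and a dynamics covariate together interprets "univariate"
per-parameter; a `strict_univariate` mode (one covariate in the whole
model, 9 specs) is provided because single-model composition is a
genuinely open design point.  Fits with any R̂ ≥ 1.1 are excluded from
averaging with a logged warning.

## The synthetic-data generator

No public camera-trap dataset accompanies this design, so the generator
is a first-class module reproducing its statistical structure: 60 sites,
four 65-day seasons (W20, D21, W21, D22; 65 days = 13 × 5-day occasions
exactly, a design choice since only month ranges are reported for real
surveys), and covariates matched to published summary moments.  Families
are chosen per support:

- moment-matched truncated normals (solving for the untruncated (μ, σ))
  for D_Rip, MINV, TPROD, NDVI, NDVIstdv;
- lognormals for Graz (mean 6.27, SD 13.24) and D_Excl (230, 303): no
  normal truncated at zero can have SD > mean, which these do;
- scaled Betas for Shrubs (39, 31 on [0, 100]) and ForInterv (0.14, 0.25
  on [0, 1]): their SDs exceed what truncation of a normal allows on a
  bounded interval, and zero-inflated cover fractions are U-shaped in
  real landscapes anyway.

Season-site covariates are drawn independently per season; the generator
therefore emulates marginal moments, not seasonal autocorrelation or
wet/dry systematics of real greenness and grazing series — a limitation
to keep in mind when reading simulation results as statements about real
data.  Default generating coefficients give φ1 ≈ 0.6 with a +0.5 TPROD
effect, γ ≈ 0.3 with +0.6 NDVI, ε ≈ 0.2 with +0.25 Graz, and occasion
detection ≈ 0.35, lower in dry seasons and higher on trails and dirt
roads — magnitudes in the range reported for Mediterranean mesocarnivore
surveys.  Effort mixes occasion-level dropout (default 5%, effort 0 → NA)
with per-day Binomial loss (default rate 0.028, floored at one active
day), approximating a mean of ~4.86 active days per 5-day occasion; the
resulting effort SD (~0.4) is below the ~0.56 of real surveys, whose
missingness mixes longer failures.  The optional event-stream generator
emits Poisson visits (default 0.5/day) with geometric trigger bursts
inside 30 minutes so the independence filter is exercised end-to-end; a
single seed drives all draws in a documented order.

## Numerical choices and verification scale

- MAP: L-BFGS-B on the log posterior, zero start (the prior mode),
  deterministic given start and tolerance.
- Hessians: central finite differences with relative step 1e−4.
- Stacking ties resolve to equal weights; duplicate score columns are
  collapsed before optimization.
- Demo/test problem sizes: the bundled demo uses 60 sites with 3 × 3,000
  iterations (~1 minute); the calibration study uses 50 replicates of 500
  sites at the same reduced budget.  These sizes were chosen so the whole
  verification chain — likelihood oracles at 1e−10, posterior vs
  quadrature within Monte-Carlo error, PSIS-LOO within 0.3 of exact
  leave-one-site-out, 95%-interval calibration across replicates —
  runs comfortably on a single CPU.

## Known limitations

- The sampler is a random-walk method; for much larger models a
  gradient-based kernel would mix better.  The contract is valid draws
  from the posterior, which the oracle tests check directly.
- Credible-interval coverage of the reduced-budget fits is mildly
  conservative (~95–100% per coefficient across 50 replicates): modest
  true effects sit near the prior mode, and finite-chain quantile noise
  widens intervals slightly.
- Random-effect structures are recognised by the prior machinery but no
  default candidate model uses them.
- The generator does not model spatial autocorrelation between sites,
  animal movement, or between-season covariate correlation.
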
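# Methods

## Problem setting

`delivcov` estimates and projects national coverage of two delivery-care
indicators among adolescent mothers (aged 15–19) in low- and middle-income
countries: institutional delivery (INSD — the most recent live birth
delivered in a health facility) and skilled birth attendance (SBA —
delivery attended by a doctor, nurse or midwife). Observed inputs are
sparse: a handful of household-survey coverage estimates per country
scattered over 2000–2019, each with an effective sample size after
design-effect deflation. The package pools these points across countries
with a Bayesian hierarchical model, projects coverage to 2030 with
credible intervals, classifies countries against coverage thresholds,
quantifies wealth-based inequality with the slope index of inequality
(SII), and fits an individual-level determinants model.

## Trend model

For survey point *s* from country *i* in year *t* (single outcome and
stratum per fit):

    successes_s ~ Binomial(n_effective_s, p_it)
    logit(p_it) = α_i + β_i (t − 2000)/10 + γ_sdi SDI_it + γ_hrh HRH_it
    α_i ~ N(μ_α, σ_α²),   β_i ~ N(μ_β, σ_β²)

The binomial likelihood uses the real-valued effective sample size as a
quasi-likelihood weight, so no integer rounding of survey denominators is
needed. Time is centred at 2000 and scaled per decade: β_i is a country's
log-odds change per ten years. SDI (Sociodemographic Index, in [0, 1]) and
HRH (health-worker density per 1,000 population) are z-scored against the
fitting set; the stored mean/SD back-transform keeps projections and
reported coefficients on natural scales. Urban/rural and wealth-quintile
series are fitted by running the same model independently per stratum —
there is no cross-stratum constraint.

Priors are weakly informative, and deliberately stress-tested by the
sensitivity protocol: N(0, 100²) on μ_α, μ_β and the γ's; half-Cauchy(0,
2.5) on σ_α and σ_β, with uniform(0, 10) and half-normal alternatives
selectable. Observed coverages of exactly 0 or 1 are clamped to
[0.5/n_eff, 1 − 0.5/n_eff] only where an empirical logit is needed
(initialisation); the likelihood itself needs no clamp.

### Sampler

Posterior sampling is adaptive Metropolis-within-Gibbs, all chains
advanced in lock-step through one seeded PCG64 generator:

* α and β blocks: per-country random-walk Metropolis, vectorised across
  chains and countries (valid because the likelihood factorises by
  country given the shared parameters);
* γ's: a joint 2-D random walk per chain;
* hyper-means μ_α, μ_β: exact conjugate Gibbs draws;
* hyper-SDs: random-walk Metropolis on the log scale (with Jacobian).

Proposal scales adapt every 50 iterations toward 44% acceptance (30% for
the joint γ block) during burn-in only and are frozen afterwards, so the
post-burn-in chain is a valid time-homogeneous MCMC. Chain *c* starts from
data-informed values (per-country least squares on the empirical logit)
jittered by N(0, (0.1·c)²). Draw count per chain is
⌊(n_iter − burn_in)/thin⌋; defaults are 10,000 iterations, 3 chains,
thinning 10, burn-in 500 (950 draws per chain). Identical seed, config and
data give bit-identical draws.

The region-hierarchy flag inserts an optional third level (region means
for α around a global mean, sharing the country-level σ as the
region-level spread). It is off by default: with few countries per region
the extra level is weakly identified and the two-level model is the
primary specification.

### Projection and sensitivity

Projection evaluates the coverage draws p_it for 2000–2030 per country and
reports the posterior mean and the 2.5th/97.5th percentiles, ×100.
Covariates are treated as fixed inputs (their uncertainty is not
propagated). If the covariate series stops before 2030, an opt-in
extrapolation fits a line to each country's last ten observed years,
clipping SDI to [0, 1] and HRH to ≥ 0; it is off by default so missing
projection-year covariates are a loud error.

The sensitivity protocol refits (a) without SDI/HRH and (b) with the
alternate hyper-SD prior family, and summarises each refit against the
base as the per-year median (across countries) of |Δ posterior mean|, in
percentage points.

## Convergence diagnostics

The classic (non-split, non-rank-normalised) Gelman–Rubin PSRF:
W = mean within-chain variance, B/n = variance of chain means,
V̂ = (n−1)/n·W + B/n, PSRF = √(V̂/W). The upper limit is the 97.5th
percentile of the variance ratio under the F-approximation, with W's
degrees of freedom moment-matched from the spread of per-chain variances;
it is floored at the point estimate so the report's ordering invariant
holds even when B = 0. A parameter is flagged when the upper limit exceeds
1.1 — a documented convention; "close to 1" is the qualitative criterion.
A split-chain variant (halving each chain first) is available behind a
flag and additionally detects within-chain drift. Degenerate chains (W=0)
raise rather than reporting an infinite or NaN ratio silently; the
table-level wrapper converts that to a NaN row with the flag raised.

## Slope index of inequality

Quintile coverage is regressed on ridit scores (midpoint of each group's
cumulative population-share interval, poorest first) by weighted least
squares with the shares as weights; the SII is the regression slope — the
fitted coverage difference between cumulative rank 1 and rank 0. Linear
WLS (not logistic) on the ridit is the documented choice. The default
operates on posterior-mean coverages; `sii_from_draws` computes a per-draw
SII and a 95% credible interval. Percentage change between two years is
reported in point mode (difference in percentage points, the default) or
relative mode (percent of the start value); the urban-rural gap is
urban − rural with a "wide disparity" classification at ≥ 30 points.

## Determinants model

Individual-level logistic regression with a random country intercept:

    y_j ~ Bernoulli(p_j),  logit(p_j) = b₀ + x_j' b + u_0i(j),
    u_0i ~ N(0, σ²_u0)

Covariates are dummy-coded against fixed reference levels (household-head
age <30 and male; no education; parity 1; no ANC visits; no media access;
poorest quintile; urban residence), 21 non-reference columns in all.
Priors: N(0, 10²) on fixed effects, half-Cauchy(0, 2.5) on sd(u). The
sampler reuses the Metropolis-within-Gibbs pattern with a joint fixed-
effect update whose proposal shape is the maximum-likelihood covariance
(Cholesky factor, adaptively scaled), vectorised per-country intercept
updates, and a log-scale update of the intercept SD. Complete or
quasi-complete separation (a level perfectly predicting the outcome) is
detected up front and reported instead of letting the chain diverge.
Odds-ratio tables report the posterior median (switchable to mean) and
central 95% interval of exp(coefficient), with reference rows fixed at
1.00, plus the σ²_u0 line. Age-group sub-analyses are input filters, not
separate code paths.

## Synthetic-data generator

The generator emulates the statistical structure the pipeline assumes,
with defaults set to the target study design: 54 countries in 6 regions,
~4 surveys each over 2000–2019 (~216 survey occasions), 2,000 respondents
per survey deflated by a design effect of 2 (effective n = 1,000). Truth
parameters default to μ_α = −0.4, μ_β = 1.0/decade, σ_α = 1.0,
σ_β = 0.3 — coverage rising from a mid-low base toward high levels by
2030, the qualitative pattern of the target setting — with an urban
advantage of 1 logit split ±0.5 around the national value and a wealth
gradient of 0.4 logits per quintile centred on Q3. SDI is a smooth
increasing series clipped to [0, 1]; HRH a positive increasing series.
Individual covariate marginals are fixed documented frequency tables
(e.g. education none/primary/secondary/higher at 25/35/30/10%); recovery
tests do not depend on them. Both outcome flags are independent Bernoulli
draws from the same linear predictor.

What the generator does *not* emulate: survey-design clustering beyond
the scalar design effect, measurement/recall error, country-specific
policy shocks or non-linear trends, correlation between INSD and SBA
within a birth, or any real country's values. Passing recovery tests
therefore demonstrates that the estimation machinery is correct under the
model's own assumptions, not that real-data estimates are unbiased.

### Identifiability note for recovery tests

A monotone increasing SDI series is nearly collinear with linear time
within a country, so per-country slope recovery against known truth is
only well-posed without that confound. Recovery and interval-calibration
simulations therefore generate with γ_sdi = γ_hrh = 0 and fit without
covariates; the covariate path is exercised by the sensitivity protocol,
where a weak SDI effect on well-identified data must produce only small
differences when excluded.

## Problem sizes and numerical choices

Recovery simulations use reduced sampler settings (3 chains × 3,000
iterations, thinning 5, burn-in 500 → 1,500 retained draws) on 10
countries × 4 surveys, chosen so the whole suite runs comfortably on one
CPU while leaving Monte-Carlo error well inside the asserted bands; the
interval-calibration check pools 25 replicate datasets (250 country-
years). The conjugate check uses the full default settings (2,850 draws)
on a single 60/100 observation: with flat-on-logit hyper-priors the exact
posterior is Beta(60, 40), whose KS distance to the Beta(61, 41) reference
(flat-on-p prior) is ≈ 0.01 at this sample size, far inside the 0.05
acceptance distance. With only 10 countries the realised variance of the
drawn country intercepts fluctuates substantially around σ²_u0 (relative
SD √(2/9) ≈ 47%), so posterior medians of σ²_u0 from a single replicate
scatter accordingly; the fixed-seed recovery test sits well inside its
band, and the acceptance script reports whatever the supplied seed
produces.

Threshold counting operates on values rounded to one decimal (the printed
precision of the national tables); "reached 80%" means ≥ 80.0 after
rounding, and no fixture cell equals exactly 80.0 in the relevant years,
so the ≥ vs > choice is observationally irrelevant. The packaged fixture
of printed national predictions is checksum-verified (SHA-256) at load
time.

## Known limitations

* The trend model is linear in time on the logit scale; it cannot express
  plateaus or reversals beyond what the covariates carry.
* Covariate uncertainty and survey-design structure beyond the effective
  sample size are not propagated.
* INSD and SBA are modelled independently; their joint distribution is
  out of scope.
* The region hierarchy shares the country-level σ at the region level —
  a simplification acceptable for its default-off, exploratory role.
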
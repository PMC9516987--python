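# Methods

`sdqmap` implements two complementary Bayesian views of small-area
variation in preschool children's social, emotional and behavioural
difficulties, as screened by the teacher-completed Strengths and
Difficulties Questionnaire (SDQ), together with the synthetic-data,
diagnostic and reporting machinery needed to exercise them end to end.

## Outcome: the SDQ total difficulties score

The SDQ has 25 items on a 0/1/2 scale in five domains (emotional
symptoms, conduct problems, hyperactivity/inattention, peer problems,
prosocial behaviour). The four difficulty domains sum to a total out of
40. UK preschool banding classifies 0–10 as close to average, 11–14 as
slightly raised, 15–17 as high and ≥ 18 as very high; a total of 15 or
more ("high") flags a high likelihood of psychiatric disorder and is the
event the disease-mapping model counts. The item→domain map and the
reverse-scored item set live in a YAML configuration
(`sdqmap/data/sdq_teacher_items.yaml`) so that form variants with
different wording share one scoring engine. Partially completed forms
follow the standard SDQ convention: a domain with at least 3 of its 5
items answered is prorated (rounded mean × 5); if any difficulty domain
has fewer, the total is missing and the child is later excluded.
Children are excluded if they live outside the study area, lack a date
of birth, are under 4 or over 6 years at school entry, have a
missing/invalid postcode, or have no total score; the tally reports both
per-reason counts and the overlap-adjusted union.

## Model 1: Poisson disease mapping of ward-year high-score counts

For ward *j* and cohort *t* (coded *t* = year − first year, so
exp(β₀) is the first-cohort baseline rate),

    Y_jt ~ Poisson(E_jt · θ_jt)
    log θ_jt = β0 + (β1 + u1_j)·t + u0_j + Σ_k βk·x_jkt

with the number of assessed children E_jt as exposure, exchangeable
ward intercepts u0_j ~ N(0, σ²_u0), optional differential trends
(random slopes) u1_j ~ N(0, σ²_u1) — independent by default, bivariate
normal with a free correlation when requested — and ward-level
covariates (proportion outside the expected school-start age 4.5–5.5,
proportion of boys, proportion in the most deprived quintile). Although
the model is conventionally written per ward, the cohort trend implies
ward × year observations; the fit uses the 21 × 8 ward-year table.
Ward effects are unstructured (exchangeable, not spatially smoothed)
by default because the Moran screen of residuals is the arbiter of
structure: a spatially structured prior is only warranted when residual
spatial correlation is detected, and the screen is part of the
pipeline. When the screen does detect correlation, an intrinsic-CAR
(ICAR) option smooths the ward intercepts toward their queen
neighbours (`DMSpec(spatial_structure="icar")`, adjacency required);
its full conditionals couple neighbouring wards, so those updates run
sequentially rather than vectorized, and the pairwise-difference
precision uses the rank-deficiency-corrected Gamma(shape + (J−1)/2, ·)
full conditional.

A Gaussian sensitivity variant replaces the count outcome with the
ward-year **median** score and a normal likelihood with unknown
observation variance, keeping the same linear predictor; it exists to
ask whether any ward heterogeneity survives when the outcome is the
middle of the score distribution rather than its upper tail.

## Model 2: ZINB multilevel model of individual scores

Child *i* in preschool *k* and ward *j* has

    Y_ijk ~ ZINB(λ_ijk, p, r)
    log λ_ijk = β0 + (β1 + v1_j)·t + α_k + v0_j + β'φ x_i

where ZINB is the structural-zero mixture
P(0) = p + (1−p)·NB(0; λ, r), P(y>0) = (1−p)·NB(y; λ, r) with the
negative binomial in mean/size form (variance λ(1+λ/r) at p = 0). A
zero-inflated — not hurdle — formulation is used; p and r are global
scalars (no covariates enter the zero component). Individual covariates
are sex, age centred on 59 months and squared (no linear age term), and
deprivation quintile as four dummies against the least-deprived
reference. Preschool effects α_k ~ N(0, σ²_preschool) and ward effects
v0_j ~ N(0, σ²_ward) are cross-classified: preschools draw children
from more than one ward, so neither factor nests the other.

## Priors

Weakly informative throughout: N(0, 1000) on every fixed effect,
Gamma(1, 0.0005) on each random-effect precision 1/σ² (and on the
Gaussian observation precision in the median variant), uniform on the
zero-inflation p, uniform on the intercept–slope correlation where
used, and a diffuse Gamma(1, 0.01) on the overdispersion r (prior mean
100, effectively flat over the plausible 0.5–10 range). All are
configurable via `PriorConfig`.

## Inference

Both models are fitted by an adaptive random-walk
Metropolis-within-Gibbs sampler written for this package:

* fixed effects update coordinate-wise against **centred** design
  columns (the intercept is nearly orthogonal to trend and covariates;
  draws are converted back to the uncentred parameterization when
  stored), with per-coordinate Robbins–Monro step-size adaptation
  targeting 0.44 acceptance, frozen after warmup;
* each set of exchangeable effects has independent full conditionals
  given the rest, so all groups are proposed and accepted/rejected in
  one vectorized pass per sweep;
* random-effect precisions are drawn from their conjugate Gamma full
  conditionals, followed by an **interweaving rescale move**: a scalar
  Metropolis step on log σ² in the non-centred parameterization
  (u = σz with z fixed), which breaks the funnel-shaped dependence
  between a small variance and its effects — without it the variance
  components mix an order of magnitude more slowly;
* p (logit scale) and r (log scale) update by scalar Metropolis steps;
  the per-child negative-binomial log-likelihood vector is cached so a
  p-proposal costs O(n) without re-evaluating gamma functions.

Identifiability of the intercept alongside exchangeable effects is
handled by post-hoc centring: each stored draw is transformed to
sum-to-zero effects with the mean folded into the intercept (and the
slope mean into the trend). This is an exact reparameterization of each
draw, so every identified quantity is unchanged and the reported
Σ_j u0_j is zero to machine precision.

Defaults are 4 chains × (2000 warmup + 2000 kept) sweeps. Convergence
is summarised by split-R̂ and ESS (arviz) over all parameters; a fit is
flagged unconverged when max R̂ ≥ 1.05 (configurable — chains of the
default length do not resolve a 1.01 criterion for this sampler family),
and RR summaries are withheld for flagged fits unless forced.

## Relative rates, exceedance and DIC

All effects are reported as relative rates RR = exp(parameter) with
central 95% credible intervals: exp(u0_j)/exp(v0_j) are ward RRs
against the city average, exp(α_k) preschool RRs, exp(β1) the per-cohort
multiplicative trend. The exceedance probability Pr(RR > 1) is the
posterior fraction of draws above zero on the log scale; values ≥ 0.8
flag high-certainty elevation and drive the binary emphasis class on
exceedance maps.

Model building is forward and DIC-driven: DIC = D̄ + pD with
pD = D̄ − D(θ̄), using the **conditional** focus (deviance given the
random effects, p and r, plugged in at posterior means). Random-effect
terms (slopes; the preschool effect) are retained only when they lower
DIC by more than a tolerance (default 1); covariates are retained unless
their removal lowers DIC by more than the same tolerance, since they
shift the ward variance even when their own interval spans 1. Because
the DIC focus used by other software is generally unspecified, absolute
DIC values are not comparable across implementations; only
within-build differences are interpreted.

## Spatial and residual diagnostics

Queen adjacency (wards sharing any border segment or corner point) is
derived from the tessellation's ridge structure at generation time and
recomputed geometrically (shapely) for user-supplied GeoJSON. Global
Moran's I uses binary weights, I = (n/S₀)·(Σ w_ij z_i z_j)/(Σ z_i²),
with permutation inference (two-sided on |I − E[I]|,
E[I] = −1/(n−1)) — 21 wards are far too few for the normal
approximation. Model residuals are simulation-based scaled residuals:
for each observation, posterior-predictive replicates are drawn (each
under a fresh posterior draw) and the randomized PIT rank of the
observed value among them is returned, with uniform tie-breaking for
the discrete outcomes; under a correctly specified model these are
exactly Uniform(0,1). Residuals averaged by ward feed the Moran screen
whose verdict (α = 0.05, configurable) decides between unstructured and
spatially structured ward effects. One genuine subtlety of the
synthetic design: because a fraction of children attend preschools
homed in an adjacent ward, neighbouring wards share preschool-level
misfit, so the screen can legitimately detect mild spatial correlation
in multilevel-model residuals even though the ward effects themselves
are exchangeable — the screen is reporting a real feature of the
crossed design, not a false positive.

## Synthetic data generator

The generator is the package's stand-in for the study population, which
is not public. It emulates: ~35,000 children (default 35,171) over 8
yearly cohorts with the study's relative cohort sizes, 21 wards, 180
preschools, 51.07% boys, school-start ages drawn uniformly in months
within four bands weighted as observed (6.0 / 46.8 / 43.5 / 3.7%),
within-city deprivation quintiles whose ward composition varies
(Dirichlet draws around the city marginals, concentration 8), and
scores drawn from the ZINB model above with the study's adjusted
posterior means as generating truth (β0 = log 4.079, cohort log 1.008,
male log 1.370, age² log 1.003, deprivation contrasts log 1.115–1.243,
σ²_ward = 0.013, σ²_preschool = 0.062). Preschools are homed one per
ward first, the rest proportional to ward population; a child attends a
home-ward preschool with probability 0.92 and an adjacent-ward
preschool otherwise, producing genuine cross-classification.

The zero-inflation and overdispersion defaults (p = 0.15, r = 1.4) are
calibrated once to the study's descriptive score distribution (median
4, IQR 1–9, 9.0% of children ≥ 15): with these values the default
simulation yields ≈ 9.3% high scorers, median 4, IQR 1–8. Scores are
drawn unbounded and values over 40 rejected and redrawn, preserving the
fitted family on the observed support; a warning is logged when more
than 1% of draws exceed 40. Every random effect drawn is recorded in a
ground-truth ledger keyed by ward/preschool id for recovery testing.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: real ward shapes and adjacency, postcode
geography, any informative missingness (exclusion noise is independent
contamination), rater effects beyond a static preschool intercept,
cohort-varying preschool participation patterns beyond random cohort
assignment, and any spatial correlation between neighbouring wards
(ward effects are exchangeable by construction, matching the model but
not necessarily reality).

One consequence of the bounded support worth knowing: fitting the
untruncated ZINB to truncated-at-40 data attenuates the largest effect
RRs slightly (≈ 0.02 on the RR scale for sex and the most-deprived
contrast) and inflates the baseline exp(β0) by roughly 3–5%. This is a
property of the generative design, not a sampler defect; recovery
checks therefore target the effect RRs, and intercept recovery is
judged on a relative scale.

## Problem sizes and numerical choices

Parameter-recovery checks run at 5,000 children / 60 preschools / 21
wards / 8 cohorts per replicate, averaged over seeds — large enough
that effect-RR averages resolve to ±0.05 while many replicates remain
cheap. Structure-decision (forward-build) checks use 5,000 children and
40 preschools: with fewer than ~100 children per preschool the free NB
overdispersion absorbs between-preschool variance almost completely and
the conditional-DIC gain from a real σ²_preschool = 0.06 falls below
any sensible retention tolerance. Ward-year count fits are effectively
instant and run at the full 21 × 8 layout throughout.

Other numerical choices: ward-year aggregation uses half-open age bands
[4,4.5), [4.5,5), [5,5.5), [5.5,6]; table percentages round half-up to
1 decimal; quartiles use lower-nearest-rank interpolation so integer
score IQRs print as integers; the permutation p-value uses the
(1 + #extreme)/(B + 1) estimator; exceedance uses a non-strict ≥ 0.8
flag; degenerate inputs (single ward, single cohort, all-zero outcome)
either drop the unidentifiable term with a warning or refuse with a
clear error, as documented per function.

## Known limitations

* The sampler is a random-walk method: posterior tails of the variance
  components at very small true values are explored more slowly than a
  gradient-based sampler would; R̂ thresholds and chain lengths are set
  accordingly.
* Conditional DIC (the only focus computable without marginalising the
  effects) penalises random effects more weakly than marginal DIC;
  retention tolerances are calibrated to this focus.
* The median-score sensitivity variant treats the integer ward-year
  median as Gaussian; with only 168 observations its variance posterior
  is diffuse.
* Exclusion contamination is independent across criteria, so the
  overlap-adjusted union behaves binomially; real administrative
  missingness is likely clustered.
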
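# Methods

## Model and estimands

The unit of analysis is one survey wave within a stratum (gender ×
optional region, or the pooled sample). Within a wave, a respondent's
binary outcome y follows a random-intercept logistic model on the
fractional-rank SES score x ∈ (0, 1]:

    logit P(y = 1 | x, cluster j) = β₀ + β₁ x + u_j,   u_j ~ N(0, σ_u²).

The estimands carried forward are the prevalence extremes
P(0) = expit(β₀) and P(1) = expit(β₀ + β₁): model extrapolations to the
origin and top of the SES scale for a cluster at the random-effect
median (u = 0). The trend of interest is the line P(0) = a + b·P(1)
across waves; its intercept a is the low-SES prevalence left when
high-SES prevalence reaches zero, and the *likelihood of eradication*
is the probability, under coefficient uncertainty, that the fitted
line's first axis crossing lies within the eradication threshold
(default 0.05) of the origin.

Assumptions worth stating plainly: the SES–log-odds relationship is
linear in the fractional rank within each wave; the P(0)–P(1)
relationship is linear across waves (a quadrennial four-wave design
gives the line only two residual degrees of freedom); waves are
independent; and the trend is interpretable as a scenario only when
prevalence declines at both ends of the scale.

## SES score

Household education is the maximum of the two parents' ordinal levels,
using the non-missing parent when one is missing; rows missing both (or
missing the outcome) are excluded and counted. Within a country,
category ties receive the mean of the ranks the category occupies, and
ranks are divided by the number of *scored* respondents in that
country, so the mean score is exactly (n+1)/2n and the score is
invariant to row order. Ranking pools waves within country by default —
the scale then means the same thing in every wave — with a `per-wave`
switch for strictly cross-sectional scoring. Gender-stratified analyses
use ranks computed on the full country sample.

## Estimation

The marginal likelihood integrates u_j out per cluster with *adaptive*
Gauss–Hermite quadrature: nodes are centred at each cluster's
conditional posterior mode (found by Newton iterations on the concave
joint density, tolerance 1e-10) and scaled by the local curvature;
15 nodes by default, one node giving the Laplace approximation. The
implementation agrees with brute-force trapezoid integration to ~1e-9
on toy data and with lme4's `glmer(nAGQ = 15)` to ~1e-5 on moderate
fits. L-BFGS-B maximizes over (β₀, β₁, σ_u) with σ_u ≥ 0, projected-
gradient tolerance 1e-8, 200 iterations maximum; non-convergence and
single-outcome (separated) strata are flagged and excluded downstream,
never silently accepted. A stratum with fewer than two clusters falls
back to ordinary logistic regression with a logged notice.

The reported variance-covariance matrix is the fixed-effects block of
the inverse observed information over all three parameters (central
finite differences, relative step 5e-4); when σ̂_u sits at the zero
boundary the information is computed over the fixed effects alone.
σ_u uncertainty is not propagated further: the simulation stage draws
only (β₀, β₁), whose inverse-logit transforms are the quantities of
interest.

## Simulation and confidence regions

Per stratum × wave, `n_sim` (default 10,000) coefficient vectors are
drawn from N((β̂₀, β̂₁), V̂). Intervals for P(0) and P(1) are percentile
(2.5, 97.5) ranges of the transformed draws — the same draws later fit
the simulated trend lines, so the CIs come free and are internally
consistent with the eradication computation. The 95% confidence region
is constructed in coefficient space as the level-set ellipse of the
draws' fitted Gaussian (radius √χ²₂,₀.₉₅), discretized at 360 boundary
points and mapped through the inverse logit; the mapped curve is not an
ellipse and visibly bends near zero prevalence, which is the correct
image of the coefficient-space region rather than an artefact. Draw
streams are derived from one master seed via a CRC of the stratum/wave
label, so any stratum reproduces independently and two runs with the
same configuration are byte-identical.

## Trend and eradication

The trend line is unweighted OLS of P(0) on P(1), one point per wave —
with only four waves, wave-level precision weighting would be hard to
justify and is not offered. Simulated lines pair draw i across waves;
since waves are independent, any pairing is distributionally
equivalent, and the fixed pairing keeps results deterministic. For each
line, travelling in the direction of declining P(1): a nonnegative
intercept means the y-axis is crossed first at (0, a); a negative
intercept with positive slope means the x-axis is crossed at (−a/b, 0);
a negative intercept with non-positive slope never meets either axis at
a nonnegative coordinate and counts as non-eradicating (its frequency
is reported). A line eradicates when its crossing coordinate lies in
[0, threshold), threshold 0.05 — strict inequality matching the "<5%"
definition of the target. Negative intercepts are legitimate results:
they describe trends that favour the low-SES group, and route through
the x-axis rule. Simulated draw sets with identical P(1) across waves
(slope undefined) are excluded and counted, aborting if they exceed 1%.
The intercept CI is the percentile range of simulated intercepts; being
a nonlinear functional, it need not bracket the plug-in intercept,
though in practice it does.

## Synthetic data

The generator emulates repeated cross-sectional school surveys: fresh
clusters per country × wave, respondents' education categories drawn
from country-specific distributions (flat-Dirichlet-sampled when not
supplied) over a five-level scale, and outcomes Bernoulli with logit
β₀(t) + β₁(t)·x + u_j. Crucially the effect applies to the *ranked*
score computed by the pipeline's own rule, so generator truth and
pipeline truth coincide and recovery tests are exact in expectation.
`scenario_from_line` inverts a target line: given per-wave P(1) values
and (slope, intercept) it sets β₀ = logit(P(0)), β₁ = logit(P(1)) −
logit(P(0)) per wave.

What the generator does *not* emulate: nonresponse and missingness
patterns, school sampling frames, post-stratification weights, ordinal
category effects distinct from their ranks, or non-linear time trends.
Passing tests therefore demonstrate the estimator and simulation
machinery are correct under the stated model, not that the model is
adequate for any particular real survey.

Default sizes are 10 countries × 20 clusters × 25 respondents × 4
waves (20,000 rows). Scale-sensitive checks — end-to-end recovery of a
known line geometry and the eradication-likelihood magnitude — use 100
respondents per cluster (≈20,000 per wave, ≈80,000 total), the scale at
which the intercept's simulation SE (~1.5 percentage points) makes
"eradication unlikely" scenarios resolvable: at a quarter of that size
the SE roughly doubles and a true intercept of 9.4% yields a
non-negligible simulated probability of crossing inside the 5% zone no
matter how the estimator behaves. Parameter-recovery checks use 100
clusters × 100 respondents; interval-coverage checks use 200 replicates
of 30 clusters × 30.

## Numerical choices and edge cases

- Education missing codes are mapped at read time via the schema;
  validation reports offending row numbers.
- Zero-variance draw covariances collapse regions to a point/segment,
  flagged rather than erroring.
- The eradication boundary case a = 0 counts as a y-axis crossing at
  the origin (eradicating for any positive threshold).
- `rank(method="average")` ties and the (0, 1] score convention mean
  the lowest possible score is 1/n, never 0 — P(0) is always an
  extrapolation, matching the SII/RII convention.
- SVG output pins matplotlib's `svg.hashsalt` so identical runs give
  identical files.

## Known limitations

Single random-intercept only (no nested class-in-school levels); no
survey weights or missing-data imputation; linear trend only — with
four waves, curvature in the P(0)–P(1) relationship is absorbed into
the line; confidence regions grow rapidly for small strata, and
single-country analyses will often be uninformative.
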
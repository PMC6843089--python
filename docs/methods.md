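# Methods

## The decision model

The package analyzes cued multialternative change detection with a
multidimensional signal-detection model (m-ADC). A session presents, on each
trial, a cue toward one of several locations; a change of magnitude θ
(orientation, degrees) then occurs at one location — or at none (catch
trial) — and the observer reports the change location or "no change". The
observer is modeled with one unit-variance Gaussian decision variable Ψ_k per
location (independent components, identity covariance; no variance parameters
are fitted). A change of magnitude θ at location k shifts E[Ψ_k] by the
sensitivity d′_k(θ); the observer holds one criterion c_k per location and
responds

    argmax_k (Ψ_k − c_k)   if the maximum is positive, else "no change".

This planar-boundary rule yields the choice probabilities

    P(respond j | μ) = ∫₀^∞ φ(u + c_j − μ_j) Π_{k≠j} Φ(u + c_k − μ_k) du,
    P(no change | μ) = Π_k Φ(c_k − μ_k),

with μ the condition's mean vector. The criteria are uniform across
magnitudes: magnitudes are interleaved unpredictably, so a magnitude-specific
threshold is not available to the observer.

Derived bias measures per location: the choice-criterion bias
b_CC = c − d′_av/2 (d′_av = unweighted mean of d′ over magnitudes) and the
likelihood-ratio bias b_LR = exp(−d′_av·b_CC), the density ratio at the
criterion for equal-variance Gaussians. Lower b_CC / higher b_LR = more
liberal responding at that location. Cue-induced modulation of any parameter
x is summarized by ADI = x_cued − mean(x_uncued) and
AMI = (x_cued − x_uncued)/(x_cued + x_uncued).

## Numerical evaluation of the choice integrals

The 1-D integrals are evaluated with 160-node Gauss–Legendre quadrature on
(0, U), U = max(8, max|c − μ| + 8), vectorized over all stimulus conditions.
The integrand is analytic with a Gaussian tail, so the fixed rule converges
spectrally; tests verify agreement with adaptive quadrature
(`scipy.integrate.quad`, abstol 1e-13) to better than 1e-10, and the
one-location reduction to the Yes/No closed form Φ(d′−c)/Φ(−c) to 1e-10.
Fixed-order quadrature was chosen over adaptive because maximum-likelihood
fitting evaluates the integrals thousands of times. Rows are renormalized to
sum exactly to 1 (slack ~1e-12).

## Estimation

Parameters are fit by maximizing the multinomial log-likelihood of the
stimulus-response contingency table: one d′ per (location, magnitude) — or a
Naka-Rushton profile d(θ) = d_max·θ²/(θ² + θ50²) per location in parametric
fits, exponent fixed at 2 — plus one criterion per location. The optimizer is
bounded L-BFGS-B with d′ ∈ [0, 8], c ∈ [−5, 5], d_max ∈ [0, 8],
θ50 ∈ [0.5, 300]; starts are an inverse-Gaussian SDT warm start (d′ from hit
rates, c from false-alarm rates) plus seeded random restarts (default 2),
because the likelihood can be locally flat for sparse cells. Zero cells need
no continuity correction (the multinomial handles them). Constrained variants
share the uncued d′ profile (eq-d) or the uncued criterion (eq-c) and are
compared by AIC (ties broken toward fewer parameters); BIC is also reported.

Parameter counting: the 4-location, 6-magnitude table has 28 free parameters
and 100 independent proportions (24 hits + 72 mislocalizations + 4 false
alarms); the collapsed 3-location table has 21 parameters, 15 under eq-d, 20
under eq-c. The package's direct count of independent proportions for the
collapsed table is 18×3 + 3 = 57 (`count_independent_observations`).

Goodness of fit uses a randomization χ² test: the null distribution is built
by drawing multinomial tables from the fitted probabilities (default 1000
draws; the count is a package default) and p follows the add-one rule. Cells
with expected count < 1 are pooled into their row's largest expected cell.
Subset-prediction fits (hits+FA, FA+misses, hits+misses) maximize the
multinomial likelihood over the named cells with each row's complement pooled
into one category (correct rejections enter implicitly as the catch-row
complement in the first two cases and explicitly in the third), then score
the held-out cells with the same randomization test.

When fitting Naka-Rushton curves to d′-by-magnitude values directly
(least squares), θ50 is bounded at 1.5× the largest sampled magnitude and
d_max at 10: beyond the sampled range the half-saturation point trades off
freely against the asymptote, and unbounded fits run away on noisy,
non-saturating data (this matters for permutation nulls, where shuffled
tables are flat). Jackknife SEs on pooled fits are leave-one-subject-out;
within subject, block-level variability uses leave-one-block-out.

## Decision optimality

Costs are parameterized by the cost ratio β = (C_CR − C_FA)/(C_Hit − C_Miss)
with C_Hit = C_CR/β, C_Miss = C_FA/β, and mislocalizations costed as misses;
β = 1 corresponds to maximizing percent correct. In the ΔRisk surface the
correct responses are rewarded (C_CR = −1, so C_Hit = −1/β) and errors
penalized (C_FA = ratio, C_Miss = ratio/β): if C_CR and C_FA shared a sign,
the criterion-relevant weight C_FA − C_CR would vanish at ratio 1 and flip
sign below it, degenerating the surface; with opposite signs the weight stays
positive over the whole ratio grid while β keeps its meaning.

Optimal criteria minimize Bayes risk within the planar family by numerical
minimization (L-BFGS-B with Nelder-Mead fallback), verified as a local
minimum under ±0.05 single-coordinate perturbations (within the bounds; an
optimum may legitimately sit on a bound when one policy dominates).
Multi-magnitude observers are reduced to their magnitude-marginal d′ first.

The observed cost ratio has two forms. The prior-odds form
β_obs(j) = [p_j/p_∅]/b_LR(j) is exact for one location. With several
locations the criteria couple through the shared decision rule, and the exact
per-location inversion of the risk-stationarity condition

    β_obs(j) = − ∂[Σ_i p_i P(hit_i)]/∂c_j ÷ [p_∅ · ∂P(CR)/∂c_j]

(central differences, step 1e-5) is also provided; it reduces to the
prior-odds form at m = 1 and satisfies the round trip
criteria = optimal(β) ⇒ β_obs = β exactly, which the prior-odds form misses
by up to ~0.1 at β far from 1.

The subjective optimal cost ratio β^s_opt minimizes
ΔRisk = Risk(observed criteria) − Risk(optimal criteria at β) over a grid of
50 log-spaced β in [0.25, 4] × 20 cost ratios in [0.5, 2]; ΔRisk ≥ 0 with
equality exactly when the observer's criteria are β-optimal, so the surface
is minimized at the cost ratio the observer behaves as if holding. Because
the grid spacing near β ≈ 1.3 (~6%) exceeds the recovery precision of
interest, a bounded continuous refinement around the grid argmin is applied
by default; β^s_opt is the median of the per-cost-ratio minimizers.
Suboptimality indices (natural log throughout; any base only rescales):
SI_O = |ln(β^s_opt/β_opt)| with β_opt = 1, SI_G = ΔRisk at β^s_opt,
SI_L(j) = |ln(β_obs(j)/β^s_opt)|.

Expectation-only accounts of the false-alarm distribution are tested with
multinomial χ² randomization tests: maximization (all false alarms at the
max-prior location — a point-mass null, so any off-maximal false alarm is an
exact p = 0 rejection), matching of task priors, and matching of perceived
priors (each subject's share of change-trial responses per location).

## Risk curvature

The risk curvature R_C at a location is the second derivative of Bayes risk
with respect to that location's criterion at its optimum, other criteria held
at optimum; ΔR_C = R_C(cued) − R_C(uncued) indexes how much more sharply
criterion misplacement is penalized at the cued location, independent of the
observer's expectations. Sweeps use 21 grid points over ±1.0 noise-SD units
(the span is the analysis's definition; the resolution is a package choice —
halving the step changes R_C by <1% because the risk is quadratic-dominated
near the optimum), and R_C is the central second difference at the center
(exact for quadratic risk at any step). With more than one uncued location
the uncued curvature is the prior-weighted mean across uncued locations.
Subject-level ΔR_C uses costs at the subject's own β^s_opt by default, with
β = 1 as the configurable alternative.

The 2-location simulation suite (equal d′ = 1.0, β = 1, no-change prior 0.25
— the task's catch rate, used because the simulation's own value is a free
choice) maps R_C against signal probability and ΔR_C against the cued/uncued
prior ratio and against the (ADI b_CC, ADI d′) plane. Over d′_cued ∈ [1, 5]
at d′_uncued = 1 the ΔR_C cross-section in ADI d′ rises then falls, while the
cross-section in ADI b_CC (traced by the prior ratio at equal d′) is
monotone — the qualitative signature that separates bias-driven from
sensitivity-driven curvature differences.

σ(b_CC), the jackknife SD of the choice-criterion bias across blocks
(leave-one-block-out refits, sqrt((n−1)/n·Σ(b_(i)−b̄)²)), is the companion
data-driven precision measure; it scales as 1/√(trials per block).

## Behavioral statistics

RTs are trimmed per subject at mean ± 3 SD and normalized by the
across-subject median of per-subject mean cued-location RT (the divisor is a
subject-level median; trial-level is the other reading of the convention —
the choice is configurable and by construction puts the median normalized
cued mean at 1). The percentage-bend correlation (Wilcox; bend constant 0.2,
the conventional default) is implemented in-package and cross-checked against
pingouin's estimator in tests; partial correlations use the closed form with
a t-approximation on n−3 df. The RT regression standardizes all predictors
(magnitude, d′_av, bias) to zero mean unit variance, and compares |β_bias|
vs |β_d′| against a permutation null built by shuffling location labels of
the d′ and bias values independently within subject (default 10⁴
permutations; add-one p-values everywhere). Linear-vs-quadratic fit
comparison reports sse/(n−m−1) and adjusted R²; incremental adjusted R² is
the gain from adding a factor to the multiple regression. Random-effects
ANOVAs (split-half covariation, motor-bias control) use statsmodels MixedLM
with subject random intercepts, falling back to OLS (flagged) when the
random-effect covariance is singular — which is the expected outcome for
exchangeable synthetic subjects. Multiple comparisons use Benjamini-Hochberg
via statsmodels where applicable.

## Synthetic cohorts

The generator reproduces the session's probabilistic structure exactly: 288
trials in 6 blocks of 48; 25% catch; conditional validities 2/3 : 1/6 : 1/12
: 1/12 (collapsed: 2/3 : 1/6 : 1/6), forcing per-session event counts (72,
144, 36, 18, 18) with magnitudes spread evenly within location; schedules
are exact-count stratified and shuffled by the seeded stream (i.i.d. draws
would let the realized proportions drift). A neutral-cue variant makes
changes equally likely at the four locations. Cohort defaults (30 subjects)
encode the structure the analyses are designed to detect: spotlight-like
sensitivity (d_max ≈ 2.6 cued vs ≈ 1.4 uncued, θ50 lower at the cued
location) and graded criteria (1.0 / 1.15 / 1.35), with between-subject SDs
of 0.35 (d_max), 3° (θ50) and 0.12 (criterion) chosen to give clearly
overlapping but distinguishable subjects at 288 trials. RTs are a linear
function of (−b_LR, −d′) at the responded location with multiplicative
lognormal noise (σ = 0.18) — the simplest generative model that exercises
every RT analysis; it is synthetic scaffolding, not a process model. The
generator is deterministic under its seed at every stage; all randomness
derives from explicit seeds or child streams.

One structural consequence of the defaults: criteria are sampled
independently of sensitivity, so b_CC = c − d′_av/2 is *mechanically*
anticorrelated with d′ across synthetic subjects. Analyses of
sensitivity-bias covariation on this cohort therefore measure the pipeline's
behavior under a known coupling, not a claim about real observers.

What passing tests on this cohort do and do not show: they validate the
estimators, their calibration, and the internal consistency of the pipeline
under the model's own assumptions (independent equal-variance Gaussian
evidence, stationary criteria, exact stratified schedules). They do not
validate those assumptions against real observers — real data bring
sequential dependencies, learning and lapses, unequal-variance evidence, and
gaze-contingent exclusions that the generator deliberately omits.

## Problem sizes used in verification

Analytic-vs-simulation agreement uses 10⁶-draw brute-force simulations of
the decision rule across ≥20 random observers (3 SE per cell). Parameter
recovery uses 2×10⁴ trials per condition (±0.05 on every d′ and c); cost-
ratio recovery uses 10⁵-trial sessions at β ∈ {0.5, 1, 1.3, 2} (±0.05).
Null calibrations run 200–300 replicates at reduced trial counts with
99–199 randomizations each, giving exact 5%-achievable p-value grids.
Model recovery simulates 100 subjects at the task's 288-trial session
length. These sizes are the package's verification conditions; the analysis
drivers run the full 30-subject cohort at study scale.

## Known limitations

- The exact optimal decision manifold for constant-stimulus designs is not
  reconstructed; the planar-boundary family (which parameterizes the fits)
  is used throughout, and its optimality is verified only locally.
- Unequal-variance and correlated-noise variants, confidence ratings, and
  hierarchical/Bayesian inference are out of scope.
- The prior-odds β_obs is exact only for one location; the stationarity
  inversion is provided for multi-location work.
- b_LR follows the exp(−d′·b_CC) convention (noise/signal density ratio at
  the criterion); users comparing with signal/noise-ratio conventions should
  invert it.
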
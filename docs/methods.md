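# Methods

## Task design

The generator reproduces the arithmetic of the probabilistic SR-congruence
task: 10 blocks × 40 trials, block-wise Bernoulli match probability in
{0.1, 0.3, 0.5, 0.7, 0.9}, each context occurring twice, 0.5 contexts in
the first and last blocks, and consecutive contexts differing by at least
0.4. Within a block the number of match trials is exactly
round(p·40) (36:4, 28:12, 20:20, 12:28, 4:36), so context totals over a
schedule are 72:8, 56:24, 40:40, 24:56, 8:72 and only trial *order* varies
with the seed.

These constraints do not pin down a unique block order. We fix one
canonical order, `[0.5, 0.1, 0.7, 0.3, 0.9, 0.1, 0.7, 0.3, 0.9, 0.5]`, in
which each of the four non-0.5 contexts is visited once before any
repeats; the second counterbalancing order is its reverse, and an override
is accepted for labs that used a different realisation. Cue identity is
balanced within every block-by-trial-type cell (all cell counts are even),
which makes both the cue and the stimulus marginals exactly 200:200 per
schedule — the design property that leaves only cue-relative congruence
predictable. Presentation timing (cue–stimulus delay, inter-trial
interval) never enters any computation and is not modelled.

## Perceptual models

**Binary 3-level HGF.** States: x₁ the binary outcome, x₂ its log-odds
tendency, x₃ the log-volatility of x₂. The trial update is the standard
binary-HGF recursion: predictions μ̂₂ = μ₂, μ̂₁ = s(μ̂₂), μ̂₃ = μ₃ with
prediction variances σ̂₂ = σ₂ + exp(κμ̂₃ + ω₂) and σ̂₃ = σ₃ + exp(ω₃);
outcome prediction error δ₁ = u − μ̂₁; level-2 posterior precision
π₂ = 1/σ̂₂ + μ̂₁(1−μ̂₁), μ₂ ← μ̂₂ + δ₁/π₂; volatility prediction error
δ₂ = (σ₂ + (μ₂−μ̂₂)²)/σ̂₂ − 1 with weight w₂ = exp(κμ̂₃+ω₂)/σ̂₂, and
π₃ = 1/σ̂₃ + (κ²/2)·w₂(w₂ + (2w₂−1)δ₂), μ₃ ← μ̂₃ + σ₃(κ/2)w₂δ₂.

Parameter choices: κ is fixed at 1; the level-3 meta-volatility parameter
(often written ϑ) is carried as exp(ω₃), so both levels expose a tonic
log-volatility with Gaussian priors N(−4, 1) and N(−2, 1). Initial states
are fixed, not estimated: μ₂⁰ = 0, σ₂⁰ = 0.1, μ₃⁰ = 1, σ₃⁰ = 1 (the
standard binary-HGF configuration convention). μ̂₁ is clipped to
[1e−8, 1−1e−8] before entering precisions. A non-positive π₃ raises an
invalid-trajectory signal, which the fitting layer converts to an infinite
objective (the parameter set is rejected, not patched).

The **effective learning rate** plotted per trial is defined as the
fraction of the outcome prediction error absorbed into the next outcome
prediction, (s(μ₂) − μ̂₁)/δ₁, zero when δ₁ = 0. This quantity lies in
[0, 1], peaks after block transitions, and decays within stable blocks;
other definitions (e.g. 1/π₂ based) change the scale but not these
qualitative features.

**Rescorla–Wagner.** v ← v + α(u − v) with α ∈ (0, 1) and v⁰ = 0.5. The
fixed learning rate is the null hypothesis against volatility-adaptive
learning.

## Response models

**Linear log-RT (HGF pairing).** Log RT is the natural log of RT in
milliseconds — the β₀ prior mean 6.2146 ≈ ln 500 ms is only meaningful on
that scale; files carry RT in seconds and the conversion happens at the
model boundary. Predicted log RT is
β₀ + β_S·S + β_σ1·μ̂₁(1−μ̂₁) + β_σ2·σ̂₂ + β_v·exp(μ̂₃), with Shannon
surprise S = −ln μ̂₁ on match trials, −ln(1−μ̂₁) otherwise. Slopes carry
N(0, 4) priors; the noise variance ζ is estimated on the log scale with
prior N(1.0972, 0.6931). Predictions are defined on every trial; missing
trials are skipped only in the likelihood.

**Gaussian observation (RW pairing).** The per-trial mean is the raw prior
belief v_pred. This is the literal continuous-response pairing and its
predictions live on [0, 1] against log-ms observations, producing
residuals of ~5–6 log-units; that scale mismatch is a property of the
model pair being compared, so it is kept as the default, with a rescaled
variant available explicitly rather than silently.

**Shifted Wald.** A response is the first passage of drifting Brownian
motion through a single boundary: density a/√(2πw³)·exp(−(a − v·w)²/(2w)),
w = t − t₀, with threshold a = 1 (fixing the scale degeneracy) and
non-decision offset t₀ = 0.2 s. Drift couples the belief aligned to the
observed trial type, b_t = p(observed outcome), to the base rate:
v_t = v₀ + c·((b_t − ½) − (μ̂₃,t − mean μ̂₃)) for the HGF (the centred
volatility term slows responses when the world seems unstable) and
v_t = v₀ + c·(b_t − ½) for the RW. The single-coefficient combination of
the level-1 and level-3 quantities is one defensible reading of "a linear
combination" with one printed coefficient; it is isolated in
`drift_from_beliefs` so alternatives are one-function replacements. Drift
is floored at 0.1 s⁻¹ to keep the density proper under extreme beliefs.

## Inversion

Fitting maximises log p(y|θ) + log p(θ) in a transformed space (identity
for volatilities and slopes, log for ζ, logit for α; the RW learning rate
gets a N(0, 1) prior on the logit scale) with L-BFGS-B from 5 starts: the
prior mean plus 4 seeded prior draws. Optimiser tolerances are tight
(relative ftol 1e−9, gtol 1e−7, finite-difference step 1e−6): looser
settings demonstrably stall at the starting point on the flat, noisy
filtered-likelihood surface. The log model evidence is the Laplace
approximation log p(y, θ̂) + (d/2)ln 2π − ½ ln det(−H), with H the
central-finite-difference Hessian at the MAP; a non-positive-definite −H
is jittered, then falls back to a pseudo-determinant with the result
flagged. The inverse of −H also supplies posterior standard errors in the
summary table. Missing trials update beliefs (their input is observed) but
contribute nothing to the response likelihood.

The Wald response model is fitted separately by maximum likelihood over
(v₀, c) with Nelder–Mead from the initial values (6, 1); a cohort helper
first optimises the pooled likelihood and uses the group estimate to
initialise each subject. Trials with RT ≤ t₀ are treated as missing; fewer
than 10 valid trials is an error.

## Model selection

Per-subject LMEs feed the Dirichlet-multinomial random-effects model,
inverted by the variational fixed point u_nk ∝ exp(lme_nk + ψ(α_k) −
ψ(Σα)), α_k = α₀ + Σ_n u_nk, with uniform prior α₀ = 1 and convergence at
‖Δα‖∞ < 1e−6. For two models the exceedance probability is the analytic
Beta tail P(r₁ > ½); for K > 2 it is 10⁶ seeded Dirichlet draws. The
Bayesian omnibus risk compares the variational free energy of the
random-effects solution against the equal-frequency null F₀ =
Σ_n ln((1/K)Σ_k exp(lme_nk)); pxp_k = xp_k(1 − BOR) + BOR/K. Log-sum-exp
is used throughout. Note a small-sample property: with n subjects
unanimously favouring one model, α = [n+1, 1], so xp is capped at
1 − 0.5ⁿ⁺¹ and BOR is bounded away from zero; pxp approaches 1 only as
the cohort grows, and at n = 28 the cap is negligible.

## Behavioural statistics

Mismatch cost is mean RT(match) − mean RT(mismatch) in ms per
subject-by-context cell; negative values are the classic mismatch cost.
Cells lacking either trial type are omitted, never zero-filled, and
inference is restricted to the 0.3/0.5/0.7 contexts because the rare trial
type occurs only 8 times per subject in the extreme contexts. The Friedman
statistic uses average ranks with tie correction; Kendall's W is reported
as χ²/(n(k−1)). Conover post-hocs use the within-subject rank-sum t
statistic with (n−1)(k−1) df and both Bonferroni and Holm adjustments.
Volatility-by-context means are compared with a one-way repeated-measures
ANOVA with Greenhouse–Geisser correction (ε from the covariance of
condition differences) and paired t-tests Bonferroni-adjusted over all 10
context pairs. Cohen's f = √(η²/(1−η²)) converts a partial η² to the
effect size used for power analysis.

## Synthetic cohorts

The generator's defaults are the study conditions: 28 subjects alternating
the two block orders (14/14), 400 trials each, RT from the shifted Wald
with belief-coupled drift (slow-tailed, realistic RT shapes; a log-normal
alternative exists for robustness checks), and responses slower than the
1-s window recorded as missing while their input still updates beliefs.
Subject-level parameter spreads are not dictated by the task, so they are
fixed once at values giving heterogeneous but stable cohorts: ω₂, ω₃ ~
N(prior mean, 0.5²), v₀ ~ N(6, 0.5²) (floored at 1), c ~ |N(1, 0.25²)|.
Per-subject seeds derive from the master seed through a counter-based
SeedSequence scheme, so adding subjects never perturbs earlier ones. At
these defaults the missingness rate is well under 10%.

What the generator does *not* emulate: error responses and their RTs,
response-repetition and handedness effects, fatigue or practice drifts,
autonomic coupling, and any within-block non-stationarity beyond the
design's own probability steps. Passing tests therefore demonstrate that
the pipeline is correct and well-calibrated under the task's generative
assumptions, not that those assumptions exhaust real participant
behaviour.

## Problem sizes and numerical choices

The group-level experiment in `scripts/acceptance.py` and the acceptance
test runs the full 28-subject cohort with 5 optimisation restarts per fit,
the size of the study cohort; smoke tests use 4-subject cohorts and
recovery checks use 20 simulated subjects, sizes chosen to exercise every
code path at desk scale. All sampling-based checks fix seeds; Monte-Carlo
assertions use explicit standard-error bounds. Degenerate inputs are
handled explicitly: identical columns give χ² = 0 (p = 1) in the Friedman
test, constant volatility gives F = 0 with ε = 1, an empty estimation
problem makes the Laplace evidence equal the log-likelihood, and a fully
missing response vector returns the prior means as the MAP.

## Known limitations

- The Laplace LME is a local approximation; strongly multimodal posteriors
  would need sampling, which is out of scope.
- The log-RT and Wald response models are fitted separately (the Wald
  model is a response-generation layer, not a second evidence term), so
  model comparison rests on the log-RT/Gaussian-observation pairings.
- Kendall's W follows the standard χ²-based formula; software packages
  differ in small-sample conventions.
- The RW pairing's scale mismatch makes the model comparison decisive by
  construction; conclusions about *how much* better a volatility learner
  fits require the rescaled variant.
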
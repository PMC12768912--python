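# Methods

## Behavioral model

Choices in the probabilistic selection task are modeled with a
Rescorla–Wagner learner under a logistic (softmax) choice rule. Each of the
six stimuli carries a value Q, initialized at `q_init = 0.5` (the midpoint of
the 0/1 outcome scale; configurable). On a trial presenting symbols i and j,

    P(choose i) = logistic(β (Q_i − Q_j)),

where β ≥ 0 is the outcome sensitivity (inverse temperature). After feedback
R ∈ {0, 1} the chosen symbol's value updates by

    Q ← Q + α (R − Q),

with α = α⁺ (reward learning rate) when the prediction error R − Q is
positive and α = α⁻ (loss learning rate) when negative (the 2-LR variant;
the 1-LR variant uses a single α). A prediction error of exactly zero takes
the α⁺ branch; under 0/1 outcomes and q_init ∈ (0, 1) this is a measure-zero
event. With R ∈ {0, 1} and q_init ∈ [0, 1] the recursion keeps every Q in
[0, 1].

Missed trials ("no response") contribute nothing to the likelihood and leave
Q unchanged. Test-phase trials (no feedback) are scored under the frozen
final Q-values and perform no update. By default they are **included** in
the likelihood (`ModelSpec.include_test=True`): they cover all 15 symbol
pairings and sharply constrain the final values, which measurably improves
the identifiability of the learning rates; a training-only likelihood is
available via the flag. Model-agnostic accuracy analyses always use the raw
choices and are unaffected by this setting.

## Hierarchical structure and priors

Subject-level parameters live on an unconstrained scale
(logit for learning rates, log for β) and are drawn non-centered from
group-level normals:

    θ_pk = μ_k + σ_k z_pk,  z_pk ~ N(0, 1),
    μ_k ~ N(0, 1),  σ_k ~ half-N(0, 1).

These are weakly informative defaults standard for this model family; both
prior scales are configurable (`ModelSpec.prior_mu_sd`, `prior_sigma_sd`).
An optional soft cap on β (`beta_cap`, a scaled-logistic link replacing the
exponential) guards against degenerate greedy solutions on
near-deterministic data; it is off by default.

## Sampler

No gradient-based MCMC backend being part of the package's dependency
surface, sampling is done by a self-contained No-U-Turn sampler
(`glucorl.sampler`): dynamic multinomial HMC with recursive doubling, the
generalized no-U-turn criterion on subtree momentum sums, dual-averaging
step-size adaptation toward a target acceptance statistic of 0.8, and
Stan-style windowed adaptation of a diagonal mass matrix (75-iteration
initial buffer, doubling slow windows, 50-iteration terminal buffer, scaled
down proportionally for short warmups). A transition whose energy error
exceeds 1000 is flagged divergent. The likelihood and its exact analytic
gradient (forward sensitivities dQ/dα propagated through the trial
recursion, compiled with numba) make one gradient evaluation of a
48-participant, 420-trial cohort cost well under a millisecond, so a full
4-chain × (500 warmup + 1000 draws) fit runs in a few minutes on one CPU.

Every fit is gated on the standard Hamiltonian diagnostics: zero
divergences, split-R̂ < 1.1 on every posterior quantity, E-BFMI > 0.3 per
chain, and no treedepth saturation. Breaches raise `DiagnosticError`
(carrying the diagnostics) unless `allow_bad_fit` is set. Split-R̂, ESS, and
E-BFMI are computed through ArviZ; PSIS-LOO model comparison
(participant-level pointwise log-likelihoods, paired standard error on the
elpd difference) also goes through ArviZ. Seeded runs are bit-reproducible;
chains advance sequentially from generators spawned off one seed.

Default draw budget is 4 chains × 1000 post-warmup draws = 4000 total.
Tests and some analysis drivers use reduced budgets (2 chains × a few
hundred draws) chosen as the package's standard quick-look configuration;
the diagnostics gate applies at every budget.

## Synthetic cohorts and what they do (not) show

`glucorl.cohort.generate_cohort` emulates the three data streams of the
study design with known ground truth:

- **Behavior**: agents simulated on a seeded task schedule. Generating
  parameters are drawn uniformly over identifiable, empirically plausible
  ranges — both learning rates on (0.10, 0.80), β log-uniform on (2, 10) —
  implemented as probit transforms of Gaussian latents. This is the
  "central region, not extreme tails" convention for recovery experiments:
  learning rates outside this range saturate the logistic link and are not
  identifiable from 420 choices, so recovery claims are explicitly
  conditional on plausible parameter ranges. The defaults produce ~70–75%
  training accuracy, typical of real cohorts on this task.
- **Glucose**: a smooth gamma-like bump
  `fasting + A (t/t_p) exp(1 − t/t_p)` (optional late undershoot as a
  second, later bump subtracted), sampled every 2 minutes over −4…120 min
  with iid Gaussian sensor noise (0.25 mmol/L). The noiseless iAUC has a
  closed form (used as ground truth); with undershoot or asymmetric decay a
  200k-point grid integration of the positive part stands in. Fasting
  levels ~N(5.0, 0.4) mmol/L; the excursion amplitude A = 2.5 (1 + 0.3 z)
  mmol/L is linear in the metabolic latent z, so the true iAUC is exactly
  linear in it.
- **Questionnaire**: a PHQ-9-like score as a rounded, range-clipped (0–27)
  affine transform of the symptom latent.
- **Affect ratings**: linear trends with Gaussian noise, clipped to
  [0, 100], rotating happiness/confidence/engagement across training
  trials; default intercepts/slopes (57.6%/−0.08, 37.8%/−0.11,
  65.9%/−0.21 per trial) encode the observed study-level trends.

A planted 3×3 correlation matrix couples the reward-learning-rate latent,
the metabolic latent, and the symptom latent; all observables are monotone,
near-linear transforms of their latents, so ground-truth sample
correlations land within a few hundredths of the planted values at large n.

What passing the synthetic tests shows: the pipeline is internally
consistent — it recovers parameters and planted effect sizes at the study's
own scale and noise levels, with calibrated uncertainty. What it does not
show: anything about real cohorts. Real CGM traces have autocorrelated
sensor error, drift, and early-wear inflammation artifacts (none modeled);
real choice behavior contains lapses, side biases, and slow nonstationarity
the Q-learning family ignores; real questionnaire scores are not Gaussian
transforms. Measured-vs-true iAUC correlates ~0.9 in the generator almost
entirely because the single noisy baseline reading propagates across the
whole 2-hour window — a faithful rendering of a real limitation of
single-baseline iAUC.

## Association analyses

Posterior correlations follow the draw-wise procedure: at every posterior
draw, the Pearson correlation between that draw's subject-level parameters
(natural scale by default) and the covariate; the resulting distribution is
summarized by its mean, 90% and 66% highest-density intervals, and
P(r > 0). Attenuation note: the draw-wise mean is conservative — posterior
sampling noise shrinks each draw's correlation relative to the correlation
of posterior means, which in turn is shrunk relative to the truth by
estimation error, so a planted latent correlation of 0.32 is expected to
appear as roughly 0.24–0.30 at the study scale.

HDIs use the sorted-window scan: the shortest interval containing
⌈mass·n⌉ of the sorted samples. Multimodal samples still get a single
interval (documented convention; cross-checked against both a brute-force
window search and ArviZ).

Win-stay is the probability of repeating the previously chosen symbol at
the **next presentation of the same pair** given the previous outcome was a
reward (pairs interleave during training, so the immediately-next trial
usually shows a different pair); lose-shift analogously. A trial-conditioned
variant (`win_stay_mode="trial"`) is available. Missed trials are excluded
from numerators and denominators.

Bayesian linear regression uses rstanarm-style weakly informative priors
(intercept ~ N(ȳ, 2.5 s_y); slopes ~ N(0, 2.5 s_y/s_x); σ ~ half-N(0,
2.5 s_y)) and is sampled with the same NUTS machinery. The noise scale
carries a small floor (10⁻³ s_y) so the posterior stays proper on exactly
collinear data. The affect-trend model is a hierarchical linear regression
of rating on trial index with non-centered participant random intercepts
and slopes; the trial index is centered internally to decorrelate intercept
and slope, and the reported intercept is transformed back to trial 1. An
optional per-participant moderator (standardized) enters as a
slope-by-covariate interaction.

The sample-size routine inverts the exact power function of the two-sided
t test of ρ = 0: power is computed by integrating Hotelling's exact density
of the sample correlation under ρ = r (via the Gaussian hypergeometric
function) over the rejection region. For r = 0.4, power 0.80, α = 0.05 this
gives n = 46; the Fisher-z approximation (offered as a method flag) is one
participant more conservative at 47.

## Reproducibility and problem sizes

One global seed fans out to per-stage seeds through `SeedSequence` spawning
(`pipeline.stage_seeds`), recorded in every report, so stages can be rerun
in isolation. Full pipelines are deterministic at fixed seed.

The package's standard problem sizes: recovery and study runs use the full
design scale (48 participants × 360 training + 60 test trials). The
acceptance script fits with 4 chains × 1000 post-warmup draws; replicated
experiments (planted-effect replicates, calibration checks) use 2-chain
fits with a few hundred draws each, which the diagnostics gate shows to be
sufficient for posterior means of subject-level parameters.

## Known limitations

- The sampler adapts only a diagonal mass matrix; strongly correlated
  posteriors mix more slowly than under a dense metric.
- Recovery figures are conditional on the generator's identifiable
  parameter ranges; they degrade sharply for learning rates near 0 or 1.
- The separate reward/punishment outcome-sensitivity variant is
  deliberately absent (known nonidentifiable against the learning rates on
  this design).
- No reaction times, fatigue dynamics, or physiological covariates beyond
  the metabolic latent are modeled.
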
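# glucorl

Glucose control and reward learning: a tested, fully synthetic-data-capable
re-implementation of the analysis pipeline linking oral-glucose-tolerance
dynamics to reinforcement-learning parameters.

## The scientific problem

Peripheral insulin resistance — indexed cheaply by how far and how long blood
glucose rises after a standardized 50 g glucose drink — may modulate
dopaminergic reward learning. Studies in this area administer an oral glucose
tolerance test (OGTT) with a continuous glucose monitor (CGM), have
participants play the probabilistic selection task (PST: six stimuli with
reward probabilities 0.2–0.8, trained in fixed 80–20 / 70–30 / 60–40 pairs
over 6 blocks of 60 trials, then a 60-trial feedback-free test phase), fit a
hierarchical Bayesian Q-learning model, and correlate the fitted learning
parameters with glucose metrics and symptom questionnaires.

This package implements every computational stage of that chain, plus a
synthetic-cohort generator with known ground truth so the whole pipeline is
testable without any participant data:

- **Task & agents** (`glucorl.task`, `glucorl.agents`) — seeded PST schedules
  and Rescorla–Wagner/softmax agents. Choice rule
  `P(choose i over j) = logistic(β (Q_i − Q_j))`; value update
  `Q ← Q + α (R − Q)` with separate learning rates α⁺ (reward) and α⁻ (loss)
  for positive and negative prediction errors.
- **Glucose metrics** (`glucorl.glucose`) — incremental area under the curve
  (iAUC) by the trapezoid rule above the fasting baseline, with linear
  interpolation at baseline crossings and exclusion of fully sub-baseline
  segments; fasting glucose as the last pre-ingestion reading; CSV ingest for
  CGM exports (mmol/L or mg/dL).
- **Hierarchical Bayesian inference** (`glucorl.model`, `glucorl.sampler`,
  `glucorl.fit`) — 1-LR and 2-LR variants with non-centered subject effects,
  inverse-logit / exponential links, and weakly informative priors, sampled
  by a built-in No-U-Turn sampler (dual-averaging step size, windowed
  diagonal mass adaptation) with the standard Hamiltonian diagnostics
  (divergences, split-R̂, E-BFMI, treedepth) and PSIS-LOO model comparison.
- **Association statistics** (`glucorl.stats`) — correlations computed at
  every posterior draw and summarized by mean, 90%/66% highest-density
  intervals and P(r > 0); Bayesian linear regression; win-stay/lose-shift and
  accuracy summaries; hierarchical affect-trend regression; exact power-based
  sample-size computation for correlation tests.
- **Orchestration** (`glucorl.pipeline`) — parameter-recovery experiments and
  the full simulate → iAUC → fit → correlate study replication, with one
  global seed fanning out deterministically to per-stage seeds.

## Worked example

```python
from glucorl import (AgentParameters, ModelSpec, build_task_design,
                     simulate_agent, fit_model, posterior_correlation)
import pandas as pd

design = build_task_design(seed=1)
trials = pd.concat([
    simulate_agent(AgentParameters(0.45, 0.25, 5.0), design,
                   seed=i, participant_id=f"p{i}")
    for i in range(8)
], ignore_index=True)

fit = fit_model(trials, ModelSpec(n_chains=2, n_warmup=300, n_draws=500), seed=0)
print(fit.diagnostics.summary())
print(fit.posterior_mean("alpha_reward").round(2).to_dict())
```

prints (agents share one generating parameter set, so estimates pool tightly
around the truth α⁺ = 0.45):

```
divergences=0, max split-Rhat=1.010, min E-BFMI=0.80, treedepth saturations=0
{'p0': 0.45, 'p1': 0.45, 'p2': 0.45, 'p3': 0.46, 'p4': 0.44, 'p5': 0.46, 'p6': 0.45, 'p7': 0.46}
```

The `analysis/` directory holds the numbered study drivers:
`01_power_analysis.py` (minimum n to detect r = 0.4 at 80% power: 46 by the
exact t method, 47 by Fisher-z), `02_simulate_cohort.py` /
`03_glucose_metrics.py` (synthetic cohort and its OGTT summaries),
`04_parameter_recovery.py` (truth-vs-estimate correlations at the 48 × 360
design scale), `05_run_study.py` (full pipeline incl. LOO model comparison
and posterior correlation report), and `06_planted_effect_replicates.py`
(replicated recovery of a planted learning-rate–glucose correlation of
0.32). Each writes its tables under `results/`.

## Documentation

`docs/methods.md` describes the models, priors, sampler, synthetic-data
generator, and the numerical and design choices in detail, including what
passing the synthetic-data tests does and does not establish about real
cohorts.
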
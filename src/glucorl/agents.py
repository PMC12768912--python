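"""Q-learning agents on the probabilistic selection task.

The generative model is a Rescorla-Wagner learner with a softmax
(logistic) choice rule: the probability of choosing symbol i over j is
``logistic(beta * (Q_i - Q_j))``, and after feedback the chosen symbol's
value is updated by ``Q <- Q + alpha * (R - Q)``, with separate learning
rates for positive (reward) and negative (loss) prediction errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task import TaskDesign

#: column order of the trial table produced by simulation and read by fitting
TRIAL_COLUMNS = [
    "participant_id",
    "phase",
    "block",
    "trial_index",
    "left_symbol",
    "right_symbol",
    "chosen_symbol",
    "outcome",
    "affect_type",
    "affect_rating",
]

MISSING = ""  # chosen_symbol sentinel for missed ("no response") trials


@dataclass(frozen=True)
class AgentParameters:
    """Subject-level Q-learning parameters.

    alpha_reward, alpha_loss : learning rates in [0, 1] applied to positive
        and negative prediction errors respectively.
    beta : outcome sensitivity (inverse temperature), >= 0.
    """

    alpha_reward: float
    alpha_loss: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("alpha_reward", "alpha_loss"):
            a = getattr(self, name)
            if not np.isfinite(a) or not 0.0 <= a <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {a}")
        if not np.isfinite(self.beta) or self.beta < 0:
            raise ValueError(f"beta must be finite and >= 0, got {self.beta}")


def softmax_choice_prob(q_chosen: float, q_other: float, beta: float) -> float:
    """Eq.-style logistic choice probability for the 'chosen' option."""
    return 1.0 / (1.0 + np.exp(-beta * (q_chosen - q_other)))


def simulate_agent(
    params: AgentParameters,
    design: TaskDesign,
    q_init: float = 0.5,
    seed: int | None = None,
    participant_id: str = "p0",
    miss_rate: float = 0.0,
) -> pd.DataFrame:
    """Simulate one agent through a full PST session.

    Training choices are sampled from the logistic rule, outcomes are
    Bernoulli draws with the chosen symbol's reward probability, and Q-values
    are updated after each outcome. Test choices use the final training
    Q-values with no feedback and no updating. Missed trials (rate
    ``miss_rate``) record no choice and leave Q unchanged.

    Returns a trial table with the :data:`TRIAL_COLUMNS` schema.
    """
    if not 0.0 <= q_init <= 1.0:
        raise ValueError(f"q_init must be in [0, 1], got {q_init}")
    if not 0.0 <= miss_rate < 1.0:
        raise ValueError(f"miss_rate must be in [0, 1), got {miss_rate}")
    rng = np.random.default_rng(seed)

    q = {s: float(q_init) for s in design.symbols}
    rows: list[tuple] = []

    for t, ((left, right), block) in enumerate(
        zip(design.training_pairs, design.training_blocks), start=1
    ):
        if miss_rate > 0 and rng.random() < miss_rate:
            rows.append((participant_id, "training", block, t, left, right,
                         MISSING, np.nan, None, np.nan))
            continue
        p_left = softmax_choice_prob(q[left], q[right], params.beta)
        chosen = left if rng.random() < p_left else right
        outcome = float(rng.random() < design.reward_probs[chosen])
        pe = outcome - q[chosen]
        alpha = params.alpha_reward if pe >= 0 else params.alpha_loss
        q[chosen] += alpha * pe
        rows.append((participant_id, "training", block, t, left, right,
                     chosen, outcome, None, np.nan))

    for t, (left, right) in enumerate(design.test_pairs, start=1):
        if miss_rate > 0 and rng.random() < miss_rate:
            rows.append((participant_id, "test", np.nan, t, left, right,
                         MISSING, np.nan, None, np.nan))
            continue
        p_left = softmax_choice_prob(q[left], q[right], params.beta)
        chosen = left if rng.random() < p_left else right
        rows.append((participant_id, "test", np.nan, t, left, right,
                     chosen, np.nan, None, np.nan))

    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)
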
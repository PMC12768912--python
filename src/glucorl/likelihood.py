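"""Q-learning trial likelihood with analytic parameter gradients.

The forward recursion (logistic choice rule over Q-value differences,
Rescorla-Wagner update of the chosen option) is compiled with numba and
also propagates the sensitivities dQ/dalpha, giving exact gradients of
each participant's log-likelihood with respect to (alpha_reward,
alpha_loss, beta). These gradients drive the Hamiltonian sampler.

Training trials update Q from the recorded outcome; test-phase trials
(no feedback) contribute choice probabilities under the frozen final
Q-values and perform no update. A prediction error of exactly zero takes
the reward-learning-rate branch (a measure-zero event under the 0/1
outcome coding).
"""

from __future__ import annotations

from dataclasses import dataclass

import numba
import numpy as np
import pandas as pd

from .agents import MISSING, AgentParameters
from .task import SYMBOLS


class TrialOrderError(ValueError):
    """Raised when trials are not in presentation order."""


@dataclass(frozen=True)
class PackedTrials:
    """Choice trials as padded index arrays, one row per participant.

    ``chosen`` and ``other`` are symbol indices; ``valid`` masks out both
    the padding beyond a participant's last trial and missed trials (which
    leave Q unchanged); ``update`` marks trials whose outcome feeds the
    Rescorla-Wagner update (training trials only).
    """

    participant_ids: list[str]
    chosen: np.ndarray  # (P, T) int64
    other: np.ndarray  # (P, T) int64
    outcome: np.ndarray  # (P, T) float64
    valid: np.ndarray  # (P, T) bool
    update: np.ndarray  # (P, T) bool
    n_symbols: int

    @property
    def n_participants(self) -> int:
        return self.chosen.shape[0]

    @property
    def n_trials_per_participant(self) -> np.ndarray:
        return self.valid.sum(axis=1)


def _is_missing(ch) -> bool:
    return ch is None or ch == MISSING or (isinstance(ch, float) and np.isnan(ch))


def pack_trials(
    trials: pd.DataFrame,
    symbols=SYMBOLS,
    phases: tuple[str, ...] = ("training", "test"),
) -> PackedTrials:
    """Pack a trial table for vectorized likelihood evaluation.

    Participants are ordered by id. Training trials precede test trials
    (matching the session) and must be in presentation order within phase.
    """
    sym_idx = {s: i for i, s in enumerate(symbols)}
    sub = trials[trials.phase.isin(phases)]
    ids = sorted(sub.participant_id.unique())
    if not ids:
        raise ValueError("no trials to pack")
    t_max = int(sub.groupby("participant_id").size().max())
    n = len(ids)
    chosen = np.zeros((n, t_max), dtype=np.int64)
    other = np.zeros((n, t_max), dtype=np.int64)
    outcome = np.zeros((n, t_max), dtype=np.float64)
    valid = np.zeros((n, t_max), dtype=np.bool_)
    update = np.zeros((n, t_max), dtype=np.bool_)
    phase_order = {"training": 0, "test": 1}
    for p, pid in enumerate(ids):
        grp = sub[sub.participant_id == pid]
        grp = grp.sort_values(
            ["phase", "trial_index"], key=lambda s: s.map(phase_order) if s.name == "phase" else s
        )
        for phase, phase_grp in grp.groupby("phase", sort=False):
            if np.any(np.diff(phase_grp.trial_index.to_numpy()) <= 0):
                raise TrialOrderError(
                    f"participant {pid!r}: {phase} trials out of order"
                )
        for t, row in enumerate(grp.itertuples()):
            ch = row.chosen_symbol
            if _is_missing(ch):
                continue
            left, right = row.left_symbol, row.right_symbol
            if ch not in (left, right):
                raise ValueError(
                    f"participant {pid!r}: chosen symbol {ch!r} not in pair"
                )
            chosen[p, t] = sym_idx[ch]
            other[p, t] = sym_idx[right if ch == left else left]
            valid[p, t] = True
            if row.phase == "training":
                outcome[p, t] = float(row.outcome)
                update[p, t] = True
    return PackedTrials(
        participant_ids=ids,
        chosen=chosen,
        other=other,
        outcome=outcome,
        valid=valid,
        update=update,
        n_symbols=len(symbols),
    )


@numba.njit(cache=True)
def _loglik_grad_kernel(
    chosen, other, outcome, valid, update, a_r, a_l, beta, q_init, n_sym
):
    """Per-participant log-likelihood and gradients wrt (a_r, a_l, beta)."""
    n_p, n_t = chosen.shape
    ll = np.zeros(n_p)
    g_ar = np.zeros(n_p)
    g_al = np.zeros(n_p)
    g_b = np.zeros(n_p)
    for p in range(n_p):
        q = np.full(n_sym, q_init)
        dq_r = np.zeros(n_sym)
        dq_l = np.zeros(n_sym)
        b = beta[p]
        ar = a_r[p]
        al = a_l[p]
        for t in range(n_t):
            if not valid[p, t]:
                continue
            c = chosen[p, t]
            u = other[p, t]
            d = q[c] - q[u]
            x = b * d
            # stable log(sigmoid(x)) and sigmoid(-x)
            if x >= 0:
                ex = np.exp(-x)
                ll[p] += -np.log1p(ex)
                s = ex / (1.0 + ex)
            else:
                ex = np.exp(x)
                ll[p] += x - np.log1p(ex)
                s = 1.0 / (1.0 + ex)
            g_b[p] += s * d
            g_ar[p] += s * b * (dq_r[c] - dq_r[u])
            g_al[p] += s * b * (dq_l[c] - dq_l[u])
            if update[p, t]:
                pe = outcome[p, t] - q[c]
                if pe >= 0.0:
                    dq_r[c] = (1.0 - ar) * dq_r[c] + pe
                    dq_l[c] = (1.0 - ar) * dq_l[c]
                    q[c] += ar * pe
                else:
                    dq_r[c] = (1.0 - al) * dq_r[c]
                    dq_l[c] = (1.0 - al) * dq_l[c] + pe
                    q[c] += al * pe
    return ll, g_ar, g_al, g_b


def loglik_and_grads(
    packed: PackedTrials,
    alpha_reward: np.ndarray,
    alpha_loss: np.ndarray,
    beta: np.ndarray,
    q_init: float = 0.5,
):
    """Vector of per-participant log-likelihoods plus parameter gradients."""
    return _loglik_grad_kernel(
        packed.chosen,
        packed.other,
        packed.outcome,
        packed.valid,
        packed.update,
        np.asarray(alpha_reward, dtype=np.float64),
        np.asarray(alpha_loss, dtype=np.float64),
        np.asarray(beta, dtype=np.float64),
        float(q_init),
        packed.n_symbols,
    )


def trial_loglik(
    params: AgentParameters,
    trials: pd.DataFrame,
    q_init: float = 0.5,
    phases: tuple[str, ...] = ("training",),
) -> float:
    """Log-likelihood of one participant's recorded choices.

    Sums, over non-missing trials in presentation order, the log logistic
    probability of the recorded choice; during training, Q-values are
    updated after each trial from the recorded outcome (reward learning
    rate for positive prediction errors, loss learning rate for negative
    ones). Missed trials are skipped with Q carried forward. ``phases``
    selects which phases contribute (training only by default; add "test"
    to score feedback-free choices under the frozen final Q-values).
    """
    pids = trials.participant_id.unique()
    if len(pids) != 1:
        raise ValueError("trial_loglik expects a single participant's trials")
    packed = pack_trials(trials, phases=phases)
    ll, _, _, _ = loglik_and_grads(
        packed,
        np.array([params.alpha_reward]),
        np.array([params.alpha_loss]),
        np.array([params.beta]),
        q_init=q_init,
    )
    return float(ll[0])
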
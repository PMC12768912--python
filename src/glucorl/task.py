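"""Probabilistic selection task (PST) design.

Six stimuli carry fixed reward probabilities (0.20-0.80). Training shows
three fixed pairs (80-20, 70-30, 60-40) over 6 blocks of 60 trials; the
test phase shows every unordered pairing twice, without feedback.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

SYMBOLS = ("A", "B", "C", "D", "E", "F")
REWARD_PROBS = (0.20, 0.30, 0.40, 0.60, 0.70, 0.80)

N_BLOCKS = 6
TRIALS_PER_BLOCK = 60
POINTS_PER_WIN = 25

#: fixed training pairs, as (high-probability, low-probability) reward levels
TRAINING_PAIR_PROBS = ((0.80, 0.20), (0.70, 0.30), (0.60, 0.40))


@dataclass(frozen=True)
class TaskDesign:
    """A fully scheduled PST session.

    ``training_pairs`` holds one ``(left_symbol, right_symbol)`` tuple per
    training trial in presentation order; ``training_blocks`` gives each
    trial's 1-based block. ``test_pairs`` is the feedback-free test schedule.
    """

    symbols: tuple[str, ...]
    reward_probs: dict[str, float]
    training_pairs: tuple[tuple[str, str], ...]
    training_blocks: tuple[int, ...]
    test_pairs: tuple[tuple[str, str], ...]
    points_per_win: int = POINTS_PER_WIN
    seed: int | None = None

    @property
    def n_training_trials(self) -> int:
        return len(self.training_pairs)

    @property
    def n_test_trials(self) -> int:
        return len(self.test_pairs)

    def higher_symbol(self, a: str, b: str) -> str:
        """The symbol of the pair with the larger reward probability."""
        return a if self.reward_probs[a] >= self.reward_probs[b] else b


def build_task_design(seed: int) -> TaskDesign:
    """Build a seeded PST schedule.

    Symbol-to-probability assignment is a seeded random permutation. Each
    fixed pair appears 20 times per block (60 / 3), with left/right
    presentation counterbalanced within block; trial order is shuffled
    within each block. The test phase presents all 15 unordered pairings
    twice, once in each left/right order, in shuffled order.
    """
    rng = np.random.default_rng(seed)

    perm = rng.permutation(len(SYMBOLS))
    reward_probs = {s: REWARD_PROBS[p] for s, p in zip(SYMBOLS, perm)}
    by_prob = {p: s for s, p in reward_probs.items()}

    fixed_pairs = [(by_prob[hi], by_prob[lo]) for hi, lo in TRAINING_PAIR_PROBS]
    per_pair = TRIALS_PER_BLOCK // len(fixed_pairs)

    training_pairs: list[tuple[str, str]] = []
    training_blocks: list[int] = []
    for block in range(1, N_BLOCKS + 1):
        block_trials: list[tuple[str, str]] = []
        for hi, lo in fixed_pairs:
            # counterbalance: half the presentations put the better symbol left
            block_trials += [(hi, lo)] * (per_pair // 2)
            block_trials += [(lo, hi)] * (per_pair - per_pair // 2)
        order = rng.permutation(len(block_trials))
        training_pairs += [block_trials[i] for i in order]
        training_blocks += [block] * len(block_trials)

    test_trials: list[tuple[str, str]] = []
    for a, b in combinations(SYMBOLS, 2):
        # each unordered pairing twice, once in each left/right order
        test_trials += [(a, b), (b, a)]
        test_trials += [(a, b), (b, a)]
    order = rng.permutation(len(test_trials))
    test_pairs = [test_trials[i] for i in order]

    return TaskDesign(
        symbols=SYMBOLS,
        reward_probs=reward_probs,
        training_pairs=tuple(training_pairs),
        training_blocks=tuple(training_blocks),
        test_pairs=tuple(test_pairs),
        seed=seed,
    )
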
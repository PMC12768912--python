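"""Synthetic study cohorts with known ground truth.

Emulates the three data streams of a glucose-and-reward-learning study —
trial-level task behavior, post-ingestion CGM traces, and questionnaire
scores — for a cohort of agents whose learning parameters, metabolic
response, and symptom burden can be given a planted correlation structure.
Every downstream stage (iAUC, model fitting, posterior correlations) is
testable against the stored ground truth.

The planted correlations live on the latent (Gaussian) scale of three
factors: the reward-learning-rate latent, a metabolic factor that scales
the glucose excursion, and a symptom factor behind the questionnaire
score. Observable quantities are monotone, near-linear transforms of
these latents, so sample correlations of ground-truth quantities land
close to the planted values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .agents import AgentParameters, simulate_agent
from .glucose import GlucoseCurveParams, GlucoseTrace, generate_glucose_trace
from .task import TaskDesign, build_task_design

AFFECT_TYPES = ("happiness", "confidence", "engagement")

#: default per-type affect trajectories: (intercept at trial 1 in %, slope %/trial)
AFFECT_DEFAULTS = {
    "happiness": (57.6, -0.08),
    "confidence": (37.8, -0.11),
    "engagement": (65.9, -0.21),
}


class CohortConfigError(ValueError):
    """Raised for invalid cohort configurations (e.g. non-PSD correlations)."""


@dataclass(frozen=True)
class CohortGroupParams:
    """Group-level generating distributions.

    Learning rates are uniform over identifiable, empirically plausible
    ranges for this task family (implemented as probit transforms of
    Gaussian latents, so planted latent correlations carry through
    monotonically); outcome sensitivity is log-uniform. The defaults
    produce cohorts with ~70-75% training accuracy, typical of real
    probabilistic-selection-task samples.
    """

    alpha_reward_range: tuple[float, float] = (0.10, 0.80)
    alpha_loss_range: tuple[float, float] = (0.10, 0.80)
    beta_range: tuple[float, float] = (2.0, 10.0)  # log-uniform
    # glucose curve: fasting varies between participants; the metabolic latent
    # scales the excursion amplitude linearly (so true iAUC is linear in it)
    fasting_mean: float = 5.0
    fasting_sd: float = 0.4
    peak_height_base: float = 2.5
    peak_height_rel_sd: float = 0.30
    time_to_peak: float = 35.0
    cgm_noise_sd: float = 0.25
    # questionnaire (PHQ-9-like): rounded clipped Gaussian on 0-27
    symptom_mean: float = 6.0
    symptom_sd: float = 4.5
    affect_noise_sd: float = 8.0
    miss_rate: float = 0.0


def planted_correlation_matrix(
    r_alpha_metabolic: float = 0.0,
    r_alpha_symptom: float = 0.0,
    r_metabolic_symptom: float = 0.0,
) -> np.ndarray:
    """3x3 latent correlation matrix, order (alpha_reward, metabolic, symptom)."""
    c = np.array(
        [
            [1.0, r_alpha_metabolic, r_alpha_symptom],
            [r_alpha_metabolic, 1.0, r_metabolic_symptom],
            [r_alpha_symptom, r_metabolic_symptom, 1.0],
        ]
    )
    return c


@dataclass
class CohortGroundTruth:
    """What the generator knows: per-participant truths + generation settings."""

    params: pd.DataFrame  # per participant: alpha_reward, alpha_loss, beta,
    # true_iauc, true_fasting, symptom_score, latent_* columns
    planted_correlations: np.ndarray
    seed: int

    def agent_parameters(self, participant_id: str) -> AgentParameters:
        row = self.params.loc[self.params.participant_id == participant_id].iloc[0]
        return AgentParameters(row.alpha_reward, row.alpha_loss, row.beta)


@dataclass
class SyntheticCohort:
    trials: pd.DataFrame
    traces: list[GlucoseTrace]
    scores: pd.DataFrame  # participant_id, symptom_score
    design: TaskDesign
    ground_truth: CohortGroundTruth


def simulate_affect_trajectory(
    start_percent: float,
    slope_per_trial: float,
    noise_sd: float,
    n_trials: int,
    seed: int | None = None,
) -> np.ndarray:
    """Linear affect trend plus Gaussian noise, clipped to [0, 100].

    The value at trial 1 equals ``start_percent`` (before noise).
    """
    if not 0.0 <= start_percent <= 100.0:
        raise ValueError("start_percent must be in [0, 100]")
    rng = np.random.default_rng(seed)
    trials = np.arange(1, n_trials + 1)
    y = start_percent + slope_per_trial * (trials - 1)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n_trials)
    return np.clip(y, 0.0, 100.0)


def generate_cohort(
    n_participants: int = 48,
    group_params: CohortGroupParams | None = None,
    planted_correlations: np.ndarray | None = None,
    seed: int = 0,
    design: TaskDesign | None = None,
) -> SyntheticCohort:
    """Generate a full synthetic study dataset with stored ground truth.

    Per-participant parameters are drawn from the group distributions on the
    unconstrained scale; the reward-learning-rate latent, the metabolic
    factor, and the symptom factor are drawn jointly under the planted
    correlation matrix. All randomness descends from ``seed``.
    """
    if n_participants < 2:
        raise CohortConfigError("need at least 2 participants")
    gp = group_params or CohortGroupParams()
    c = (
        np.asarray(planted_correlations, dtype=float)
        if planted_correlations is not None
        else planted_correlation_matrix()
    )
    if c.shape != (3, 3) or not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1):
        raise CohortConfigError("planted_correlations must be a 3x3 correlation matrix")
    eigmin = np.linalg.eigvalsh(c)[0]
    if eigmin < -1e-10:
        raise CohortConfigError(
            f"planted correlation matrix is not positive semi-definite "
            f"(min eigenvalue {eigmin:.3g})"
        )

    ss = np.random.SeedSequence(seed)
    s_design, s_latent, s_agents, s_traces, s_affect = ss.spawn(5)
    rng = np.random.default_rng(s_latent)

    if design is None:
        design = build_task_design(int(s_design.generate_state(1)[0] % 2**31))

    # correlated latents (alpha_reward, metabolic, symptom) + independent ones
    evals, evecs = np.linalg.eigh(c)
    sqrt_c = evecs @ np.diag(np.sqrt(np.maximum(evals, 0.0))) @ evecs.T
    lat = rng.standard_normal((n_participants, 3)) @ sqrt_c.T
    z_ar, z_met, z_sym = lat[:, 0], lat[:, 1], lat[:, 2]

    # probit transforms: uniform marginals, monotone in the Gaussian latents
    lo, hi = gp.alpha_reward_range
    alpha_reward = lo + (hi - lo) * norm.cdf(z_ar)
    lo, hi = gp.alpha_loss_range
    alpha_loss = lo + (hi - lo) * norm.cdf(rng.standard_normal(n_participants))
    lo, hi = np.log(gp.beta_range)
    beta = np.exp(lo + (hi - lo) * norm.cdf(rng.standard_normal(n_participants)))

    fasting = np.maximum(
        gp.fasting_mean + gp.fasting_sd * rng.standard_normal(n_participants), 3.5
    )
    peak_height = np.maximum(
        gp.peak_height_base * (1.0 + gp.peak_height_rel_sd * z_met), 0.2
    )
    symptom = np.clip(
        np.rint(gp.symptom_mean + gp.symptom_sd * z_sym), 0, 27
    ).astype(int)

    ids = [f"p{i:03d}" for i in range(n_participants)]
    agent_seeds = s_agents.generate_state(n_participants) % 2**31
    trace_seeds = s_traces.generate_state(n_participants) % 2**31
    affect_rng = np.random.default_rng(s_affect)

    trial_frames, traces, truth_rows = [], [], []
    for i, pid in enumerate(ids):
        params = AgentParameters(alpha_reward[i], alpha_loss[i], beta[i])
        trials = simulate_agent(
            params,
            design,
            seed=int(agent_seeds[i]),
            participant_id=pid,
            miss_rate=gp.miss_rate,
        )
        trials = _attach_affect(trials, gp, affect_rng)
        trial_frames.append(trials)

        curve = GlucoseCurveParams(
            fasting=float(fasting[i]),
            peak_height=float(peak_height[i]),
            time_to_peak=gp.time_to_peak,
            noise_sd=gp.cgm_noise_sd,
        )
        trace, true_iauc = generate_glucose_trace(
            curve, seed=int(trace_seeds[i]), participant_id=pid
        )
        traces.append(trace)
        truth_rows.append(
            {
                "participant_id": pid,
                "alpha_reward": alpha_reward[i],
                "alpha_loss": alpha_loss[i],
                "beta": beta[i],
                "true_iauc": true_iauc,
                "true_fasting": fasting[i],
                "symptom_score": int(symptom[i]),
                "latent_alpha_reward": z_ar[i],
                "latent_metabolic": z_met[i],
                "latent_symptom": z_sym[i],
            }
        )

    truth = CohortGroundTruth(
        params=pd.DataFrame(truth_rows), planted_correlations=c, seed=seed
    )
    scores = truth.params[["participant_id", "symptom_score"]].copy()
    return SyntheticCohort(
        trials=pd.concat(trial_frames, ignore_index=True),
        traces=traces,
        scores=scores,
        design=design,
        ground_truth=truth,
    )


def _attach_affect(
    trials: pd.DataFrame, gp: CohortGroupParams, rng: np.random.Generator
) -> pd.DataFrame:
    """Add rotating happiness/confidence/engagement ratings to training rows."""
    trials = trials.copy()
    train = trials.phase == "training"
    n = int(train.sum())
    idx = trials.index[train]
    types = [AFFECT_TYPES[t % 3] for t in range(n)]
    ratings = np.full(n, np.nan)
    for a_type in AFFECT_TYPES:
        start, slope = AFFECT_DEFAULTS[a_type]
        traj = simulate_affect_trajectory(
            start, slope, gp.affect_noise_sd, n,
            seed=int(rng.integers(2**31)),
        )
        mask = np.array([t == a_type for t in types])
        ratings[mask] = traj[mask]
    trials.loc[idx, "affect_type"] = types
    trials.loc[idx, "affect_rating"] = ratings
    # missed trials carry no rating
    missed = train & (trials.chosen_symbol == "")
    trials.loc[trials.index[missed], ["affect_type", "affect_rating"]] = [None, np.nan]
    return trials
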
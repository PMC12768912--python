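"""Model fitting, HMC diagnostics, posterior prediction, and LOO comparison.

``fit_model`` runs the hierarchical Q-learning model through the NUTS
sampler and returns the posterior as an ArviZ ``InferenceData`` (with
per-participant pointwise log-likelihoods for PSIS-LOO) wrapped in a
:class:`FitResult`. Fits are gated on the standard Hamiltonian
diagnostics — zero divergences, split-Rhat < 1.1, E-BFMI > 0.3,
treedepth below the cap — and fail loudly when these are breached
unless ``allow_bad_fit`` is set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

from .agents import AgentParameters, simulate_agent
from .likelihood import PackedTrials, pack_trials
from .model import ONE_LR, TWO_LR, HierarchicalQModel, ModelSpec
from .sampler import NutsConfig, SamplerRun, sample_nuts
from .task import TaskDesign

RHAT_THRESHOLD = 1.1
EBFMI_THRESHOLD = 0.3


@dataclass(frozen=True)
class FitDiagnostics:
    n_divergent: int
    max_rhat: float
    min_ebfmi: float
    n_max_treedepth: int
    max_treedepth: int
    rhat_per_var: dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return (
            self.n_divergent == 0
            and self.max_rhat < RHAT_THRESHOLD
            and self.min_ebfmi > EBFMI_THRESHOLD
            and self.n_max_treedepth == 0
        )

    def summary(self) -> str:
        return (
            f"divergences={self.n_divergent}, max split-Rhat={self.max_rhat:.3f}, "
            f"min E-BFMI={self.min_ebfmi:.2f}, "
            f"treedepth saturations={self.n_max_treedepth}"
        )

    def to_dict(self) -> dict:
        return {
            "n_divergent": self.n_divergent,
            "max_rhat": self.max_rhat,
            "min_ebfmi": self.min_ebfmi,
            "n_max_treedepth": self.n_max_treedepth,
            "max_treedepth": self.max_treedepth,
            "ok": self.ok,
            "rhat_per_var": self.rhat_per_var,
        }


class DiagnosticError(RuntimeError):
    """Sampler convergence failure; carries the offending diagnostics."""

    def __init__(self, diagnostics: FitDiagnostics):
        self.diagnostics = diagnostics
        super().__init__(f"MCMC diagnostics breached thresholds: {diagnostics.summary()}")


@dataclass
class FitResult:
    """Posterior draws plus everything needed downstream.

    ``idata`` holds groups ``posterior`` (group_mean/group_sd with a
    ``param`` dim; subject-level alpha_reward/alpha_loss/beta with a
    ``participant`` dim), ``log_likelihood`` (per-participant), and
    ``sample_stats``.
    """

    idata: az.InferenceData
    spec: ModelSpec
    participants: list[str]
    diagnostics: FitDiagnostics
    seed: int

    @property
    def variant(self) -> str:
        return self.spec.variant

    def draws_matrix(self, param: str) -> np.ndarray:
        """Subject-level draws stacked to (n_total_draws, n_participants)."""
        da = self.idata.posterior[param]
        return da.stack(sample=("chain", "draw")).transpose("sample", "participant").values

    def posterior_mean(self, param: str) -> pd.Series:
        da = self.idata.posterior[param].mean(dim=("chain", "draw"))
        return pd.Series(da.values, index=self.participants, name=param)


def fit_model(
    trials: pd.DataFrame,
    spec: ModelSpec | None = None,
    seed: int = 0,
    allow_bad_fit: bool = False,
) -> FitResult:
    """Fit the hierarchical Q-learning model to recorded choices.

    By default the likelihood covers training choices (with Rescorla-Wagner
    updating) and feedback-free test choices under the frozen final
    Q-values; set ``ModelSpec(include_test=False)`` for a training-only
    likelihood.
    """
    spec = spec or ModelSpec()
    phases = ("training", "test") if spec.include_test else ("training",)
    packed = pack_trials(trials, phases=phases)
    if packed.n_participants == 1:
        warnings.warn(
            "fitting a hierarchy to a single participant: group-level scales "
            "are dominated by their priors",
            stacklevel=2,
        )
    if np.any(packed.n_trials_per_participant < 1):
        raise ValueError("every participant needs at least one non-missing trial")

    model = HierarchicalQModel(packed, spec)
    run = sample_nuts(
        model.logp_grad,
        model.dim,
        NutsConfig(
            n_chains=spec.n_chains,
            n_warmup=spec.n_warmup,
            n_draws=spec.n_draws,
            target_accept=spec.target_accept,
            max_treedepth=spec.max_treedepth,
        ),
        seed=seed,
    )
    idata = _build_idata(run, model, packed)
    diagnostics = compute_diagnostics(run, idata, spec.max_treedepth)
    if not diagnostics.ok and not allow_bad_fit:
        raise DiagnosticError(diagnostics)
    return FitResult(
        idata=idata,
        spec=spec,
        participants=list(packed.participant_ids),
        diagnostics=diagnostics,
        seed=seed,
    )


def _build_idata(
    run: SamplerRun, model: HierarchicalQModel, packed: PackedTrials
) -> az.InferenceData:
    spec = model.spec
    n_chains, n_draws, _ = run.draws.shape
    p = packed.n_participants
    k = model.k

    names = spec.param_names
    subj = {name: np.empty((n_chains, n_draws, p)) for name in names}
    group_mean = np.empty((n_chains, n_draws, k))
    group_sd = np.empty((n_chains, n_draws, k))
    loglik = np.empty((n_chains, n_draws, p))
    for c in range(n_chains):
        for d in range(n_draws):
            vec = run.draws[c, d]
            cons = model.constrain(vec)
            for name in names:
                subj[name][c, d] = cons[name]
            group_mean[c, d] = cons["group_mean"]
            group_sd[c, d] = cons["group_sd"]
            loglik[c, d] = model.pointwise_loglik(vec)

    coords = {
        "participant": packed.participant_ids,
        "param": list(names),
    }
    posterior = dict(subj)
    posterior["group_mean"] = group_mean
    posterior["group_sd"] = group_sd
    dims = {name: ["participant"] for name in names}
    dims["group_mean"] = ["param"]
    dims["group_sd"] = ["param"]
    dims["choices"] = ["participant"]
    sample_stats = {
        "lp": run.logp,
        "energy": run.energy,
        "diverging": run.diverging,
        "tree_depth": run.tree_depth,
        "acceptance_rate": run.accept_stat,
    }
    return az.from_dict(
        posterior=posterior,
        sample_stats=sample_stats,
        log_likelihood={"choices": loglik},
        coords=coords,
        dims=dims,
    )


def compute_diagnostics(
    run: SamplerRun, idata: az.InferenceData, max_treedepth: int
) -> FitDiagnostics:
    """Divergence count, split-Rhat, E-BFMI, and treedepth saturation."""
    rhat = az.rhat(idata)
    rhat_per_var = {
        name: float(np.nanmax(rhat[name].values)) for name in rhat.data_vars
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ebfmi = az.bfmi(run.energy)
    return FitDiagnostics(
        n_divergent=run.n_divergent,
        max_rhat=float(max(rhat_per_var.values())),
        min_ebfmi=float(np.min(ebfmi)),
        n_max_treedepth=int((run.tree_depth >= max_treedepth).sum()),
        max_treedepth=max_treedepth,
        rhat_per_var=rhat_per_var,
    )


def posterior_predict(
    fit: FitResult,
    design: TaskDesign,
    seed: int = 0,
    n_draws: int = 50,
) -> pd.DataFrame:
    """Simulate per-pair choice accuracies from a subsample of posterior draws.

    For each sampled draw, every participant is re-simulated through the
    task with that draw's parameters; rows give the across-participant mean
    probability of choosing the better symbol, per fixed pair and phase —
    the quantity overlaid on empirical learning curves in posterior
    predictive checks.
    """
    if n_draws < 1:
        raise ValueError("need at least one posterior draw to predict from")
    rng = np.random.default_rng(seed)
    names = fit.spec.param_names
    mats = {name: fit.draws_matrix(name) for name in names}
    total = next(iter(mats.values())).shape[0]
    if n_draws > total:
        raise ValueError(f"requested {n_draws} draws but only {total} available")
    draw_idx = rng.choice(total, size=n_draws, replace=False)

    records = []
    for d in draw_idx:
        acc: dict[tuple[str, str], list[float]] = {}
        for i in range(len(fit.participants)):
            if fit.variant == TWO_LR:
                params = AgentParameters(
                    mats["alpha_reward"][d, i],
                    mats["alpha_loss"][d, i],
                    mats["beta"][d, i],
                )
            else:
                a = mats["alpha"][d, i]
                params = AgentParameters(a, a, mats["beta"][d, i])
            sim = simulate_agent(
                params, design, q_init=fit.spec.q_init,
                seed=int(rng.integers(2**31)),
            )
            for phase in ("training", "test"):
                sub = sim[(sim.phase == phase) & (sim.chosen_symbol != "")]
                correct = [
                    design.higher_symbol(l, r) == ch
                    for l, r, ch in zip(
                        sub.left_symbol, sub.right_symbol, sub.chosen_symbol
                    )
                ]
                pair_labels = [
                    _pair_label(design, l, r)
                    for l, r in zip(sub.left_symbol, sub.right_symbol)
                ]
                frame = pd.DataFrame({"pair": pair_labels, "correct": correct})
                for pair, grp in frame.groupby("pair"):
                    acc.setdefault((phase, pair), []).append(grp.correct.mean())
        for (phase, pair), vals in acc.items():
            records.append(
                {
                    "draw": int(d),
                    "phase": phase,
                    "pair": pair,
                    "accuracy": float(np.mean(vals)),
                }
            )
    return pd.DataFrame(records)


def _pair_label(design: TaskDesign, left: str, right: str) -> str:
    hi = design.higher_symbol(left, right)
    lo = right if hi == left else left
    return f"{int(design.reward_probs[hi] * 100)}-{int(design.reward_probs[lo] * 100)}"


@dataclass(frozen=True)
class LooResult:
    """PSIS-LOO comparison of two fits on the same participants.

    ``elpd_diff = elpd(model_a) - elpd(model_b)``; positive favors model a.
    """

    model_a: str
    model_b: str
    elpd_a: float
    elpd_b: float
    elpd_diff: float
    diff_se: float
    n_high_pareto_k: int

    @property
    def favored(self) -> str:
        return self.model_a if self.elpd_diff >= 0 else self.model_b


def loo_compare(fit_a: FitResult, fit_b: FitResult) -> LooResult:
    """Pareto-smoothed importance-sampling LOO, participant-level pointwise.

    The difference standard error is the paired SE over pointwise elpd
    contributions, as in standard LOO model comparison.
    """
    if fit_a.participants != fit_b.participants:
        raise ValueError("fits cover different participant sets; cannot compare")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        loo_a = az.loo(fit_a.idata, pointwise=True)
        loo_b = az.loo(fit_b.idata, pointwise=True)
    pw_a = np.asarray(loo_a.loo_i)
    pw_b = np.asarray(loo_b.loo_i)
    diff = pw_a - pw_b
    n = diff.size
    diff_se = float(np.sqrt(n * np.var(diff, ddof=1))) if n > 1 else 0.0
    k_a = np.asarray(loo_a.pareto_k)
    k_b = np.asarray(loo_b.pareto_k)
    return LooResult(
        model_a=fit_a.variant,
        model_b=fit_b.variant,
        elpd_a=float(loo_a.elpd_loo),
        elpd_b=float(loo_b.elpd_loo),
        elpd_diff=float(diff.sum()),
        diff_se=diff_se,
        n_high_pareto_k=int((k_a > 0.7).sum() + (k_b > 0.7).sum()),
    )
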
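"""End-to-end orchestration: parameter recovery and full study runs.

A study run reproduces the analysis chain of the glucose-and-learning
design: per-participant iAUC and fasting glucose from CGM traces, 1-LR
and 2-LR hierarchical fits with PSIS-LOO comparison, posterior-draw
correlations of each learning parameter against the glucose metrics and
the questionnaire score, model-agnostic behavioral summaries, and
affect trends. A recovery run simulates a cohort with known parameters,
refits, and reports truth-versus-posterior-mean correlations.

One global seed fans out deterministically to per-stage seeds (recorded
in every report), so stages can be re-run in isolation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (
    CohortGroupParams,
    SyntheticCohort,
    generate_cohort,
    planted_correlation_matrix,
)
from .fit import FitResult, LooResult, fit_model, loo_compare
from .glucose import summarize_trace
from .model import ONE_LR, TWO_LR, ModelSpec
from .stats import (
    CorrelationPosterior,
    affect_trend,
    behavioral_summaries,
    posterior_correlation,
)

#: stage names in fan-out order; the index defines each stage's child seed
_STAGES = ("cohort", "fit_two_lr", "fit_one_lr", "affect", "behavior", "extra")


def stage_seeds(global_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds derived from one global seed."""
    ss = np.random.SeedSequence(global_seed)
    children = ss.spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1)[0] % 2**31)
        for name, child in zip(_STAGES, children)
    }


@dataclass
class StudyRunConfig:
    """Everything needed to reproduce a run, serializable to JSON."""

    n_participants: int = 48
    planted_r_alpha_metabolic: float = 0.32
    planted_r_alpha_symptom: float = 0.18
    planted_r_metabolic_symptom: float = 0.18
    variant: str = TWO_LR
    n_chains: int = 4
    n_warmup: int = 1000
    n_draws: int = 1000
    global_seed: int = 0
    output_dir: str | None = None
    compare_models: bool = True
    fit_affect: bool = True

    def model_spec(self, variant: str | None = None) -> ModelSpec:
        return ModelSpec(
            variant=variant or self.variant,
            n_chains=self.n_chains,
            n_warmup=self.n_warmup,
            n_draws=self.n_draws,
        )

    def planted_matrix(self) -> np.ndarray:
        return planted_correlation_matrix(
            self.planted_r_alpha_metabolic,
            self.planted_r_alpha_symptom,
            self.planted_r_metabolic_symptom,
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "StudyRunConfig":
        return cls(**json.loads(text))


@dataclass
class RecoveryReport:
    """Truth-versus-estimate agreement for a simulate-and-refit experiment."""

    correlations: dict[str, float]  # per parameter: Pearson r truth vs post. mean
    bias: dict[str, float]
    rmse: dict[str, float]
    n_participants: int
    n_trials_per_participant: int
    seed: int
    sampler_settings: dict
    degenerate: list[str] = field(default_factory=list)  # zero-variance params

    def to_dict(self) -> dict:
        return asdict(self)


def run_recovery(
    config: StudyRunConfig,
    group_params: CohortGroupParams | None = None,
) -> tuple[RecoveryReport, FitResult, SyntheticCohort]:
    """Simulate a cohort with known parameters, refit, correlate truth vs fit.

    Generating parameters are drawn from the group distributions in
    :class:`CohortGroupParams`, whose defaults sit in the central region of
    the model's priors.
    """
    seeds = stage_seeds(config.global_seed)
    cohort = generate_cohort(
        n_participants=config.n_participants,
        group_params=group_params,
        planted_correlations=None,
        seed=seeds["cohort"],
    )
    fit = fit_model(
        cohort.trials, spec=config.model_spec(), seed=seeds["fit_two_lr"]
    )
    report = recovery_report(cohort, fit)
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(config.to_json())
        (out / "recovery_report.json").write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True)
        )
        scatter = cohort.ground_truth.params[
            ["participant_id"] + list(fit.spec.param_names)
        ].copy()
        for name in fit.spec.param_names:
            scatter[f"{name}_posterior_mean"] = fit.posterior_mean(name).values
        scatter.to_csv(out / "recovery_scatter.csv", index=False)
    return report, fit, cohort


def recovery_report(cohort: SyntheticCohort, fit: FitResult) -> RecoveryReport:
    truth = cohort.ground_truth.params.set_index("participant_id")
    correlations, bias, rmse, degenerate = {}, {}, {}, []
    for name in fit.spec.param_names:
        true_col = {"alpha": "alpha_reward"}.get(name, name)
        t = truth.loc[fit.participants, true_col].to_numpy()
        est = fit.posterior_mean(name).to_numpy()
        if np.std(t) <= 1e-10 * max(1.0, float(np.abs(t).max())):
            degenerate.append(name)
            correlations[name] = float("nan")
        else:
            correlations[name] = float(np.corrcoef(t, est)[0, 1])
        bias[name] = float(np.mean(est - t))
        rmse[name] = float(np.sqrt(np.mean((est - t) ** 2)))
    n_trials = int(
        cohort.trials[cohort.trials.phase == "training"]
        .groupby("participant_id")
        .size()
        .iloc[0]
    )
    return RecoveryReport(
        correlations=correlations,
        bias=bias,
        rmse=rmse,
        n_participants=len(fit.participants),
        n_trials_per_participant=n_trials,
        seed=fit.seed,
        sampler_settings={
            "n_chains": fit.spec.n_chains,
            "n_warmup": fit.spec.n_warmup,
            "n_draws": fit.spec.n_draws,
        },
        degenerate=degenerate,
    )


@dataclass
class StudyResults:
    """Full results bundle of one (synthetic or user-supplied) study run."""

    config: StudyRunConfig
    seeds: dict[str, int]
    glucose_summaries: pd.DataFrame
    fit: FitResult
    fit_one_lr: FitResult | None
    loo: LooResult | None
    parameter_correlations: dict[str, CorrelationPosterior]
    behavior: pd.DataFrame
    behavior_correlations: dict[str, CorrelationPosterior]
    affect_trends: dict | None
    cohort: SyntheticCohort | None


def run_study(
    config: StudyRunConfig,
    cohort: SyntheticCohort | None = None,
    group_params: CohortGroupParams | None = None,
) -> StudyResults:
    """Execute the full analysis pipeline on a synthetic (or supplied) cohort."""
    seeds = stage_seeds(config.global_seed)
    if cohort is None:
        cohort = generate_cohort(
            n_participants=config.n_participants,
            group_params=group_params,
            planted_correlations=config.planted_matrix(),
            seed=seeds["cohort"],
        )

    glucose = pd.DataFrame(
        [summarize_trace(tr).__dict__ for tr in cohort.traces]
    ).set_index("participant_id")

    fit = fit_model(
        cohort.trials, spec=config.model_spec(TWO_LR), seed=seeds["fit_two_lr"]
    )
    fit_one = None
    loo = None
    if config.compare_models:
        fit_one = fit_model(
            cohort.trials, spec=config.model_spec(ONE_LR), seed=seeds["fit_one_lr"]
        )
        loo = loo_compare(fit, fit_one)

    covariates = {
        "iauc": glucose.loc[fit.participants, "iauc"],
        "fasting_glucose": glucose.loc[fit.participants, "fasting"],
        "symptom_score": cohort.scores.set_index("participant_id").loc[
            fit.participants, "symptom_score"
        ],
    }
    parameter_correlations = {}
    for param in fit.spec.param_names:
        for cov_name, cov in covariates.items():
            key = f"{param}~{cov_name}"
            parameter_correlations[key] = posterior_correlation(
                fit, param, cov, covariate_name=cov_name
            )

    behavior = behavioral_summaries(cohort.trials, cohort.design)
    behavior = behavior.set_index("participant_id").loc[fit.participants]
    behavior_correlations = {}
    iauc = covariates["iauc"].to_numpy(dtype=float)
    for col in ("training_accuracy", "test_accuracy", "win_stay"):
        vals = behavior[col].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        if ok.sum() >= 3 and np.std(vals[ok]) > 0 and np.std(iauc[ok]) > 0:
            # behavioral rates are point statistics, so their association
            # with iAUC is an ordinary Pearson correlation
            r = float(np.corrcoef(vals[ok], iauc[ok])[0, 1])
            behavior_correlations[f"{col}~iauc"] = r

    affect = None
    if config.fit_affect:
        affect = {}
        for a_type in ("happiness", "confidence", "engagement"):
            try:
                tr = affect_trend(
                    cohort.trials, a_type, seed=seeds["affect"],
                    n_chains=2, n_warmup=300, n_draws=500,
                )
            except ValueError:
                continue
            affect[a_type] = {
                "intercept_mean": tr.intercept_mean,
                "intercept_hdi90": [tr.intercept_hdi90.lower, tr.intercept_hdi90.upper],
                "slope_mean": tr.slope_mean,
                "slope_hdi90": [tr.slope_hdi90.lower, tr.slope_hdi90.upper],
            }

    results = StudyResults(
        config=config,
        seeds=seeds,
        glucose_summaries=glucose,
        fit=fit,
        fit_one_lr=fit_one,
        loo=loo,
        parameter_correlations=parameter_correlations,
        behavior=behavior,
        behavior_correlations=behavior_correlations,
        affect_trends=affect,
        cohort=cohort,
    )
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(config.to_json())
        report = make_report(results)
        (out / "study_report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True)
        )
        (out / "study_report.md").write_text(render_report_markdown(report))
        glucose.to_csv(out / "glucose_summaries.csv")
        behavior.to_csv(out / "behavior.csv")
    return results


class IncompleteRunError(RuntimeError):
    """A results bundle is missing one or more pipeline stages."""


def make_report(results: StudyResults) -> dict:
    """Machine-readable summary of a completed study run.

    Raises :class:`IncompleteRunError` listing the missing stages if the
    bundle is incomplete (model comparison counts as a stage when the run
    was configured to include it).
    """
    missing = []
    if results.glucose_summaries is None or results.glucose_summaries.empty:
        missing.append("glucose_summaries")
    if results.fit is None:
        missing.append("fit_two_lr")
    if results.config.compare_models and (
        results.fit_one_lr is None or results.loo is None
    ):
        missing.append("loo_comparison")
    if not results.parameter_correlations:
        missing.append("parameter_correlations")
    if results.behavior is None or results.behavior.empty:
        missing.append("behavioral_summaries")
    if missing:
        raise IncompleteRunError(f"missing stages: {', '.join(missing)}")

    report: dict = {
        "config": asdict(results.config),
        "seeds": results.seeds,
        "diagnostics": {"two_lr": results.fit.diagnostics.to_dict()},
        "correlations": {
            k: v.to_dict() for k, v in sorted(results.parameter_correlations.items())
        },
        "behavior_correlations": results.behavior_correlations,
        "glucose": {
            "mean_iauc": float(results.glucose_summaries.iauc.mean()),
            "mean_fasting": float(results.glucose_summaries.fasting.mean()),
        },
    }
    if results.fit_one_lr is not None:
        report["diagnostics"]["one_lr"] = results.fit_one_lr.diagnostics.to_dict()
    if results.loo is not None:
        report["loo"] = {
            "elpd_two_lr": results.loo.elpd_a,
            "elpd_one_lr": results.loo.elpd_b,
            "elpd_diff": results.loo.elpd_diff,
            "diff_se": results.loo.diff_se,
            "favored": results.loo.favored,
            "n_high_pareto_k": results.loo.n_high_pareto_k,
        }
    if results.affect_trends:
        report["affect_trends"] = results.affect_trends
    return report


def render_report_markdown(report: dict) -> str:
    """Human-readable rendering: posterior mean r with 90% HDI per effect."""
    lines = ["# Study run report", ""]
    lines.append("## Posterior correlations (mean r, 90% HDI)")
    for key, c in report["correlations"].items():
        lo, hi = c["hdi90"]
        flags = []
        if c["excludes_zero_90"]:
            flags.append("90% HDI excludes 0")
        elif c["excludes_zero_66"]:
            flags.append("66% HDI excludes 0")
        flag = f"  ({'; '.join(flags)})" if flags else ""
        lines.append(
            f"- {key}: r = {c['mean']:.2f}, 90% HDI [{lo:.2f}, {hi:.2f}]{flag}"
        )
    if "loo" in report:
        loo = report["loo"]
        lines += [
            "",
            "## Model comparison (PSIS-LOO)",
            f"- elpd difference (2-LR minus 1-LR): {loo['elpd_diff']:.1f} "
            f"(SE {loo['diff_se']:.1f}); favored: {loo['favored']}",
        ]
    if "affect_trends" in report:
        lines += ["", "## Affect trends"]
        for a_type, tr in report["affect_trends"].items():
            lo, hi = tr["slope_hdi90"]
            lines.append(
                f"- {a_type}: starts at {tr['intercept_mean']:.1f}%, slope "
                f"{tr['slope_mean']:.3f} %/trial (90% HDI [{lo:.3f}, {hi:.3f}])"
            )
    lines.append("")
    return "\n".join(lines)
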
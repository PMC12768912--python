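"""Posterior association analyses and behavioral summaries.

Implements the posterior-draw correlation procedure (a Pearson
correlation between subject-level parameter draws and a covariate,
computed at every posterior draw, summarized by its mean and highest
density intervals), HDIs by shortest sorted-window scan, a Bayesian
linear regression with weakly informative priors, model-agnostic
behavioral summaries (training/test accuracy, win-stay, lose-shift),
hierarchical affect-trend estimation, and the exact power-based sample
size for detecting a correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, special, stats as sps

from .agents import MISSING
from .sampler import NutsConfig, sample_nuts
from .task import TaskDesign


# ---------------------------------------------------------------------------
# highest density intervals


@dataclass(frozen=True)
class HdiInterval:
    lower: float
    upper: float
    mass: float

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, x: float) -> bool:
        return self.lower <= x <= self.upper


def hdi(samples, mass: float = 0.90) -> HdiInterval:
    """Shortest interval containing ``ceil(mass * n)`` of the samples.

    Sorted-window scan; for multimodal samples this still returns a single
    interval (the unimodal-interval convention).
    """
    if not 0.0 < mass < 1.0:
        raise ValueError(f"mass must be in (0, 1), got {mass}")
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    if x.size < 2:
        raise ValueError("hdi needs at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("hdi requires finite samples")
    k = int(np.ceil(mass * x.size))
    k = max(k, 2)
    widths = x[k - 1 :] - x[: x.size - k + 1]
    i = int(np.argmin(widths))
    return HdiInterval(lower=float(x[i]), upper=float(x[i + k - 1]), mass=mass)


# ---------------------------------------------------------------------------
# posterior-draw correlations


@dataclass
class CorrelationPosterior:
    """Posterior distribution of a parameter-covariate Pearson correlation."""

    parameter: str
    covariate: str
    values: np.ndarray  # one correlation per posterior draw
    mean: float
    hdi90: HdiInterval
    hdi66: HdiInterval
    p_positive: float

    @property
    def excludes_zero_90(self) -> bool:
        return not self.hdi90.contains(0.0)

    @property
    def excludes_zero_66(self) -> bool:
        return not self.hdi66.contains(0.0)

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "covariate": self.covariate,
            "mean": self.mean,
            "hdi90": [self.hdi90.lower, self.hdi90.upper],
            "hdi66": [self.hdi66.lower, self.hdi66.upper],
            "p_positive": self.p_positive,
            "excludes_zero_90": self.excludes_zero_90,
            "excludes_zero_66": self.excludes_zero_66,
        }


def correlation_posterior_from_draws(
    draws: np.ndarray,
    covariate: np.ndarray,
    parameter: str = "parameter",
    covariate_name: str = "covariate",
) -> CorrelationPosterior:
    """Per-draw Pearson correlations between (draws, participants) and a covariate."""
    draws = np.asarray(draws, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    if draws.ndim != 2:
        raise ValueError("draws must be (n_draws, n_participants)")
    if cov.shape != (draws.shape[1],):
        raise ValueError(
            f"covariate must have one value per participant "
            f"({draws.shape[1]}), got shape {cov.shape}"
        )
    if not np.all(np.isfinite(cov)):
        raise ValueError("covariate contains non-finite values")
    cov_c = cov - cov.mean()
    cov_ss = float(cov_c @ cov_c)
    if cov_ss == 0.0:
        raise ValueError("covariate has zero variance; correlation undefined")
    d_c = draws - draws.mean(axis=1, keepdims=True)
    d_ss = np.einsum("ij,ij->i", d_c, d_c)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (d_c @ cov_c) / np.sqrt(d_ss * cov_ss)
    if np.any(~np.isfinite(r)):
        raise ValueError("some draws have zero parameter variance across participants")
    return CorrelationPosterior(
        parameter=parameter,
        covariate=covariate_name,
        values=r,
        mean=float(r.mean()),
        hdi90=hdi(r, 0.90),
        hdi66=hdi(r, 0.66),
        p_positive=float((r > 0).mean()),
    )


def posterior_correlation(
    fit, parameter: str, covariate, covariate_name: str = "covariate"
) -> CorrelationPosterior:
    """Correlate subject-level parameter draws with a per-participant covariate.

    ``covariate`` may be a mapping/Series indexed by participant id or an
    array aligned with the fit's participant order. Correlations are on the
    natural (constrained) parameter scale.
    """
    draws = fit.draws_matrix(parameter)
    if isinstance(covariate, (dict, pd.Series)):
        cov = np.array([covariate[p] for p in fit.participants], dtype=float)
    else:
        cov = np.asarray(covariate, dtype=float)
    return correlation_posterior_from_draws(
        draws, cov, parameter=parameter, covariate_name=covariate_name
    )


# ---------------------------------------------------------------------------
# Bayesian linear regression


@dataclass
class RegressionPosterior:
    """Coefficient draws and HDI summaries of a Bayesian linear regression."""

    names: list[str]
    coef_draws: np.ndarray  # (n_draws, n_coef)
    sigma_draws: np.ndarray
    means: np.ndarray
    hdi90: list[HdiInterval]
    hdi66: list[HdiInterval]

    def coefficient(self, name: str) -> dict:
        j = self.names.index(name)
        return {
            "mean": float(self.means[j]),
            "hdi90": [self.hdi90[j].lower, self.hdi90[j].upper],
            "hdi66": [self.hdi66[j].lower, self.hdi66[j].upper],
            "excludes_zero_90": not self.hdi90[j].contains(0.0),
            "excludes_zero_66": not self.hdi66[j].contains(0.0),
        }


def bayesian_regression(
    outcome,
    predictors: pd.DataFrame | np.ndarray | None = None,
    seed: int = 0,
    n_chains: int = 2,
    n_warmup: int = 400,
    n_draws: int = 1000,
) -> RegressionPosterior:
    """Normal-likelihood linear regression sampled by NUTS.

    Weakly informative priors in the style of rstanarm's defaults:
    intercept ~ N(mean(y), 2.5 sd(y)); slopes ~ N(0, 2.5 sd(y)/sd(x_j));
    sigma ~ half-N(0, 2.5 sd(y)). Pass ``predictors=None`` for an
    intercept-only model. Complete cases only.
    """
    y = np.asarray(outcome, dtype=float)
    if predictors is None:
        x = np.empty((y.size, 0))
        names = ["intercept"]
    elif isinstance(predictors, pd.DataFrame):
        x = predictors.to_numpy(dtype=float)
        names = ["intercept"] + list(predictors.columns)
    else:
        x = np.asarray(predictors, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        names = ["intercept"] + [f"x{j}" for j in range(x.shape[1])]
    keep = np.isfinite(y) & np.all(np.isfinite(x), axis=1)
    y, x = y[keep], x[keep]
    n = y.size
    if n < 3:
        raise ValueError("regression needs at least 3 complete cases")
    design = np.column_stack([np.ones(n), x])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design matrix")

    sd_y = float(np.std(y, ddof=1)) or 1.0
    prior_loc = np.r_[float(np.mean(y)), np.zeros(x.shape[1])]
    sd_x = np.std(x, axis=0, ddof=1) if x.shape[1] else np.empty(0)
    sd_x[sd_x == 0] = 1.0
    prior_sd = np.r_[2.5 * sd_y, 2.5 * sd_y / sd_x] if x.shape[1] else np.array([2.5 * sd_y])
    sigma_scale = 2.5 * sd_y

    xtx = design.T @ design
    xty = design.T @ y
    yty = float(y @ y)
    p = design.shape[1]

    s_floor = 1e-3 * sd_y  # keeps the target proper when residuals vanish

    def logp_grad(vec):
        b = vec[:p]
        log_s = vec[p]
        e_s = np.exp(log_s)
        s = s_floor + e_s
        s2 = s * s
        resid_ss = yty - 2 * float(b @ xty) + float(b @ xtx @ b)
        lp = (
            -0.5 * resid_ss / s2
            - n * np.log(s)
            - 0.5 * float(((b - prior_loc) / prior_sd) @ ((b - prior_loc) / prior_sd))
            - 0.5 * s2 / sigma_scale**2
            + log_s
        )
        g = np.empty(p + 1)
        g[:p] = (xty - xtx @ b) / s2 - (b - prior_loc) / prior_sd**2
        g[p] = (resid_ss / (s2 * s) - n / s - s / sigma_scale**2) * e_s + 1.0
        return lp, g

    init = np.r_[np.linalg.lstsq(design, y, rcond=None)[0], np.log(sd_y)]
    run = sample_nuts(
        logp_grad,
        p + 1,
        NutsConfig(n_chains=n_chains, n_warmup=n_warmup, n_draws=n_draws,
                   init_jitter=0.1),
        seed=seed,
        init=init,
    )
    flat = run.draws.reshape(-1, p + 1)
    coef = flat[:, :p]
    return RegressionPosterior(
        names=names,
        coef_draws=coef,
        sigma_draws=s_floor + np.exp(flat[:, p]),
        means=coef.mean(axis=0),
        hdi90=[hdi(coef[:, j], 0.90) for j in range(p)],
        hdi66=[hdi(coef[:, j], 0.66) for j in range(p)],
    )


# ---------------------------------------------------------------------------
# behavioral summaries


@dataclass(frozen=True)
class BehavioralSummary:
    participant_id: str
    training_accuracy: float
    test_accuracy: float
    win_stay: float  # NaN if no rewarded repeat opportunities
    lose_shift: float
    n_training: int
    n_test: int
    n_win_stay_opportunities: int
    n_lose_shift_opportunities: int


def behavioral_summaries(
    trials: pd.DataFrame,
    design: TaskDesign,
    win_stay_mode: str = "pair",
) -> pd.DataFrame:
    """Per-participant accuracy and win-stay/lose-shift rates.

    Accuracy is the probability of choosing the higher-reward-probability
    symbol. Win-stay is the probability of repeating the previously chosen
    symbol on the next opportunity given the previous outcome was a reward;
    lose-shift analogously for non-reward. ``win_stay_mode='pair'``
    conditions on the next presentation of the same stimulus pair (pairs
    interleave during training); ``'trial'`` conditions on the immediately
    following trial regardless of pair. Missed trials are excluded
    throughout.
    """
    if win_stay_mode not in ("pair", "trial"):
        raise ValueError("win_stay_mode must be 'pair' or 'trial'")
    rows = []
    for pid, grp in trials.groupby("participant_id", sort=True):
        grp = grp.sort_values(["phase", "trial_index"])
        train = grp[(grp.phase == "training") & (grp.chosen_symbol != MISSING)]
        test = grp[(grp.phase == "test") & (grp.chosen_symbol != MISSING)]
        train_acc = _accuracy(train, design)
        test_acc = _accuracy(test, design)
        ws_num = ws_den = ls_num = ls_den = 0
        if win_stay_mode == "pair":
            groups = train.groupby(
                train.apply(
                    lambda r: frozenset((r.left_symbol, r.right_symbol)), axis=1
                ),
                sort=False,
            )
            sequences = [g for _, g in groups]
        else:
            sequences = [train]
        for seq in sequences:
            ch = seq.chosen_symbol.to_numpy()
            out = seq.outcome.to_numpy()
            for i in range(len(ch) - 1):
                stayed = ch[i + 1] == ch[i]
                if out[i] == 1:
                    ws_den += 1
                    ws_num += stayed
                else:
                    ls_den += 1
                    ls_num += not stayed
        rows.append(
            BehavioralSummary(
                participant_id=str(pid),
                training_accuracy=train_acc,
                test_accuracy=test_acc,
                win_stay=ws_num / ws_den if ws_den else np.nan,
                lose_shift=ls_num / ls_den if ls_den else np.nan,
                n_training=len(train),
                n_test=len(test),
                n_win_stay_opportunities=ws_den,
                n_lose_shift_opportunities=ls_den,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def _accuracy(sub: pd.DataFrame, design: TaskDesign) -> float:
    if sub.empty:
        return np.nan
    correct = [
        design.higher_symbol(l, r) == c
        for l, r, c in zip(sub.left_symbol, sub.right_symbol, sub.chosen_symbol)
    ]
    return float(np.mean(correct))


# ---------------------------------------------------------------------------
# affect trends


@dataclass
class AffectTrend:
    """Hierarchical linear trend of an affect rating over training trials."""

    rating_type: str
    intercept_mean: float  # value at trial 1
    intercept_hdi90: HdiInterval
    slope_mean: float  # percentage points per trial
    slope_hdi90: HdiInterval
    interaction_mean: float | None
    interaction_hdi90: HdiInterval | None
    intercept_draws: np.ndarray
    slope_draws: np.ndarray


def affect_trend(
    trials: pd.DataFrame,
    rating_type: str,
    seed: int = 0,
    moderator=None,
    n_chains: int = 2,
    n_warmup: int = 400,
    n_draws: int = 1000,
) -> AffectTrend:
    """Bayesian mixed-effects regression of an affect rating on trial index.

    Model: rating ~ (b0 + u0_i) + (b1 + u1_i [+ b2 * x_i]) * (trial - 1),
    with participant random intercepts/slopes (non-centered) and Gaussian
    noise. ``moderator`` optionally supplies a per-participant covariate
    x_i (standardized internally) whose interaction with the trial slope is
    estimated. Reports the fixed intercept at trial 1 and slope per trial
    with 90% HDIs.
    """
    sub = trials[
        (trials.phase == "training")
        & (trials.affect_type == rating_type)
        & trials.affect_rating.notna()
    ]
    if sub.empty:
        raise ValueError(f"no ratings of type {rating_type!r}")
    pids = sorted(sub.participant_id.unique())
    counts = sub.groupby("participant_id").size()
    if len(pids) < 2 or (counts < 2).any():
        raise ValueError("affect_trend needs >= 2 participants with >= 2 ratings each")
    p_idx = {p: i for i, p in enumerate(pids)}
    i_part = sub.participant_id.map(p_idx).to_numpy()
    t = sub.trial_index.to_numpy(dtype=float) - 1.0
    y = sub.affect_rating.to_numpy(dtype=float)
    n_p = len(pids)

    if moderator is not None:
        if isinstance(moderator, (dict, pd.Series)):
            x_mod = np.array([moderator[p] for p in pids], dtype=float)
        else:
            x_mod = np.asarray(moderator, dtype=float)
        x_mod = (x_mod - x_mod.mean()) / (x_mod.std(ddof=1) or 1.0)
    else:
        x_mod = None

    # internally the intercept sits at the mean trial (centering decorrelates
    # it from the slope); parameter vector:
    # b0c, b1, [b2], log_tau0, log_tau1, log_sigma, z0 (P), z1 (P)
    t_mean = float(t.mean())
    tc = t - t_mean
    n_fixed = 3 if x_mod is not None else 2
    dim = n_fixed + 3 + 2 * n_p
    sd_y = float(np.std(y, ddof=1)) or 1.0
    b0_loc, b0_scale = float(np.mean(y)), 2.5 * sd_y
    b_scale = 1.0  # slopes in %-points/trial: unit-scale prior is weakly informative
    s_floor = 1e-3 * sd_y  # keeps the target proper when residuals vanish

    def logp_grad(vec):
        b0, b1 = vec[0], vec[1]
        b2 = vec[2] if x_mod is not None else 0.0
        lt0, lt1, ls = vec[n_fixed], vec[n_fixed + 1], vec[n_fixed + 2]
        z0 = vec[n_fixed + 3 : n_fixed + 3 + n_p]
        z1 = vec[n_fixed + 3 + n_p :]
        tau0, tau1 = np.exp(lt0), np.exp(lt1)
        e_s = np.exp(ls)
        sig = s_floor + e_s
        u0 = tau0 * z0
        u1 = tau1 * z1
        slope_i = b1 + u1 + (b2 * x_mod if x_mod is not None else 0.0)
        mu = b0 + u0[i_part] + slope_i[i_part] * tc
        resid = y - mu
        s2 = sig**2
        lp = (
            -0.5 * float(resid @ resid) / s2
            - y.size * np.log(sig)
            - 0.5 * ((b0 - b0_loc) / b0_scale) ** 2
            - 0.5 * (b1 / b_scale) ** 2
            - (0.5 * (b2 / b_scale) ** 2 if x_mod is not None else 0.0)
            - 0.5 * (tau0 / (2.5 * sd_y)) ** 2 + lt0
            - 0.5 * (tau1 / b_scale) ** 2 + lt1
            - 0.5 * (sig / (2.5 * sd_y)) ** 2 + ls
            - 0.5 * float(z0 @ z0)
            - 0.5 * float(z1 @ z1)
        )
        g = np.zeros(dim)
        w = resid / s2
        g[0] = float(w.sum()) - (b0 - b0_loc) / b0_scale**2
        wt = w * tc
        g[1] = float(wt.sum()) - b1 / b_scale**2
        if x_mod is not None:
            g[2] = float((wt * x_mod[i_part]).sum()) - b2 / b_scale**2
        gu0 = np.bincount(i_part, weights=w, minlength=n_p)
        gu1 = np.bincount(i_part, weights=wt, minlength=n_p)
        g[n_fixed] = float(gu0 @ z0) * tau0 - (tau0 / (2.5 * sd_y)) ** 2 + 1.0
        g[n_fixed + 1] = float(gu1 @ z1) * tau1 - (tau1 / b_scale) ** 2 + 1.0
        g[n_fixed + 2] = (
            float(resid @ resid) / (s2 * sig) - y.size / sig - sig / (2.5 * sd_y) ** 2
        ) * e_s + 1.0
        g[n_fixed + 3 : n_fixed + 3 + n_p] = gu0 * tau0 - z0
        g[n_fixed + 3 + n_p :] = gu1 * tau1 - z1
        return lp, g

    init = np.zeros(dim)
    init[0] = b0_loc
    init[n_fixed] = np.log(sd_y)  # tau0 start near outcome scale
    init[n_fixed + 1] = np.log(0.05)
    init[n_fixed + 2] = np.log(sd_y)
    run = sample_nuts(
        logp_grad,
        dim,
        NutsConfig(n_chains=n_chains, n_warmup=n_warmup, n_draws=n_draws,
                   init_jitter=0.1),
        seed=seed,
        init=init,
    )
    flat = run.draws.reshape(-1, dim)
    b1_d = flat[:, 1]
    b0_d = flat[:, 0] - t_mean * b1_d  # back to the trial-1 intercept
    b2_d = flat[:, 2] if x_mod is not None else None
    return AffectTrend(
        rating_type=rating_type,
        intercept_mean=float(b0_d.mean()),
        intercept_hdi90=hdi(b0_d, 0.90),
        slope_mean=float(b1_d.mean()),
        slope_hdi90=hdi(b1_d, 0.90),
        interaction_mean=float(b2_d.mean()) if b2_d is not None else None,
        interaction_hdi90=hdi(b2_d, 0.90) if b2_d is not None else None,
        intercept_draws=b0_d,
        slope_draws=b1_d,
    )


# ---------------------------------------------------------------------------
# power / sample size


def _sample_r_logpdf(r, rho, n):
    """Hotelling's exact density of the Pearson r under bivariate normality."""
    return (
        np.log(n - 2)
        + special.gammaln(n - 1)
        + 0.5 * (n - 1) * np.log1p(-(rho**2))
        - 0.5 * np.log(2 * np.pi)
        - special.gammaln(n - 0.5)
        + 0.5 * (n - 4) * np.log1p(-(r**2))
        - (n - 1.5) * np.log1p(-rho * r)
        + np.log(special.hyp2f1(0.5, 0.5, n - 0.5, 0.5 * (1 + rho * r)))
    )


def correlation_test_power(
    r: float, n: int, alpha: float = 0.05, method: str = "exact"
) -> float:
    """Power of the two-sided t test of rho = 0 when the true rho is ``r``.

    'exact' integrates Hotelling's density of the sample correlation;
    'fisher-z' uses the normal approximation on atanh(r).
    """
    if n < 4:
        return 0.0
    if method == "exact":
        t_crit = sps.t.ppf(1 - alpha / 2, n - 2)
        r_crit = t_crit / np.sqrt(n - 2 + t_crit**2)
        dens = lambda x: np.exp(_sample_r_logpdf(x, r, n))
        lo, _ = integrate.quad(dens, -1, -r_crit)
        hi, _ = integrate.quad(dens, r_crit, 1)
        return float(lo + hi)
    if method == "fisher-z":
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        z_crit = sps.norm.ppf(1 - alpha / 2)
        return float(sps.norm.sf(z_crit - z / se) + sps.norm.cdf(-z_crit - z / se))
    raise ValueError(f"unknown method {method!r}")


def sample_size_for_correlation(
    r: float, power: float = 0.80, alpha: float = 0.05, method: str = "exact"
) -> int:
    """Smallest n whose two-sided correlation test reaches the target power."""
    if not 0.0 < r < 1.0:
        raise ValueError("r must be in (0, 1)")
    if not 0.0 < power < 1.0 or not 0.0 < alpha < 1.0:
        raise ValueError("power and alpha must be in (0, 1)")
    n = 4
    while correlation_test_power(r, n, alpha, method=method) < power:
        n += 1
        if n > 100_000:
            raise ValueError("sample size exceeds 100000; infeasible inputs")
    return n
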
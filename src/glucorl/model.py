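"""Hierarchical Bayesian Q-learning models (1-LR and 2-LR variants).

Subject-level parameters live on an unconstrained scale and are drawn,
non-centered, from group-level normal distributions:

    theta_pk = mu_k + sigma_k * z_pk,   z_pk ~ N(0, 1)
    mu_k ~ N(0, 1),  sigma_k ~ half-N(0, 1)

with inverse-logit links for learning rates and an exponential link for
outcome sensitivity. The joint log density and its exact gradient over
the unconstrained vector (mu, log sigma, z) are assembled from the
compiled trial-likelihood kernel, so any gradient-based MCMC sampler can
execute the model; here it is paired with the package's NUTS sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .likelihood import PackedTrials, loglik_and_grads

ONE_LR = "one_lr"
TWO_LR = "two_lr"

#: unconstrained parameter columns per variant, in order
PARAM_NAMES = {
    ONE_LR: ("alpha", "beta"),
    TWO_LR: ("alpha_reward", "alpha_loss", "beta"),
}


@dataclass(frozen=True)
class ModelSpec:
    """Model variant, links/priors, and sampler settings.

    Defaults follow the convention of 4 chains x 1000 post-warmup draws
    (4000 total). ``beta_cap`` optionally replaces the exponential link for
    outcome sensitivity with a soft-capped logistic link ``cap * expit``,
    guarding against degenerate greedy solutions on near-deterministic data.
    """

    variant: str = TWO_LR
    q_init: float = 0.5
    prior_mu_sd: float = 1.0
    prior_sigma_sd: float = 1.0
    beta_cap: float | None = None
    #: score feedback-free test-phase choices under the frozen final Q-values
    include_test: bool = True
    n_chains: int = 4
    n_warmup: int = 1000
    n_draws: int = 1000
    target_accept: float = 0.8
    max_treedepth: int = 10

    def __post_init__(self) -> None:
        if self.variant not in (ONE_LR, TWO_LR):
            raise ValueError(f"unknown model variant {self.variant!r}")

    @property
    def param_names(self) -> tuple[str, ...]:
        return PARAM_NAMES[self.variant]

    @property
    def n_subject_params(self) -> int:
        return len(self.param_names)

    @property
    def total_draws(self) -> int:
        return self.n_chains * self.n_draws


class HierarchicalQModel:
    """Log joint density (and gradient) of the hierarchical Q-learning model.

    The unconstrained vector is laid out as
    ``[mu (K), log_sigma (K), z (P*K row-major)]`` with K subject-level
    parameters and P participants.
    """

    def __init__(self, packed: PackedTrials, spec: ModelSpec):
        self.packed = packed
        self.spec = spec
        self.n_participants = packed.n_participants
        self.k = spec.n_subject_params
        self.dim = self.k * (self.n_participants + 2)

    def unpack(self, vec: np.ndarray):
        k, p = self.k, self.n_participants
        mu = vec[:k]
        log_sigma = vec[k : 2 * k]
        z = vec[2 * k :].reshape(p, k)
        return mu, log_sigma, z

    def constrain(self, vec: np.ndarray) -> dict[str, np.ndarray]:
        """Subject-level parameters on the natural scale, plus group levels."""
        mu, log_sigma, z = self.unpack(vec)
        theta = mu + np.exp(log_sigma) * z  # (P, K)
        out: dict[str, np.ndarray] = {"group_mean": mu, "group_sd": np.exp(log_sigma)}
        for j, name in enumerate(self.spec.param_names):
            if name == "beta":
                out[name] = self._beta_from_theta(theta[:, j])
            else:
                out[name] = expit(theta[:, j])
        return out

    def _beta_from_theta(self, th: np.ndarray) -> np.ndarray:
        if self.spec.beta_cap is None:
            with np.errstate(over="ignore"):
                return np.exp(th)
        return self.spec.beta_cap * expit(th)

    def _subject_params(self, theta: np.ndarray):
        """Map theta columns to (alpha_reward, alpha_loss, beta) arrays."""
        if self.spec.variant == TWO_LR:
            a_r = expit(theta[:, 0])
            a_l = expit(theta[:, 1])
            beta = self._beta_from_theta(theta[:, 2])
        else:
            a_r = expit(theta[:, 0])
            a_l = a_r
            beta = self._beta_from_theta(theta[:, 1])
        return a_r, a_l, beta

    def pointwise_loglik(self, vec: np.ndarray) -> np.ndarray:
        """Per-participant training log-likelihood at one posterior point."""
        _, log_sigma, z = self.unpack(vec)
        mu = vec[: self.k]
        theta = mu + np.exp(log_sigma) * z
        a_r, a_l, beta = self._subject_params(theta)
        ll, _, _, _ = loglik_and_grads(
            self.packed, a_r, a_l, beta, q_init=self.spec.q_init
        )
        return ll

    def logp_grad(self, vec: np.ndarray) -> tuple[float, np.ndarray]:
        k = self.k
        mu, log_sigma, z = self.unpack(vec)
        sigma = np.exp(log_sigma)
        theta = mu + sigma * z  # (P, K)
        a_r, a_l, beta = self._subject_params(theta)

        ll, g_ar, g_al, g_b = loglik_and_grads(
            self.packed, a_r, a_l, beta, q_init=self.spec.q_init
        )

        # chain rule: likelihood gradients wrt theta columns
        g_theta = np.empty_like(theta)
        if self.spec.variant == TWO_LR:
            g_theta[:, 0] = g_ar * a_r * (1.0 - a_r)
            g_theta[:, 1] = g_al * a_l * (1.0 - a_l)
            g_theta[:, 2] = self._dbeta_dtheta(beta) * g_b
        else:
            g_theta[:, 0] = (g_ar + g_al) * a_r * (1.0 - a_r)
            g_theta[:, 1] = self._dbeta_dtheta(beta) * g_b

        # priors: mu ~ N(0, prior_mu_sd), sigma ~ half-N(0, prior_sigma_sd)
        # (log-sigma parametrization adds the Jacobian term +log_sigma), z ~ N(0,1)
        mu_var = self.spec.prior_mu_sd**2
        sg_var = self.spec.prior_sigma_sd**2
        logp = (
            float(ll.sum())
            - 0.5 * float(mu @ mu) / mu_var
            - 0.5 * float((sigma**2).sum()) / sg_var
            + float(log_sigma.sum())
            - 0.5 * float((z * z).sum())
        )

        grad = np.empty_like(vec)
        grad[:k] = g_theta.sum(axis=0) - mu / mu_var
        grad[k : 2 * k] = (
            (g_theta * z).sum(axis=0) * sigma - sigma**2 / sg_var + 1.0
        )
        grad[2 * k :] = (g_theta * sigma - z).ravel()
        return logp, grad

    def _dbeta_dtheta(self, beta: np.ndarray) -> np.ndarray:
        if self.spec.beta_cap is None:
            return beta
        return beta * (1.0 - beta / self.spec.beta_cap)
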
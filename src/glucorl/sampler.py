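"""No-U-Turn Hamiltonian Monte Carlo sampler.

A self-contained implementation of dynamic multinomial HMC (NUTS) over a
user-supplied log-density-and-gradient callable: recursive doubling with
the generalized no-U-turn criterion, multinomial sampling of the proposal
within the trajectory, dual-averaging step-size adaptation toward a
target acceptance statistic, and windowed diagonal mass-matrix
adaptation. Divergences (energy error > 1000), tree depths, and
per-draw energies are recorded so the standard Hamiltonian diagnostics
(divergence count, split-Rhat, E-BFMI, treedepth saturation) can be
computed downstream.

Seeded runs are bit-reproducible: chains are advanced sequentially with
independent generators spawned from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]

DIVERGENCE_THRESHOLD = 1000.0  # energy error beyond which a transition diverges


@dataclass(frozen=True)
class NutsConfig:
    n_chains: int = 4
    n_warmup: int = 1000
    n_draws: int = 1000
    target_accept: float = 0.8
    max_treedepth: int = 10
    init_jitter: float = 0.5  # chains start at iid U(-jitter, jitter)


@dataclass
class SamplerRun:
    """Raw MCMC output: arrays indexed (chain, draw[, dim])."""

    draws: np.ndarray  # (chains, n_draws, dim)
    logp: np.ndarray  # (chains, n_draws)
    energy: np.ndarray  # (chains, n_draws)
    diverging: np.ndarray  # (chains, n_draws) bool
    tree_depth: np.ndarray  # (chains, n_draws) int
    accept_stat: np.ndarray  # (chains, n_draws)
    step_size: np.ndarray  # (chains,)
    inv_mass: np.ndarray  # (chains, dim)

    @property
    def n_divergent(self) -> int:
        return int(self.diverging.sum())


class _Tree:
    __slots__ = (
        "q_minus", "p_minus", "g_minus", "q_plus", "p_plus", "g_plus",
        "q_prop", "lp_prop", "g_prop", "p_prop", "logw", "rho",
        "diverged", "turning", "sum_accept", "n_steps",
    )

    def __init__(self, q, p, g, lp, logw, sum_accept):
        self.q_minus = self.q_plus = self.q_prop = q
        self.p_minus = self.p_plus = self.p_prop = p
        self.g_minus = self.g_plus = self.g_prop = g
        self.lp_prop = lp
        self.logw = logw
        self.rho = p.copy()
        self.diverged = False
        self.turning = False
        self.sum_accept = sum_accept
        self.n_steps = 1


def _leapfrog(logp_grad, q, p, g, eps, inv_mass):
    # overflow here only occurs while probing overly large step sizes; the
    # resulting non-finite energies are rejected by the caller
    with np.errstate(over="ignore", invalid="ignore"):
        p_half = p + 0.5 * eps * g
        q_new = q + eps * inv_mass * p_half
        lp, g_new = logp_grad(q_new)
        p_new = p_half + 0.5 * eps * g_new
    return q_new, p_new, g_new, lp


def _kinetic(p, inv_mass):
    with np.errstate(over="ignore", invalid="ignore"):
        return 0.5 * float(np.dot(p * p, inv_mass))


def _is_turning(rho, p_minus, p_plus, inv_mass):
    return (
        np.dot(rho, inv_mass * p_minus) <= 0 or np.dot(rho, inv_mass * p_plus) <= 0
    )


def _build_tree(logp_grad, q, p, g, direction, depth, eps, inv_mass, h0, rng):
    if depth == 0:
        q1, p1, g1, lp1 = _leapfrog(logp_grad, q, p, g, direction * eps, inv_mass)
        h = -lp1 + _kinetic(p1, inv_mass)
        if not np.isfinite(h):
            h = np.inf
        dh = h0 - h  # log weight relative to the initial point
        accept = float(np.exp(min(dh, 0.0))) if np.isfinite(dh) else 0.0
        tree = _Tree(q1, p1, g1, lp1, dh, accept)
        tree.diverged = (h - h0) > DIVERGENCE_THRESHOLD
        return tree

    first = _build_tree(logp_grad, q, p, g, direction, depth - 1, eps, inv_mass, h0, rng)
    if first.diverged or first.turning:
        return first
    if direction > 0:
        second = _build_tree(
            logp_grad, first.q_plus, first.p_plus, first.g_plus,
            direction, depth - 1, eps, inv_mass, h0, rng,
        )
    else:
        second = _build_tree(
            logp_grad, first.q_minus, first.p_minus, first.g_minus,
            direction, depth - 1, eps, inv_mass, h0, rng,
        )
    # merge second into first
    if direction > 0:
        first.q_plus, first.p_plus, first.g_plus = (
            second.q_plus, second.p_plus, second.g_plus,
        )
    else:
        first.q_minus, first.p_minus, first.g_minus = (
            second.q_minus, second.p_minus, second.g_minus,
        )
    total = np.logaddexp(first.logw, second.logw)
    # multinomial sampling within the subtree
    if np.log(rng.random()) < second.logw - total:
        first.q_prop, first.lp_prop, first.g_prop, first.p_prop = (
            second.q_prop, second.lp_prop, second.g_prop, second.p_prop,
        )
    first.logw = total
    first.rho = first.rho + second.rho
    first.sum_accept += second.sum_accept
    first.n_steps += second.n_steps
    first.diverged = second.diverged
    first.turning = second.turning or _is_turning(
        first.rho, first.p_minus, first.p_plus, inv_mass
    )
    return first


def _nuts_transition(logp_grad, q, lp, g, eps, inv_mass, max_treedepth, rng):
    p0 = rng.standard_normal(q.size) / np.sqrt(inv_mass)
    h0 = -lp + _kinetic(p0, inv_mass)
    tree = _Tree(q, p0, g, lp, 0.0, 1.0)
    tree.p_prop = p0
    diverged = False
    depth = 0
    sum_accept = 0.0
    n_steps = 0
    while depth < max_treedepth:
        direction = 1 if rng.random() < 0.5 else -1
        if direction > 0:
            sub = _build_tree(
                logp_grad, tree.q_plus, tree.p_plus, tree.g_plus,
                direction, depth, eps, inv_mass, h0, rng,
            )
        else:
            sub = _build_tree(
                logp_grad, tree.q_minus, tree.p_minus, tree.g_minus,
                direction, depth, eps, inv_mass, h0, rng,
            )
        sum_accept += sub.sum_accept
        n_steps += sub.n_steps
        if sub.diverged:
            diverged = True
            break
        if sub.turning:
            break
        # biased progressive sampling favors the new subtree
        if np.log(rng.random()) < sub.logw - tree.logw:
            tree.q_prop, tree.lp_prop, tree.g_prop, tree.p_prop = (
                sub.q_prop, sub.lp_prop, sub.g_prop, sub.p_prop,
            )
        if direction > 0:
            tree.q_plus, tree.p_plus, tree.g_plus = sub.q_plus, sub.p_plus, sub.g_plus
        else:
            tree.q_minus, tree.p_minus, tree.g_minus = (
                sub.q_minus, sub.p_minus, sub.g_minus,
            )
        tree.rho = tree.rho + sub.rho
        tree.logw = np.logaddexp(tree.logw, sub.logw)
        depth += 1
        if _is_turning(tree.rho, tree.p_minus, tree.p_plus, inv_mass):
            break
    accept_stat = sum_accept / max(n_steps, 1)
    energy = -tree.lp_prop + _kinetic(tree.p_prop, inv_mass)
    return tree.q_prop, tree.lp_prop, tree.g_prop, {
        "accept_stat": accept_stat,
        "diverging": diverged,
        "tree_depth": depth,
        "energy": energy,
    }


def _find_reasonable_eps(logp_grad, q, lp, g, inv_mass, rng):
    eps = 1.0
    p = rng.standard_normal(q.size) / np.sqrt(inv_mass)
    h0 = -lp + _kinetic(p, inv_mass)
    _, p1, _, lp1 = _leapfrog(logp_grad, q, p, g, eps, inv_mass)
    h1 = -lp1 + _kinetic(p1, inv_mass)
    dh = h0 - h1 if np.isfinite(h1) else -np.inf
    direction = 1 if dh > np.log(0.5) else -1
    for _ in range(100):
        eps *= 2.0**direction
        _, p1, _, lp1 = _leapfrog(logp_grad, q, p, g, eps, inv_mass)
        h1 = -lp1 + _kinetic(p1, inv_mass)
        dh = h0 - h1 if np.isfinite(h1) else -np.inf
        if (direction == 1 and dh <= np.log(0.5)) or (
            direction == -1 and dh >= np.log(0.5)
        ):
            break
    return eps


def _mass_windows(n_warmup: int) -> tuple[int, list[int], int]:
    """Stan-style warmup phases: (init_buffer, slow window ends, term_buffer)."""
    if n_warmup < 20:
        return n_warmup, [], 0
    init_buffer = max(1, int(round(0.15 * n_warmup))) if n_warmup < 150 else 75
    term_buffer = max(1, int(round(0.10 * n_warmup))) if n_warmup < 150 else 50
    base = 25 if n_warmup >= 150 else max(5, int(round(0.1 * n_warmup)))
    ends: list[int] = []
    pos, width = init_buffer, base
    while pos < n_warmup - term_buffer:
        end = pos + width
        if end + 2 * width > n_warmup - term_buffer:
            end = n_warmup - term_buffer
        ends.append(end)
        pos = end
        width *= 2
    return init_buffer, ends, term_buffer


class _DualAveraging:
    def __init__(self, eps0, target, gamma=0.05, t0=10.0, kappa=0.75):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.gamma, self.t0, self.kappa = gamma, t0, kappa
        self.m = 0
        self.h_bar = 0.0
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0

    def update(self, accept_stat):
        self.m += 1
        frac = 1.0 / (self.m + self.t0)
        self.h_bar = (1 - frac) * self.h_bar + frac * (self.target - accept_stat)
        self.log_eps = self.mu - np.sqrt(self.m) / self.gamma * self.h_bar
        w = self.m ** (-self.kappa)
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar

    @property
    def eps(self):
        return float(np.exp(self.log_eps))

    @property
    def eps_bar(self):
        return float(np.exp(self.log_eps_bar))


def sample_nuts(
    logp_grad: LogpGrad,
    dim: int,
    config: NutsConfig = NutsConfig(),
    seed: int = 0,
    init: np.ndarray | None = None,
) -> SamplerRun:
    """Run seeded NUTS chains over a log density with gradient.

    ``init`` may give a shared starting point (chains add seeded jitter);
    by default chains start at iid uniform(-jitter, jitter) positions.
    """
    cfg = config
    chain_seeds = np.random.SeedSequence(seed).spawn(cfg.n_chains)
    draws = np.empty((cfg.n_chains, cfg.n_draws, dim))
    logp = np.empty((cfg.n_chains, cfg.n_draws))
    energy = np.empty((cfg.n_chains, cfg.n_draws))
    diverging = np.zeros((cfg.n_chains, cfg.n_draws), dtype=bool)
    tree_depth = np.zeros((cfg.n_chains, cfg.n_draws), dtype=np.int64)
    accept_stat = np.empty((cfg.n_chains, cfg.n_draws))
    step_sizes = np.empty(cfg.n_chains)
    inv_masses = np.empty((cfg.n_chains, dim))

    for c, ss in enumerate(chain_seeds):
        rng = np.random.default_rng(ss)
        if init is not None:
            q = np.asarray(init, dtype=float) + cfg.init_jitter * rng.uniform(
                -1, 1, size=dim
            )
        else:
            q = cfg.init_jitter * rng.uniform(-1, 1, size=dim)
        lp, g = logp_grad(q)
        if not np.isfinite(lp):
            raise ValueError("log density is not finite at the initial point")
        inv_mass = np.ones(dim)

        init_buffer, window_ends, _ = _mass_windows(cfg.n_warmup)
        eps = _find_reasonable_eps(logp_grad, q, lp, g, inv_mass, rng)
        da = _DualAveraging(eps, cfg.target_accept)
        welford_n = 0
        welford_mean = np.zeros(dim)
        welford_m2 = np.zeros(dim)

        for it in range(cfg.n_warmup):
            q, lp, g, stats = _nuts_transition(
                logp_grad, q, lp, g, da.eps, inv_mass, cfg.max_treedepth, rng
            )
            da.update(stats["accept_stat"])
            if it >= init_buffer and (not window_ends or it < window_ends[-1]):
                welford_n += 1
                delta = q - welford_mean
                welford_mean += delta / welford_n
                welford_m2 += delta * (q - welford_mean)
            if window_ends and (it + 1) == window_ends[0]:
                window_ends.pop(0)
                if welford_n >= 10:
                    var = welford_m2 / max(welford_n - 1, 1)
                    # Stan's regularization toward the unit metric
                    inv_mass = (
                        welford_n / (welford_n + 5.0) * var
                        + 1e-3 * 5.0 / (welford_n + 5.0)
                    )
                welford_n = 0
                welford_mean[:] = 0.0
                welford_m2[:] = 0.0
                eps = _find_reasonable_eps(logp_grad, q, lp, g, inv_mass, rng)
                da = _DualAveraging(eps, cfg.target_accept)

        eps_final = da.eps_bar if cfg.n_warmup > 0 else da.eps
        for it in range(cfg.n_draws):
            q, lp, g, stats = _nuts_transition(
                logp_grad, q, lp, g, eps_final, inv_mass, cfg.max_treedepth, rng
            )
            draws[c, it] = q
            logp[c, it] = lp
            energy[c, it] = stats["energy"]
            diverging[c, it] = stats["diverging"]
            tree_depth[c, it] = stats["tree_depth"]
            accept_stat[c, it] = stats["accept_stat"]
        step_sizes[c] = eps_final
        inv_masses[c] = inv_mass

    return SamplerRun(
        draws=draws,
        logp=logp,
        energy=energy,
        diverging=diverging,
        tree_depth=tree_depth,
        accept_stat=accept_stat,
        step_size=step_sizes,
        inv_mass=inv_masses,
    )
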
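"""Preregistration-style power analysis for a correlation effect.

Finds the smallest sample able to detect r = 0.4 with 80% power at
alpha = 0.05 under the exact sampling distribution of the Pearson
correlation, cross-checks it by Monte-Carlo simulation, and contrasts it
with the Fisher-z approximation (which is one participant more
conservative). Writes results/power_analysis.json.

Finding: n = 46 (exact; Fisher-z gives 47); simulated power at 46 clears
0.80 while 45 falls short.
"""

import json
from pathlib import Path

import numpy as np
from scipy import stats

from glucorl.stats import correlation_test_power, sample_size_for_correlation

R, POWER, ALPHA, SEED = 0.4, 0.80, 0.05, 0


def monte_carlo_power(r, n, alpha, reps=50_000, seed=SEED):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((reps, n))
    y = r * x + np.sqrt(1 - r**2) * rng.standard_normal((reps, n))
    xc = x - x.mean(1, keepdims=True)
    yc = y - y.mean(1, keepdims=True)
    rs = (xc * yc).sum(1) / np.sqrt((xc**2).sum(1) * (yc**2).sum(1))
    t = rs * np.sqrt(n - 2) / np.sqrt(1 - rs**2)
    return float((np.abs(t) > stats.t.ppf(1 - alpha / 2, n - 2)).mean())


def main():
    n_exact = sample_size_for_correlation(R, POWER, ALPHA)
    n_fisher = sample_size_for_correlation(R, POWER, ALPHA, method="fisher-z")
    out = {
        "target": {"r": R, "power": POWER, "alpha": ALPHA},
        "n_exact": n_exact,
        "n_fisher_z": n_fisher,
        "analytic_power_at_n": correlation_test_power(R, n_exact, ALPHA),
        "analytic_power_at_n_minus_1": correlation_test_power(R, n_exact - 1, ALPHA),
        "mc_power_at_n": monte_carlo_power(R, n_exact, ALPHA),
        "mc_power_at_n_minus_1": monte_carlo_power(R, n_exact - 1, ALPHA),
    }
    Path("results").mkdir(exist_ok=True)
    Path("results/power_analysis.json").write_text(json.dumps(out, indent=2))
    print(f"minimum n (exact t): {n_exact}   (Fisher-z: {n_fisher})")
    print(
        f"power at n={n_exact}: analytic {out['analytic_power_at_n']:.3f}, "
        f"Monte-Carlo {out['mc_power_at_n']:.3f}"
    )
    print(
        f"power at n={n_exact - 1}: analytic {out['analytic_power_at_n_minus_1']:.3f}, "
        f"Monte-Carlo {out['mc_power_at_n_minus_1']:.3f}"
    )


if __name__ == "__main__":
    main()
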
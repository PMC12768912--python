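import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def numeric_iauc_oracle(times, values, baseline):
    """Independent positive-area integral of a piecewise-linear trace.

    Non-crossing segments integrate exactly by the trapezoid of their
    endpoints (the integrand is linear there); segments whose excess
    changes sign are integrated on a dense uniform grid, so the kink
    error is O(dt / N^2) and negligible at N = 2e6.
    """
    times = np.asarray(times, float)
    excess = np.asarray(values, float) - baseline
    total = 0.0
    for i in range(times.size - 1):
        e1, e2 = excess[i], excess[i + 1]
        dt = times[i + 1] - times[i]
        if e1 <= 0 and e2 <= 0:
            continue
        if e1 >= 0 and e2 >= 0:
            total += 0.5 * (e1 + e2) * dt
        else:
            grid = np.linspace(0.0, dt, 2_000_001)
            seg = np.maximum(e1 + (e2 - e1) * grid / dt, 0.0)
            total += float(np.trapezoid(seg, grid))
    return total

from glucorl.agents import AgentParameters, simulate_agent
from glucorl.task import build_task_design


@pytest.fixture(scope="session")
def design():
    return build_task_design(seed=1)


@pytest.fixture(scope="session")
def small_cohort_trials(design):
    """Six simulated agents with known parameters on the shared design."""
    rng = np.random.default_rng(42)
    params = [
        AgentParameters(
            alpha_reward=float(rng.uniform(0.1, 0.7)),
            alpha_loss=float(rng.uniform(0.05, 0.5)),
            beta=float(rng.uniform(2.0, 8.0)),
        )
        for _ in range(6)
    ]
    frames = [
        simulate_agent(p, design, seed=100 + i, participant_id=f"p{i:02d}")
        for i, p in enumerate(params)
    ]
    return pd.concat(frames, ignore_index=True), params
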
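"""HDI, posterior correlations, regression, behavior, affect, power."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glucorl.agents import TRIAL_COLUMNS, AgentParameters, simulate_agent
from glucorl.stats import (
    affect_trend,
    bayesian_regression,
    behavioral_summaries,
    correlation_posterior_from_draws,
    correlation_test_power,
    hdi,
    sample_size_for_correlation,
)


def brute_force_hdi(samples, mass):
    """O(n^2) exhaustive scan over all candidate windows."""
    x = np.sort(np.asarray(samples, float))
    k = max(int(np.ceil(mass * x.size)), 2)
    best = (np.inf, None)
    for i in range(x.size - k + 1):
        width = x[i + k - 1] - x[i]
        if width < best[0]:
            best = (width, (x[i], x[i + k - 1]))
    return best[1]


class TestHdi:
    def test_point_mass(self):
        iv = hdi(np.full(50, 3.2), 0.9)
        assert (iv.lower, iv.upper) == (3.2, 3.2)

    def test_equally_spaced_grid(self):
        x = np.linspace(0, 1, 1000)
        iv = hdi(x, 0.9)
        assert iv.width == pytest.approx(0.9, abs=2e-3)
        assert (iv.lower, iv.upper) == brute_force_hdi(x, 0.9)

    @pytest.mark.parametrize("mass", [0.5, 0.66, 0.9, 0.95])
    def test_matches_brute_force_on_random_samples(self, mass):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(5, 400))
            kind = rng.integers(3)
            if kind == 0:
                x = rng.standard_normal(n)
            elif kind == 1:
                x = rng.exponential(2.0, n)
            else:  # bimodal
                x = np.concatenate(
                    [rng.normal(-3, 0.5, n // 2), rng.normal(3, 0.5, n - n // 2)]
                )
            iv = hdi(x, mass)
            assert (iv.lower, iv.upper) == brute_force_hdi(x, mass)

    def test_agrees_with_reference_implementation(self):
        import arviz as az

        rng = np.random.default_rng(5)
        x = rng.standard_normal(4000)
        iv = hdi(x, 0.9)
        lo, hi = az.hdi(x, hdi_prob=0.9)
        # the two estimators differ only in window-width convention
        assert iv.lower == pytest.approx(lo, abs=0.02)
        assert iv.upper == pytest.approx(hi, abs=0.02)

    def test_nesting_of_masses(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(2000)
        inner, outer = hdi(x, 0.66), hdi(x, 0.90)
        assert outer.lower <= inner.lower and inner.upper <= outer.upper

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            hdi([1.0], 0.9)
        with pytest.raises(ValueError):
            hdi([1.0, 2.0], 1.5)
        with pytest.raises(ValueError):
            hdi([np.nan, 1.0, 2.0], 0.9)


class TestCorrelationPosterior:
    def test_frozen_draw_perfect_correlation(self):
        rng = np.random.default_rng(0)
        draws = rng.normal(size=(100, 20))
        cov = draws[57].copy()
        post = correlation_posterior_from_draws(draws, cov)
        assert post.values[57] == pytest.approx(1.0)

    def test_constant_draws_reduce_to_plain_pearson(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=30)
        cov = rng.normal(size=30)
        draws = np.tile(vals, (500, 1))
        post = correlation_posterior_from_draws(draws, cov)
        expected = np.corrcoef(vals, cov)[0, 1]
        assert post.mean == pytest.approx(expected, rel=1e-12)
        assert post.hdi90.width == pytest.approx(0.0, abs=1e-12)

    def test_independent_covariate_centers_near_zero(self):
        rng = np.random.default_rng(2)
        draws = rng.normal(size=(2000, 200))
        cov = rng.normal(size=200)
        post = correlation_posterior_from_draws(draws, cov)
        assert abs(post.mean) < 0.05
        assert post.hdi90.contains(0.0)

    def test_hdi66_nested_in_hdi90_and_values_bounded(self):
        rng = np.random.default_rng(3)
        draws = rng.normal(size=(300, 15)) + rng.normal(size=15)
        cov = rng.normal(size=15)
        post = correlation_posterior_from_draws(draws, cov)
        assert np.all(np.abs(post.values) <= 1.0)
        assert post.hdi90.lower <= post.hdi66.lower
        assert post.hdi66.upper <= post.hdi90.upper

    def test_zero_variance_covariate_rejected(self):
        draws = np.random.default_rng(0).normal(size=(50, 10))
        with pytest.raises(ValueError, match="zero variance"):
            correlation_posterior_from_draws(draws, np.full(10, 2.0))

    def test_null_calibration_of_p_positive(self):
        """With no association, P(r > 0) spreads roughly uniformly over runs."""
        rng = np.random.default_rng(9)
        p_pos = []
        for _ in range(60):
            draws = rng.normal(size=30) + 0.15 * rng.normal(size=(400, 30))
            cov = rng.normal(size=30)
            p_pos.append(correlation_posterior_from_draws(draws, cov).p_positive)
        p_pos = np.asarray(p_pos)
        assert 0.3 < (p_pos < 0.5).mean() < 0.7  # median near 1/2
        assert p_pos.std() > 0.2  # spread, not clustered at 0.5
        assert (p_pos < 0.1).any() and (p_pos > 0.9).any()


class TestBayesianRegression:
    def test_noiseless_slope_recovered(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=100)
        y = 2.0 * x + 0.01 * rng.normal(size=100)
        post = bayesian_regression(y, x, seed=0)
        coef = post.coefficient("x0")
        assert coef["mean"] == pytest.approx(2.0, abs=0.05)
        assert coef["excludes_zero_90"]

    def test_intercept_only_matches_sample_mean(self):
        rng = np.random.default_rng(5)
        y = 3.0 + rng.normal(size=200)
        post = bayesian_regression(y, None, seed=0)
        assert post.coefficient("intercept")["mean"] == pytest.approx(
            float(np.mean(y)), abs=0.1
        )

    def test_null_slope_hdi_overlaps_zero_in_most_replicates(self):
        rng = np.random.default_rng(6)
        covered = 0
        reps = 12
        for s in range(reps):
            x = rng.normal(size=40)
            y = rng.normal(size=40)
            post = bayesian_regression(y, x, seed=s, n_draws=500)
            covered += not post.coefficient("x0")["excludes_zero_90"]
        assert covered >= reps - 3  # ~90% nominal coverage

    def test_rank_deficient_design_rejected(self):
        x = np.ones((10, 2))
        y = np.arange(10.0)
        with pytest.raises(ValueError, match="rank"):
            bayesian_regression(y, x, seed=0)

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError):
            bayesian_regression([1.0, 2.0], None, seed=0)


def policy_trials(policy, n=60, pid="p0"):
    """Alternating A/B pair with deterministic outcomes and a fixed policy."""
    rows = []
    prev_choice, prev_outcome = None, None
    rng = np.random.default_rng(0)
    for t in range(n):
        if prev_choice is None:
            choice = "A"
        else:
            choice = policy(prev_choice, prev_outcome)
        outcome = float(rng.random() < 0.5)
        rows.append((pid, "training", 1, t + 1, "A", "B", choice, outcome, None, np.nan))
        prev_choice, prev_outcome = choice, outcome
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


class TestBehavioralSummaries:
    def test_deterministic_stay_policy_has_winstay_one(self, design):
        trials = policy_trials(lambda c, o: c if o == 1 else ("B" if c == "A" else "A"))
        summary = behavioral_summaries(trials, design).iloc[0]
        assert summary.win_stay == 1.0
        assert summary.lose_shift == 1.0

    def test_deterministic_shift_policy_has_winstay_zero(self, design):
        trials = policy_trials(lambda c, o: ("B" if c == "A" else "A") if o == 1 else c)
        summary = behavioral_summaries(trials, design).iloc[0]
        assert summary.win_stay == 0.0
        assert summary.lose_shift == 0.0

    def test_hand_built_six_trial_fixture(self, design):
        """3 reward-followed trials: 2 repeats, 1 switch -> win-stay 2/3."""
        rows = [
            ("p0", "training", 1, 1, "A", "B", "A", 1.0, None, np.nan),
            ("p0", "training", 1, 2, "A", "B", "A", 1.0, None, np.nan),  # stay
            ("p0", "training", 1, 3, "A", "B", "A", 1.0, None, np.nan),  # stay
            ("p0", "training", 1, 4, "A", "B", "B", 0.0, None, np.nan),  # shift
            ("p0", "training", 1, 5, "A", "B", "A", 0.0, None, np.nan),
            ("p0", "training", 1, 6, "A", "B", "A", 1.0, None, np.nan),
        ]
        trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
        summary = behavioral_summaries(trials, design).iloc[0]
        assert summary.win_stay == pytest.approx(2 / 3)
        assert summary.n_win_stay_opportunities == 3

    def test_trial_conditioning_differs_from_pair_conditioning(self, design):
        """Interleaved pairs: a win followed by a different pair is a 'shift'
        under trial conditioning but invisible to pair conditioning."""
        rows = [
            ("p", "training", 1, 1, "A", "B", "A", 1.0, None, np.nan),
            ("p", "training", 1, 2, "C", "D", "C", 1.0, None, np.nan),
            ("p", "training", 1, 3, "A", "B", "A", 0.0, None, np.nan),
            ("p", "training", 1, 4, "C", "D", "C", 0.0, None, np.nan),
        ]
        trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
        pair = behavioral_summaries(trials, design, win_stay_mode="pair").iloc[0]
        trial = behavioral_summaries(trials, design, win_stay_mode="trial").iloc[0]
        assert pair.win_stay == 1.0  # A repeated at the next A-B presentation
        assert trial.win_stay == 0.0  # the literally-next trial shows C-D

    def test_random_agent_winstay_near_half(self, design):
        params = AgentParameters(0.3, 0.3, 0.0)
        frames = [
            simulate_agent(params, design, seed=s, participant_id=f"p{s}")
            for s in range(8)
        ]
        summary = behavioral_summaries(pd.concat(frames, ignore_index=True), design)
        assert abs(summary.win_stay.mean() - 0.5) < 0.04

    def test_accuracy_of_good_learner_above_chance(self, design):
        sim = simulate_agent(AgentParameters(0.4, 0.2, 8.0), design, seed=0)
        summary = behavioral_summaries(sim, design).iloc[0]
        assert summary.training_accuracy > 0.6
        assert summary.test_accuracy > 0.6
        assert summary.n_training == 360
        assert summary.n_test == 60


class TestAffectTrend:
    def _trials_with_ratings(self, slopes, starts, n_trials=120, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(len(slopes)):
            for t in range(1, n_trials + 1):
                rating = starts[i] + slopes[i] * (t - 1)
                if noise:
                    rating += rng.normal(0, noise)
                rows.append(
                    (f"p{i}", "training", 1, t, "A", "B", "A", 1.0, "happiness",
                     float(np.clip(rating, 0, 100)))
                )
        return pd.DataFrame(rows, columns=TRIAL_COLUMNS)

    def test_noiseless_trend_recovered(self):
        trials = self._trials_with_ratings(
            slopes=[-0.08] * 6, starts=[57.6] * 6
        )
        trend = affect_trend(trials, "happiness", seed=0, n_warmup=300, n_draws=400)
        assert trend.slope_mean == pytest.approx(-0.08, abs=0.01)
        assert trend.intercept_mean == pytest.approx(57.6, abs=1.0)

    def test_zero_slope_hdi_overlaps_zero(self):
        trials = self._trials_with_ratings(
            slopes=[0.0] * 6, starts=[50.0] * 6, noise=5.0, seed=3
        )
        trend = affect_trend(trials, "happiness", seed=1, n_warmup=300, n_draws=400)
        assert trend.slope_hdi90.contains(0.0)

    def test_moderator_interaction_recovered(self):
        """A covariate that slows the decline shows a positive interaction."""
        x = np.array([-1.2, -0.6, 0.0, 0.6, 1.2, 0.3])
        slopes = -0.20 + 0.10 * x  # slope grows with the moderator
        trials = self._trials_with_ratings(
            slopes=list(slopes), starts=[60.0] * 6, noise=2.0, seed=5
        )
        trend = affect_trend(
            trials, "happiness", seed=2, moderator=x, n_warmup=300, n_draws=400
        )
        # moderator is standardized internally; expected coefficient is
        # 0.10 * sd(x)
        assert trend.interaction_mean == pytest.approx(0.10 * np.std(x, ddof=1), abs=0.03)

    def test_missing_rating_type_rejected(self):
        trials = self._trials_with_ratings(slopes=[0.0] * 3, starts=[50.0] * 3)
        with pytest.raises(ValueError, match="no ratings"):
            affect_trend(trials, "engagement", seed=0)


class TestPower:
    def test_preregistered_sample_size(self):
        assert sample_size_for_correlation(0.4, 0.80, 0.05) == 46

    def test_fisher_z_variant(self):
        assert sample_size_for_correlation(0.4, 0.80, 0.05, method="fisher-z") == 47

    def test_monotone_in_effect_size(self):
        n_small = sample_size_for_correlation(0.6, 0.80, 0.05)
        assert n_small < 46

    def test_monotone_in_power_and_alpha(self):
        assert sample_size_for_correlation(0.4, 0.90, 0.05) > 46
        assert sample_size_for_correlation(0.4, 0.80, 0.01) > 46
        assert sample_size_for_correlation(0.4, 0.80, 0.10) < 46

    def test_power_function_brackets_target_at_returned_n(self):
        assert correlation_test_power(0.4, 46) >= 0.80
        assert correlation_test_power(0.4, 45) < 0.80

    def test_invalid_inputs(self):
        for bad in [(-0.1, 0.8, 0.05), (0.4, 1.2, 0.05), (0.4, 0.8, 0.0)]:
            with pytest.raises(ValueError):
                sample_size_for_correlation(*bad)
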
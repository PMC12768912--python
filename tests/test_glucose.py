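"""iAUC correctness: hand-worked fixtures, oracle agreement, invariances."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glucorl.glucose import (
    GlucoseCurveParams,
    GlucoseTrace,
    TraceError,
    compute_iauc,
    fasting_glucose,
    generate_glucose_trace,
    read_cgm_csv,
    summarize_trace,
)


from conftest import numeric_iauc_oracle


def trace(times, values, baseline=None, pid="t"):
    return GlucoseTrace(pid, np.asarray(times, float), np.asarray(values, float), baseline)


class TestComputeIauc:
    def test_hand_worked_triangle(self):
        """Two trapezoids above baseline: ((0+2)/2)*30 + ((2+0)/2)*30 = 60."""
        t = trace([0, 30, 60], [5.0, 7.0, 5.0], baseline=5.0)
        assert compute_iauc(t) == pytest.approx(60.0, abs=1e-12)

    def test_hand_worked_baseline_crossing(self):
        """Second segment crosses baseline at t=45; area = 15 + 7.5 = 22.5."""
        t = trace([0, 30, 60], [5.0, 6.0, 4.0], baseline=5.0)
        assert compute_iauc(t) == pytest.approx(22.5, abs=1e-12)

    def test_flat_trace_is_zero(self):
        t = trace([0, 30, 60], [5.0, 5.0, 5.0], baseline=5.0)
        assert compute_iauc(t) == 0.0

    def test_fully_below_baseline_is_zero(self):
        t = trace([0, 30, 60], [4.0, 4.5, 4.2], baseline=5.0)
        assert compute_iauc(t) == 0.0

    def test_upward_crossing_counts_partial_area(self):
        # crosses baseline upward at t=15, then trapezoid to t=30
        t = trace([0, 30], [4.0, 6.0], baseline=5.0)
        assert compute_iauc(t, window=None) == pytest.approx(0.5 * 1.0 * 15.0)

    def test_too_few_readings_rejected(self):
        with pytest.raises(TraceError):
            trace([0], [5.0])

    def test_nonmonotone_times_rejected(self):
        with pytest.raises(TraceError):
            trace([0, 30, 20], [5.0, 6.0, 5.5])

    def test_matches_numeric_oracle_on_random_traces(self):
        """100 random piecewise-linear traces vs fine-grid integration."""
        rng = np.random.default_rng(2024)
        worst = 0.0
        for _ in range(100):
            n = rng.integers(3, 40)
            times = np.sort(rng.uniform(0, 120, size=n))
            times += np.arange(n) * 1e-6  # ensure strictly increasing
            values = rng.uniform(3.0, 10.0, size=n)
            baseline = rng.uniform(4.0, 6.0)
            t = trace(times, values, baseline=baseline)
            got = compute_iauc(t, window=None)
            want = numeric_iauc_oracle(times, values, baseline)
            if want > 0:
                worst = max(worst, abs(got - want) / want)
        assert worst < 1e-9

    def test_baseline_shift_invariance(self):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0, 120, 20))
        values = rng.uniform(4, 9, 20)
        t1 = trace(times, values, baseline=5.0)
        t2 = trace(times, values + 2.0, baseline=7.0)
        assert compute_iauc(t1) == pytest.approx(compute_iauc(t2), rel=1e-12)

    def test_scale_linearity(self):
        times = np.array([0.0, 10.0, 40.0, 90.0, 120.0])
        values = np.array([5.0, 7.5, 6.0, 4.5, 5.2])
        base = compute_iauc(trace(times, values, baseline=5.0), window=None)
        # time scaling
        k = 3.0
        scaled_t = compute_iauc(trace(times * k, values, baseline=5.0), window=None)
        assert scaled_t == pytest.approx(k * base, rel=1e-12)
        # value-excess scaling
        scaled_v = compute_iauc(
            trace(times, 5.0 + k * (values - 5.0), baseline=5.0), window=None
        )
        assert scaled_v == pytest.approx(k * base, rel=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(
        data=st.lists(
            st.tuples(st.floats(0.1, 119.9), st.floats(3.0, 9.0)),
            min_size=2,
            max_size=15,
            unique_by=lambda x: round(x[0], 6),
        ),
        insert_at=st.floats(0.05, 0.95),
    )
    def test_refinement_consistency(self, data, insert_at):
        """Inserting an exactly interpolated reading never changes iAUC."""
        data = sorted(data)
        times = np.array([d[0] for d in data])
        values = np.array([d[1] for d in data])
        t_new = times[0] + insert_at * (times[-1] - times[0])
        if np.min(np.abs(times - t_new)) < 1e-9:
            return
        v_new = np.interp(t_new, times, values)
        times2 = np.sort(np.append(times, t_new))
        values2 = np.interp(times2, times, values)
        assert np.interp(t_new, times2, values2) == pytest.approx(v_new)
        a = compute_iauc(trace(times, values, baseline=5.0), window=None)
        b = compute_iauc(trace(times2, values2, baseline=5.0), window=None)
        assert b == pytest.approx(a, rel=1e-9, abs=1e-9)

    def test_monotone_in_each_reading(self):
        rng = np.random.default_rng(3)
        times = np.sort(rng.uniform(0, 120, 12))
        values = rng.uniform(4, 8, 12)
        base_val = compute_iauc(trace(times, values, baseline=5.5), window=None)
        for i in range(12):
            bumped = values.copy()
            bumped[i] += 0.5
            assert (
                compute_iauc(trace(times, bumped, baseline=5.5), window=None)
                >= base_val - 1e-12
            )


class TestFastingGlucose:
    def test_first_reading_at_zero(self):
        t = trace([0, 2, 4], [5.2, 6.0, 6.5])
        assert fasting_glucose(t) == 5.2

    def test_latest_pre_ingestion_reading(self):
        t = trace([-4, -2, 0, 2], [5.0, 5.1, 5.3, 6.0])
        assert fasting_glucose(t) == 5.3

    def test_no_pre_ingestion_warns_and_uses_first(self):
        t = trace([2, 4, 6], [5.4, 6.0, 6.2])
        with pytest.warns(UserWarning):
            assert fasting_glucose(t) == 5.4

    def test_empty_trace_is_an_error(self):
        with pytest.raises(TraceError):
            trace([], [])


class TestSummarize:
    def test_flat_trace(self):
        s = summarize_trace(trace([0, 30, 60], [5.0, 5.0, 5.0]))
        assert s.iauc == 0.0
        assert s.peak == s.fasting == 5.0
        assert s.time_above_baseline == 0.0

    def test_triangle(self):
        s = summarize_trace(trace([0, 30, 60], [5.0, 7.0, 5.0], baseline=5.0))
        assert s.iauc == pytest.approx(60.0)
        assert s.peak == 7.0
        assert s.time_above_baseline == pytest.approx(60.0)

    def test_below_baseline(self):
        s = summarize_trace(trace([0, 30, 60], [4.0, 4.5, 4.0], baseline=5.0))
        assert s.iauc == 0.0
        assert s.time_above_baseline == 0.0


class TestGenerator:
    def test_flat_curve_zero_iauc(self):
        curve = GlucoseCurveParams(peak_height=0.0, noise_sd=0.0)
        tr, truth = generate_glucose_trace(curve, seed=0)
        assert truth == 0.0
        assert np.allclose(tr.values, curve.fasting)

    def test_noiseless_trace_iauc_matches_ground_truth(self):
        """Discretization error shrinks as the sampling interval shrinks."""
        errors = []
        for interval in (4.0, 1.0, 0.25):
            curve = GlucoseCurveParams(noise_sd=0.0, sampling_interval=interval)
            tr, truth = generate_glucose_trace(curve, seed=0)
            errors.append(abs(compute_iauc(tr) - truth) / truth)
        assert errors[0] > errors[2]
        assert errors[2] < 1e-3

    def test_closed_form_iauc_matches_fine_grid(self):
        curve = GlucoseCurveParams(noise_sd=0.0)
        grid = np.linspace(0, 120, 400_001)
        numeric = float(
            np.trapezoid(np.maximum(curve.noiseless(grid) - curve.fasting, 0), grid)
        )
        assert curve.true_iauc() == pytest.approx(numeric, rel=1e-8)

    def test_undershoot_reduces_late_curve_not_truth_positivity(self):
        curve = GlucoseCurveParams(noise_sd=0.0, undershoot_depth=1.0)
        tr, truth = generate_glucose_trace(curve, seed=0)
        assert truth > 0
        assert tr.values.min() < curve.fasting  # dips below baseline late
        assert compute_iauc(tr) == pytest.approx(truth, rel=2e-3)

    def test_same_seed_identical_traces(self):
        curve = GlucoseCurveParams()
        a, _ = generate_glucose_trace(curve, seed=9)
        b, _ = generate_glucose_trace(curve, seed=9)
        assert np.array_equal(a.values, b.values)

    def test_nonpositive_fasting_rejected(self):
        with pytest.raises(ValueError):
            GlucoseCurveParams(fasting=0.0)


def test_cgm_csv_roundtrip_with_units():
    csv = "participant_id,t_min,glucose\np1,0,90.08\np1,30,126.112\np2,0,99.088\np2,30,90.08\n"
    traces = read_cgm_csv(io.StringIO(csv), units="mg/dL")
    assert [t.participant_id for t in traces] == ["p1", "p2"]
    assert traces[0].values[0] == pytest.approx(5.0, rel=1e-6)
    assert traces[0].values[1] == pytest.approx(7.0, rel=1e-6)
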
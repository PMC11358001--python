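"""Trace decomposition: segmentation, relaxation fits, normalization."""

import numpy as np
import pytest

from myostiff import (
    DecompositionError,
    NormalizedSeries,
    fit_polynomial,
    fit_relaxation,
    normalize,
    segment_steps,
    simulate_trace,
)
from myostiff.decompose import StepDecomposition, StepWindow, decompose_trace
from myostiff.defaults import FIVE_STEP, SIX_STEP
from myostiff.trace import ForceTrace

from conftest import make_relaxation_trace


class TestSegmentSteps:
    def test_zero_strain_trace_has_no_windows(self):
        n = 3000
        trace = ForceTrace(np.arange(n) / 1000.0, np.zeros(n), np.zeros(n))
        assert segment_steps(trace) == []

    def test_native_protocol_windows_match_simulator_hold_bounds(self, ladder):
        exp = ladder.experiment("fiber_native_colchicine")
        trace = simulate_trace(exp.baseline_state, FIVE_STEP, exp.components, exp.couplings)
        windows = segment_steps(trace, FIVE_STEP)
        assert [w.target_strain for w in windows] == pytest.approx(
            [0.04, 0.08, 0.12, 0.16, 0.20]
        )
        # ground truth from the generator: ramp up n_up samples, hold 10 000
        offset = 0
        for (strain, hold_s), w in zip(FIVE_STEP.steps, windows):
            n_up = round(strain / FIVE_STEP.ramp_rate * FIVE_STEP.fs)
            start = offset + n_up
            assert abs(w.i_start - start) <= 1
            assert abs(w.i_end - (start + 10_000)) <= 1
            offset = start + 10_000 + n_up + round(FIVE_STEP.rest_s * FIVE_STEP.fs)

    def test_six_step_protocol_yields_six_windows_last_at_30pct(self, ladder):
        exp = ladder.experiment("fiber_perm_tevp")
        trace = simulate_trace(exp.baseline_state, SIX_STEP, exp.components, exp.couplings)
        windows = segment_steps(trace)
        assert len(windows) == 6
        assert windows[-1].target_strain == pytest.approx(0.30)

    def test_protocol_hint_mismatch_raises(self, ladder):
        exp = ladder.experiment("fiber_native_colchicine")
        trace = simulate_trace(exp.baseline_state, FIVE_STEP, exp.components, exp.couplings)
        with pytest.raises(DecompositionError, match="do not match"):
            segment_steps(trace, SIX_STEP)


class TestFitRelaxation:
    def test_constant_window_is_purely_elastic(self):
        trace = make_relaxation_trace(3.0, 0.0, 1.0)
        d = fit_relaxation(trace, StepWindow(0.2, 0, len(trace), 0))
        assert d.F_elastic == pytest.approx(3.0, abs=1e-9)
        assert d.F_viscous == pytest.approx(0.0, abs=1e-9)
        assert d.flags == ()

    def test_closed_form_window_recovered_to_1e6(self):
        """F(t) = 2 + 3 exp(-t/0.8) at 1 kHz for 10 s recovers exactly."""
        trace = make_relaxation_trace(2.0, 3.0, 0.8)
        d = fit_relaxation(trace, StepWindow(0.2, 0, len(trace), 0))
        assert d.F_elastic == pytest.approx(2.0, abs=1e-6)
        assert d.F_viscous == pytest.approx(3.0, abs=1e-6)
        assert d.tau_fit == pytest.approx(0.8, abs=1e-6)
        assert d.r2 > 0.999999

    def test_noisy_windows_estimate_is_unbiased(self):
        """200 noisy replicates: mean F_elastic within 0.005, s.d. < 0.01."""
        vals = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            trace = make_relaxation_trace(2.0, 3.0, 0.8, rng=rng, sigma=0.01)
            d = fit_relaxation(trace, StepWindow(0.2, 0, len(trace), int(np.argmax(trace.force))))
            vals.append(d.F_elastic)
        assert np.mean(vals) == pytest.approx(2.0, abs=0.005)
        assert np.std(vals) < 0.01

    def test_conservation_elastic_plus_viscous_equals_peak(self, ladder):
        exp = ladder.experiment("fiber_native_colchicine")
        trace = simulate_trace(exp.baseline_state, FIVE_STEP, exp.components, exp.couplings)
        for d in decompose_trace(trace):
            assert d.F_elastic + d.F_viscous == d.F_peak  # exact, by construction

    @pytest.mark.parametrize("tau", [0.05, 0.5, 2.0])
    def test_elastic_recovery_insensitive_to_time_constant(self, tau):
        """F_elastic error < 0.1% for tau in [0.05, 2] s with 10-s holds."""
        trace = make_relaxation_trace(2.0, 3.0, tau)
        d = fit_relaxation(trace, StepWindow(0.2, 0, len(trace), 0))
        assert abs(d.F_elastic - 2.0) / 2.0 < 1e-3

    def test_too_few_post_peak_samples_raises(self):
        trace = make_relaxation_trace(2.0, 3.0, 0.8, hold_s=10.0)
        with pytest.raises(DecompositionError, match="50 samples"):
            fit_relaxation(trace, StepWindow(0.2, 0, 40, 0))

    def test_rising_force_flagged_not_raised(self):
        trace = make_relaxation_trace(2.0, -0.5, 0.8)
        i_peak = int(np.argmax(trace.force[:1000]))
        d = fit_relaxation(trace, StepWindow(0.2, 0, len(trace), i_peak))
        assert "rising_force" in d.flags or "negative_viscous" in d.flags

    def test_simulated_elastic_recovered_at_every_step(self, ladder):
        """Round-trip: generator's configured elastic value per step, 1e-6."""
        from myostiff.simulate import _totals

        exp = ladder.experiment("fiber_perm_gln40")
        state = exp.baseline_state
        trace = simulate_trace(state, FIVE_STEP, exp.components, exp.couplings)
        for d in decompose_trace(trace, FIVE_STEP):
            expected_e, expected_v = _totals(
                state, d.target_strain, exp.components, exp.couplings
            )
            assert d.F_elastic == pytest.approx(float(expected_e), rel=1e-6)
            assert d.F_viscous == pytest.approx(float(expected_v), rel=1e-6)


def decomp(strain, elastic, viscous=0.0):
    return StepDecomposition(strain, elastic + viscous, elastic, viscous, 1.0, 1.0)


class TestNormalize:
    def test_max_at_20_uses_highest_pre_treatment_replicate(self):
        pre = {0: [decomp(0.20, 0.9)], 1: [decomp(0.20, 1.1)]}
        post = {0: [decomp(0.20, 0.55)], 1: [decomp(0.20, 0.55)]}
        pre_n, post_n = normalize(pre, post, "max_at_20", "elastic")
        assert pre_n.reference_value == pytest.approx(1.1)
        assert post_n.at(0.20, 0) == [pytest.approx(0.5)]

    def test_mean_at_25_maps_pre_values_to_one(self):
        pre = {0: [decomp(0.25, 2.0)], 1: [decomp(0.25, 2.0)]}
        pre_n, _ = normalize(pre, {}, "mean_at_25", "elastic")
        assert pre_n.reference_value == pytest.approx(2.0)
        assert all(v == pytest.approx(1.0) for v in pre_n.at(0.25))

    def test_all_zero_forces_is_an_error(self):
        pre = {0: [decomp(0.20, 0.0)]}
        with pytest.raises(DecompositionError, match="reference"):
            normalize(pre, {}, "max_at_20", "elastic")

    def test_normalization_is_idempotent(self):
        pre = {0: [decomp(0.12, 0.4), decomp(0.20, 0.8)], 1: [decomp(0.20, 1.0)]}
        once, _ = normalize(pre, {}, "max_at_20", "elastic")
        redecomp = {
            r: [decomp(s, v) for s, v, rr in once.points if rr == r] for r in (0, 1)
        }
        twice, _ = normalize(redecomp, {}, "max_at_20", "elastic")
        assert twice.reference_value == pytest.approx(1.0)
        assert sorted(v for _, v, _ in twice.points) == pytest.approx(
            sorted(v for _, v, _ in once.points)
        )


class TestFitPolynomial:
    def test_exact_quadratic_interpolation(self):
        pts = [(e, 1 + 2 * e + 3 * e**2, 0) for e in (0.05, 0.1, 0.15, 0.2)]
        series = NormalizedSeries("elastic", "max_at_20", 1.0, pts)
        coef, rss = fit_polynomial(series)
        assert coef == pytest.approx((1.0, 2.0, 3.0), abs=1e-10)
        assert rss < 1e-20

    def test_matches_normal_equations_oracle_on_noisy_points(self):
        rng = np.random.default_rng(7)
        strains = np.tile([0.04, 0.08, 0.12, 0.16, 0.20], 4)
        values = 0.5 + 1.5 * strains + 8 * strains**2 + 0.05 * rng.standard_normal(20)
        series = NormalizedSeries(
            "elastic", "max_at_20", 1.0, [(s, v, 0) for s, v in zip(strains, values)]
        )
        coef, _ = fit_polynomial(series)
        # independent closed-form least squares via the normal equations
        X = np.column_stack([np.ones_like(strains), strains, strains**2])
        oracle = np.linalg.solve(X.T @ X, X.T @ values)
        assert coef == pytest.approx(tuple(oracle), abs=1e-8)

    def test_two_distinct_strains_rejected(self):
        series = NormalizedSeries(
            "elastic", "max_at_20", 1.0, [(0.1, 1.0, 0), (0.2, 2.0, 0), (0.2, 2.1, 1)]
        )
        with pytest.raises(DecompositionError, match="3 distinct"):
            fit_polynomial(series)
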
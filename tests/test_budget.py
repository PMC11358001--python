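"""Contribution estimation, budget composition, paired statistics."""

import numpy as np
import pytest
from scipy import stats

from myostiff import (
    BudgetError,
    ContributionEstimate,
    NormalizedSeries,
    adjust_p_values,
    compose_budget,
    contribution_from_pair,
)


def series(values_by_rep, strain=0.20, force_type="elastic"):
    pts = [(strain, v, r) for r, v in values_by_rep.items()]
    return NormalizedSeries(force_type, "pre_value_cell", 1.0, pts)


class TestContributionFromPair:
    def test_identical_pre_post_gives_zero_share_and_p_one(self):
        pre = series({0: 1.0, 1: 0.9, 2: 1.1})
        post = series({0: 1.0, 1: 0.9, 2: 1.1})
        est = contribution_from_pair(pre, post, 0.20)
        assert est.share == pytest.approx(0.0)
        assert est.p_value == 1.0

    def test_uniform_fourteen_percent_drop(self):
        pre = series({r: 1.0 for r in range(4)})
        post = series({r: 0.86 for r in range(4)})
        est = contribution_from_pair(pre, post, 0.20)
        assert est.share == pytest.approx(0.14)

    def test_paired_t_statistic_matches_t_distribution_oracle(self):
        """Differences {1,2,3,4}: t = 3.873, two-sided p ~ 0.0305 (df=3)."""
        pre = series({0: 11.0, 1: 12.0, 2: 13.0, 3: 14.0})
        post = series({0: 10.0, 1: 10.0, 2: 10.0, 3: 10.0})
        est = contribution_from_pair(pre, post, 0.20)
        diffs = np.array([1.0, 2.0, 3.0, 4.0])
        t_oracle = diffs.mean() / (diffs.std(ddof=1) / 2.0)
        assert t_oracle == pytest.approx(3.873, abs=1e-3)
        assert est.p_value == pytest.approx(2 * stats.t.sf(t_oracle, df=3), abs=1e-12)
        assert est.p_value == pytest.approx(0.0305, abs=2e-4)

    def test_single_pair_returns_estimate_with_undefined_p(self):
        est = contribution_from_pair(series({0: 1.0}), series({0: 0.8}), 0.20)
        assert est.share == pytest.approx(0.2)
        assert np.isnan(est.p_value)
        assert "p_undefined" in est.flags

    def test_unpaired_replicates_rejected(self):
        with pytest.raises(BudgetError, match="unpaired"):
            contribution_from_pair(series({0: 1.0, 1: 1.0}), series({0: 0.8}), 0.20)

    def test_type_I_error_calibrated_under_null(self):
        """No true effect, sigma 1%, n = 7 pairs: ~5% rejections (2000 sims)."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            base = 1.0 + 0.1 * rng.standard_normal(7)
            pre = series({r: base[r] * (1 + 0.01 * rng.standard_normal()) for r in range(7)})
            post = series({r: base[r] * (1 + 0.01 * rng.standard_normal()) for r in range(7)})
            if contribution_from_pair(pre, post, 0.20).p_value < 0.05:
                rejections += 1
        assert rejections / n_sim == pytest.approx(0.05, abs=0.02)


def estimate(component, baseline, share, strain=0.20, force_type="elastic"):
    return ContributionEstimate(
        component=component, preparation="", baseline=baseline, force_type=force_type,
        strain=strain, share=share, n=5, sem=0.0, p_value=0.01,
    )


def brute_force_budget(c_mt, c_sarc_post, titin_fiber, titin_cell, actin_cell):
    """Independent arithmetic oracle for the composition chain."""
    c_sarc = c_sarc_post * (1 - c_mt)
    pool = 1 - c_mt - c_sarc
    x = min(max(1 - titin_fiber / titin_cell, 0.0), 1.0)
    shares = {
        "microtubules": c_mt,
        "sarcolemma": c_sarc,
        "ecm": pool * x,
        "titin": pool * (1 - x) * titin_cell,
        "actin": pool * (1 - x) * actin_cell,
    }
    shares["desmin"] = max(0.0, 1 - sum(shares.values()))
    shares = {k: max(0.0, v) for k, v in shares.items()}
    total = sum(shares.values())
    return {k: v / total for k, v in shares.items()}


def full_estimate_set(c_mt, c_sarc_post, titin_fiber, titin_cell, actin_cell):
    return [
        estimate("microtubules", "native_total", c_mt),
        estimate("sarcolemma", "post_colchicine_total", c_sarc_post),
        estimate("titin", "permeabilized_total", titin_fiber),
        estimate("titin", "cell_total", titin_cell),
        estimate("actin", "cell_total", actin_cell),
    ]


class TestComposeBudget:
    def test_single_full_share_native_estimate(self):
        budget = compose_budget([estimate("titin", "native_total", 1.0)], "high", "elastic")
        assert budget.shares["titin"] == pytest.approx(1.0)
        assert budget.shares.get("desmin", 0.0) == pytest.approx(0.0)

    def test_worked_chain_example(self):
        """c_MT=0.14, sarc 0.16, titin 0.54/0.78, actin 0.30: the chain gives
        sarc_native 0.1376, pool 0.7224, x ~ 0.3077, ECM ~ 0.2223,
        titin ~ 0.3901, actin ~ 0.1500 before renormalization."""
        budget = compose_budget(
            full_estimate_set(0.14, 0.16, 0.54, 0.78, 0.30), "high", "elastic"
        )
        oracle = brute_force_budget(0.14, 0.16, 0.54, 0.78, 0.30)
        total_raw = 0.14 + 0.1376 + 0.22228 + 0.39014 + 0.15005  # ~1.04, residual clipped
        assert budget.shares["microtubules"] == pytest.approx(0.14 / total_raw, abs=1e-4)
        assert budget.shares["sarcolemma"] == pytest.approx(0.1376 / total_raw, abs=1e-4)
        assert budget.shares["ecm"] == pytest.approx(0.22228 / total_raw, abs=1e-4)
        for comp, share in oracle.items():
            assert budget.shares[comp] == pytest.approx(share, abs=1e-12)

    def test_matches_brute_force_oracle_on_100_random_inputs(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            c_mt = rng.uniform(0.0, 0.4)
            c_sarc = rng.uniform(0.0, 0.3)
            titin_cell = rng.uniform(0.3, 0.9)
            titin_fiber = rng.uniform(0.1, titin_cell)
            actin_cell = rng.uniform(0.0, 1.0 - titin_cell)
            budget = compose_budget(
                full_estimate_set(c_mt, c_sarc, titin_fiber, titin_cell, actin_cell),
                "high",
                "elastic",
            )
            oracle = brute_force_budget(c_mt, c_sarc, titin_fiber, titin_cell, actin_cell)
            assert sum(budget.shares.values()) == pytest.approx(1.0, abs=1e-9)
            for comp, share in oracle.items():
                assert budget.shares[comp] == pytest.approx(share, abs=1e-12)

    def test_budget_shares_sum_to_one_for_ladder(self, ladder):
        from myostiff.budget import ladder_estimates

        estimates = ladder_estimates(ladder)
        for regime in ("low", "high"):
            for ft in ("elastic", "viscous"):
                budget = compose_budget(estimates, regime, ft)
                assert sum(budget.shares.values()) == pytest.approx(1.0, abs=1e-9)
                assert all(v >= 0 for v in budget.shares.values())

    def test_zero_titin_cell_share_is_an_error(self):
        with pytest.raises(BudgetError, match="titin cell"):
            compose_budget(full_estimate_set(0.1, 0.1, 0.0, 0.0, 0.3), "high", "elastic")

    def test_empty_estimates_rejected(self):
        with pytest.raises(BudgetError):
            compose_budget([], "high", "elastic")


class TestAdjustPValues:
    def test_single_p_unchanged(self):
        assert adjust_p_values([0.03]) == [pytest.approx(0.03)]

    def test_two_value_sidak_example(self):
        adj = adjust_p_values([0.01, 0.04])
        assert adj[0] == pytest.approx(1 - (1 - 0.01) ** 2)
        assert adj[1] == pytest.approx(0.04)

    def test_ties_stay_equal_and_not_below_raw(self):
        adj = adjust_p_values([0.2, 0.2, 0.2])
        assert adj[0] == adj[1] == adj[2]
        assert all(a >= 0.2 for a in adj)

    def test_matches_statsmodels_holm_sidak(self):
        statsmodels = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(3)
        p = rng.uniform(0, 1, 12)
        ours = adjust_p_values(list(p))
        theirs = statsmodels.multipletests(p, method="holm-sidak")[1]
        assert ours == pytest.approx(list(theirs), abs=1e-12)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(BudgetError):
            adjust_p_values([0.5, 1.2])


class TestOrderRobustness:
    def test_residual_share_identical_for_either_disruption_order(self, ladder):
        """End-state determinism propagated through the full pipeline, and the
        per-step titin drop differing by exactly the configured tensegrity
        loss fraction."""
        import dataclasses

        from myostiff.budget import measure_readout, run_experiment
        from myostiff.defaults import ACTIN_TITIN_LOSS

        exp = ladder.experiment("cell_gln40_tevp")
        swapped = dataclasses.replace(exp, treatments=("tevp", "gln40"))
        ro_rem = {"label": "", "stage": 2, "mode": "remaining", "force_type": "elastic",
                  "strain": 0.20, "relative_to": "baseline"}
        s1 = run_experiment(exp)
        s2 = run_experiment(swapped)
        rem1 = measure_readout(s1, ro_rem)
        rem2 = measure_readout(s2, ro_rem)
        assert rem1 == pytest.approx(rem2, abs=1e-9)

        # titin's measured per-step contribution is history dependent:
        # cleaved first it takes its full share T of the baseline total;
        # cleaved after actin severing it contributes only (1 - loss) * T
        ro_drop1 = dict(ro_rem, stage=1, mode="drop")
        ro_drop2 = dict(ro_rem, stage=2, mode="drop")
        titin_first = measure_readout(s2, ro_drop1)
        titin_second = measure_readout(s1, ro_drop2) - measure_readout(s1, ro_drop1)
        assert titin_first - titin_second == pytest.approx(
            ACTIN_TITIN_LOSS * titin_first, abs=1e-9
        )
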
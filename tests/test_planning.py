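"""Prospective planning, retrospective evaluation, sensitivity grids."""

import numpy as np
import pytest

from designanalysis import (
    DesignConfig,
    analytic_power,
    make_interval_effect,
    make_point_effect,
    power_curve,
    prospective_design,
    retrospective_design,
    sensitivity_grid,
)


class TestProspective:
    def test_plan_small_effect_80_power(self, fast_config):
        """d = 0.25 at 80% power needs ~252 per group, with residual
        exaggeration ~1.13."""
        plan = prospective_design(make_point_effect(0.25), 0.80, fast_config)
        assert abs(plan.n_per_group - 252) <= 2
        assert plan.type_m == pytest.approx(1.13, abs=max(0.01, 4 * plan.result.mc_se_type_m))
        assert plan.type_s == pytest.approx(0.00, abs=0.01)

    def test_plan_small_effect_60_power(self, fast_config):
        plan = prospective_design(make_point_effect(0.25), 0.60, fast_config)
        assert abs(plan.n_per_group - 158) <= 2
        assert plan.type_m == pytest.approx(1.30, abs=max(0.01, 4 * plan.result.mc_se_type_m))

    def test_search_brackets_target(self, fast_config):
        """The returned n is minimal: analytic power crosses the (slackened)
        target exactly between n-1 and n."""
        for d, target in [(0.25, 0.80), (0.35, 0.60), (0.5, 0.9)]:
            plan = prospective_design(make_point_effect(d), target, fast_config)
            n = plan.n_per_group
            assert analytic_power(d, n, n, 0.05) >= target - 0.002
            if n > 2:
                assert analytic_power(d, n - 1, n - 1, 0.05) < target - 0.002

    def test_huge_effect_boundary(self, fast_config):
        plan = prospective_design(make_point_effect(5.0), 0.06, fast_config)
        assert plan.n_per_group == 2

    def test_negative_effect_plans_like_positive(self, fast_config):
        pos = prospective_design(make_point_effect(0.4), 0.8, fast_config)
        neg = prospective_design(make_point_effect(-0.4), 0.8, fast_config)
        assert pos.n_per_group == neg.n_per_group

    def test_interval_spec_plans_at_center(self, fast_config):
        spec = make_interval_effect(0.2, 0.6, "truncated_normal", 1 / 6)
        plan = prospective_design(spec, 0.8, fast_config)
        point = prospective_design(make_point_effect(0.4), 0.8, fast_config)
        assert plan.n_per_group == point.n_per_group

    def test_errors(self, fast_config):
        with pytest.raises(ValueError, match="target_power"):
            prospective_design(make_point_effect(0.3), 0.05, fast_config)
        with pytest.raises(ValueError, match="zero plausible"):
            prospective_design(make_point_effect(0.0), 0.8, fast_config)
        with pytest.raises(ValueError, match="too small to plan"):
            prospective_design(make_point_effect(1e-4), 0.8, fast_config, n_cap=10_000)
        with pytest.raises(ValueError, match="balanced"):
            prospective_design(make_point_effect(0.3), 0.8, fast_config, balanced=False)


class TestRetrospective:
    def test_completed_trial_metrics(self, fast_config):
        """31 per group under plausible d = 0.25: power 0.16, Type S 0.01,
        Type M 2.59."""
        res = retrospective_design(31, 31, make_point_effect(0.25), fast_config)
        assert res.power == pytest.approx(0.16, abs=max(0.01, 4 * res.mc_se_power))
        assert res.type_s == pytest.approx(0.01, abs=0.01)
        assert res.type_m == pytest.approx(2.59, abs=max(0.01, 4 * res.mc_se_type_m))

    def test_unbalanced_groups_accepted(self, fast_config):
        res = retrospective_design(33, 34, make_point_effect(0.20), fast_config)
        assert res.n1 == 33 and res.n2 == 34
        assert res.power == pytest.approx(0.127, abs=max(0.01, 4 * res.mc_se_power))

    def test_round_trip_with_plan(self, fast_config):
        """Retrospective analysis at a plan's n reproduces its power."""
        plan = prospective_design(make_point_effect(0.35), 0.8, fast_config)
        other = DesignConfig(n_sims=fast_config.n_sims, seed=fast_config.seed + 1)
        res = retrospective_design(plan.n_per_group, plan.n_per_group, plan.spec, other)
        se = np.sqrt(2) * max(res.mc_se_power, plan.result.mc_se_power)
        assert abs(res.power - plan.achieved_power) < 3 * se


class TestGrids:
    def test_sensitivity_grid_shape_and_monotonicity(self, fast_config):
        table = sensitivity_grid([0.20, 0.35, 0.50], [0.80, 0.60], fast_config).table
        assert len(table) == 6
        for power, sub in table.groupby("power"):
            ns = sub.sort_values("d").n_per_group.values
            assert all(a > b for a, b in zip(ns, ns[1:]))
        row = table[(table.d == 0.35) & (table.power == 0.80)].iloc[0]
        assert abs(row.n_per_group - 130) <= 2
        assert row.total_n == 2 * row.n_per_group

    def test_grid_matches_individual_calls(self, fast_config):
        table = sensitivity_grid([0.35], [0.80], fast_config).table
        plan = prospective_design(make_point_effect(0.35), 0.80, fast_config)
        assert table.iloc[0].n_per_group == plan.n_per_group
        assert table.iloc[0].typeM == pytest.approx(plan.type_m)

    def test_power_curve_relationships(self, fast_config):
        """Across n: power rises, Type M and Type S fall (d = 0.35)."""
        table = power_curve(make_point_effect(0.35), [10, 48, 130], fast_config).table
        assert table.power.is_monotonic_increasing
        assert table.typeM.is_monotonic_decreasing
        assert table.typeS.is_monotonic_decreasing
        row48 = table[table.n_per_group == 48].iloc[0]
        assert row48.typeM == pytest.approx(1.58, abs=0.05)
        row10 = table[table.n_per_group == 10].iloc[0]
        assert row10.typeS == pytest.approx(0.03, abs=0.02)

    def test_empty_grids_rejected(self, fast_config):
        with pytest.raises(ValueError):
            sensitivity_grid([], [0.8], fast_config)
        with pytest.raises(ValueError):
            power_curve(make_point_effect(0.3), [], fast_config)
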
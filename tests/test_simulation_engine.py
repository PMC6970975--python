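"""Monte-Carlo engine: calibration, determinism, strategy equivalence."""

import numpy as np
import pytest

from designanalysis import (
    DesignConfig,
    analytic_power,
    critical_d,
    make_interval_effect,
    make_point_effect,
    run_simulation,
    simulate_replicate,
)
from designanalysis.simulation_engine import BLOCK_SIZE


class TestSimulateReplicate:
    def test_significance_flag_matches_p(self, rng):
        out = simulate_replicate(0.3, 20, 20, 0.05, rng)
        assert out.significant == (out.p_value < 0.05)
        assert out.sign_positive == (out.d_obs > 0)

    def test_reproducible(self):
        a = simulate_replicate(0.3, 20, 20, 0.05, np.random.default_rng(5))
        b = simulate_replicate(0.3, 20, 20, 0.05, np.random.default_rng(5))
        assert a == b

    def test_rejects_tiny_groups(self, rng):
        with pytest.raises(ValueError):
            simulate_replicate(0.3, 1, 20, 0.05, rng)


class TestRunSimulation:
    def test_null_calibration(self, fast_config):
        """At d = 0 the significant fraction recovers alpha."""
        reps = run_simulation(make_point_effect(0.0), 25, 25, fast_config)
        frac = reps.significant.mean()
        bound = 4 * np.sqrt(0.05 * 0.95 / fast_config.n_sims)
        assert abs(frac - 0.05) < bound

    def test_winners_curse_threshold(self, fast_config):
        """Every significant estimate clears the critical d (0.49 at 33/33):
        in this underpowered design significance forces inflation."""
        reps = run_simulation(make_point_effect(0.20), 33, 33, fast_config)
        thresh = critical_d(33, 33, fast_config.alpha)
        assert np.all(np.abs(reps.d_obs[reps.significant]) >= thresh - 1e-9)
        assert thresh == pytest.approx(0.49, abs=0.005)

    def test_separation_limit(self):
        cfg = DesignConfig(n_sims=2000, seed=1)
        reps = run_simulation(make_point_effect(5.0), 50, 50, cfg)
        assert reps.significant.mean() == pytest.approx(1.0)

    def test_seed_determinism_bit_identical(self, fast_config):
        spec = make_interval_effect(0.2, 0.6, "truncated_normal", 1 / 6)
        a = run_simulation(spec, 31, 31, fast_config)
        b = run_simulation(spec, 31, 31, fast_config)
        for field in ("d_true", "d_obs", "p_value", "significant"):
            assert np.array_equal(getattr(a, field), getattr(b, field))

    def test_short_run_is_prefix_of_long_run(self):
        """Fixed substream blocks: n_sims only extends the ensemble."""
        spec = make_point_effect(0.3)
        short = run_simulation(spec, 10, 10, DesignConfig(n_sims=BLOCK_SIZE + 100, seed=3))
        long = run_simulation(spec, 10, 10, DesignConfig(n_sims=2 * BLOCK_SIZE, seed=3))
        assert np.array_equal(short.d_obs, long.d_obs[: len(short)])

    def test_single_replicate(self):
        reps = run_simulation(make_point_effect(0.3), 10, 10, DesignConfig(n_sims=1, seed=2))
        assert len(reps) == 1
        out = list(reps.outcomes)[0]
        assert out.significant == (out.p_value < 0.05)

    def test_strategy_equivalence(self):
        """Explicit data simulation and the noncentral-t shortcut agree."""
        spec = make_point_effect(0.35)
        n_sims = 20_000
        p_data = run_simulation(
            spec, 50, 50, DesignConfig(n_sims=n_sims, seed=11, strategy="data_sim")
        ).significant.mean()
        p_ncp = run_simulation(
            spec, 50, 50, DesignConfig(n_sims=n_sims, seed=12, strategy="ncp_sim")
        ).significant.mean()
        se = np.sqrt(2 * p_data * (1 - p_data) / n_sims)
        assert abs(p_data - p_ncp) < 3 * se

    @pytest.mark.parametrize("d,n", [(0.2, 33), (0.35, 130), (0.5, 20)])
    def test_power_matches_analytic_oracle(self, d, n, fast_config):
        reps = run_simulation(make_point_effect(d), n, n, fast_config)
        p_hat = reps.significant.mean()
        p_true = analytic_power(d, n, n, fast_config.alpha)
        se = np.sqrt(p_true * (1 - p_true) / fast_config.n_sims)
        assert abs(p_hat - p_true) < 3 * se

    def test_interval_mode_draws_within_bounds(self, fast_config):
        spec = make_interval_effect(0.2, 0.6, "truncated_normal", 1 / 6)
        reps = run_simulation(spec, 31, 31, fast_config)
        assert reps.d_true.min() >= 0.2 and reps.d_true.max() <= 0.6
        assert len(np.unique(reps.d_true)) > 1000  # hierarchical, not fixed

    def test_fixed_center_collapses_interval(self, fast_config):
        spec = make_interval_effect(0.2, 0.6, "truncated_normal", 1 / 6)
        cfg = DesignConfig(
            n_sims=fast_config.n_sims, seed=fast_config.seed, fixed_center=True
        )
        reps = run_simulation(spec, 31, 31, cfg)
        assert np.all(reps.d_true == 0.4)

    def test_memory_guard(self):
        cfg = DesignConfig(n_sims=100_000, seed=0, max_total_draws=1e6)
        with pytest.raises(ValueError, match="max_total_draws"):
            run_simulation(make_point_effect(0.2), 100, 100, cfg)

    def test_export_roundtrip(self, tmp_path):
        import pandas as pd

        reps = run_simulation(make_point_effect(0.3), 10, 10, DesignConfig(n_sims=50, seed=2))
        path = tmp_path / "reps.csv"
        reps.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["d_true", "d_obs", "p_value", "significant"]
        assert np.allclose(df.d_obs.values, reps.d_obs)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(alpha=0.0),
            dict(alpha=1.0),
            dict(n_sims=0),
            dict(strategy="bootstrap"),
            dict(tails="one"),
        ],
    )
    def test_invalid_config(self, kwargs):
        with pytest.raises(ValueError):
            DesignConfig(**kwargs)
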
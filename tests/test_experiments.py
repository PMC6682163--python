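"""Session driver, windowed averaging, sweeps, presets and serialization."""

import dataclasses
import math

import numpy as np
import pytest

from fddm.core import SDEConfig, UtilityConfig
from fddm.experiments import (
    PRESET_GRID,
    PatchVisit,
    config_hash,
    environment_presets,
    preset_environment,
    prt_regression,
    read_summary,
    read_visits,
    simulate_session,
    summarize,
    sweep,
    sweep_seed,
    validate_summary,
    write_summary,
    write_visits,
)
from fddm.mvt import StrategyConfig, solve_environment

from conftest import A_MED, ESTAR_MED, S_MED, TTR_MED


def run_session(env, kind="density_adaptive", seed=0, total_time=1000.0, burn_in=100.0,
                sigma=0.0, fix_energy=None, utility=None, **kw):
    cfg = SDEConfig(sigma=sigma, seed=seed, fix_energy=fix_energy)
    return simulate_session(
        env, StrategyConfig(kind), utility, cfg,
        total_time=total_time, burn_in=burn_in, **kw,
    )


class TestSimulateSession:
    def test_noiseless_session_reaches_mvt_residence(self, medium_env, medium_sol):
        """Continuous reward, sigma = 0, E clamped at E*: every windowed PRT
        equals T* up to the step size."""
        visits, summary = run_session(medium_env, fix_energy=ESTAR_MED)
        assert summary.n_patches > 50
        assert summary.mean_prt == pytest.approx(medium_sol.T_star, abs=0.02)
        assert summary.sd_prt < 1e-9

    def test_noiseless_energy_rate_approximates_optimum(self, medium_env):
        """With dynamic E the realized long-run net rate settles near E*
        (slightly below, since the forager's estimate lags the optimum)."""
        _, summary = run_session(medium_env, total_time=3000.0, burn_in=500.0)
        assert summary.mean_energy_rate == pytest.approx(ESTAR_MED, abs=0.15)

    def test_cycle_accounting_is_exact(self, medium_env):
        """The window length is exactly the sum of PRTs and travel times,
        and window bounds match (no drift from fractional travel steps)."""
        visits, summary = run_session(medium_env, total_time=600.0, burn_in=100.0)
        inside = [
            v for v in visits if v.t_enter >= 100.0 and v.t_leave + v.travel_after <= 600.0
        ]
        assert summary.n_patches == len(inside)
        length = summary.window[1] - summary.window[0]
        assert length == pytest.approx(sum(v.prt + v.travel_after for v in inside), abs=1e-8)

    def test_same_seed_reproduces_identical_session(self, medium_env_chunks):
        v1, s1 = run_session(medium_env_chunks, sigma=0.5, seed=42)
        v2, s2 = run_session(medium_env_chunks, sigma=0.5, seed=42)
        assert v1 == v2 and s1 == s2

    def test_different_seeds_differ(self, medium_env_chunks):
        _, s1 = run_session(medium_env_chunks, sigma=0.5, seed=1)
        _, s2 = run_session(medium_env_chunks, sigma=0.5, seed=2)
        assert s1.mean_prt != s2.mean_prt

    def test_max_prt_caps_runaway_visits(self, medium_env):
        """Visits that outlast max_prt are truncated and flagged degenerate
        rather than hanging the session."""
        visits, summary = run_session(
            medium_env, total_time=300.0, burn_in=0.0, max_prt=2.0,
            fix_energy=ESTAR_MED,
        )
        # T* = 5.73 > 2, so every visit hits the cap
        assert summary.degenerate_exits == summary.n_patches > 0
        assert all(v.prt == pytest.approx(2.0, abs=0.02) for v in visits[:-1])

    def test_undefined_threshold_produces_immediate_degenerate_exit(self, medium_env):
        """An energy estimate above rho0_bar - s makes every patch look
        worse than the environment; the forager exits at entry."""
        visits, summary = run_session(
            medium_env, total_time=300.0, burn_in=0.0, fix_energy=9.0
        )
        assert summary.degenerate_exits == summary.n_patches > 0
        assert all(v.prt == 0.0 for v in visits)

    def test_invalid_window_rejected(self, medium_env):
        with pytest.raises(ValueError):
            run_session(medium_env, total_time=100.0, burn_in=100.0)

    def test_noisy_prt_variance_grows_with_sigma(self, medium_env):
        sds = []
        for sigma in (0.25, 1.5):
            _, summary = run_session(
                medium_env, sigma=sigma, seed=7, total_time=2000.0, burn_in=200.0
            )
            sds.append(summary.sd_prt)
        assert 0 < sds[0] < sds[1]

    def test_heterogeneous_patches_report_actual_draws(self, uncertain_density_env):
        visits, _ = run_session(uncertain_density_env, total_time=500.0, burn_in=0.0)
        rho0s = {v.rho0_actual for v in visits}
        assert len(rho0s) == len(visits)  # every draw distinct
        assert all(r > 0 for r in rho0s)


class TestSummarize:
    def make_visit(self, t0, prt, food, travel, chunks=0, degenerate=False):
        return PatchVisit(
            t_enter=t0, t_leave=t0 + prt, prt=prt, chunks=chunks, food=food,
            E_exit=0.0, travel_after=travel, rho0_actual=9.439, A_actual=5.0,
            degenerate=degenerate,
        )

    def test_windowed_rate_matches_hand_computation(self):
        visits = [
            self.make_visit(0.0, 5.0, 40.0, 5.0),     # before burn-in: excluded
            self.make_visit(10.0, 6.0, 30.0, 4.0),
            self.make_visit(20.0, 4.0, 26.0, 6.0),
            self.make_visit(30.0, 5.0, 40.0, 100.0),  # incomplete cycle: excluded
        ]
        s = summarize(visits, burn_in=10.0, total_time=40.0, s=1.0)
        assert s.n_patches == 2
        assert s.total_food == 56.0
        assert s.mean_energy_rate == pytest.approx((56.0 - 20.0) / 20.0)
        assert s.mean_prt == 5.0
        assert s.window == (10.0, 30.0)

    def test_chunk_histogram_counts_visits(self):
        visits = [self.make_visit(10.0 * i, 5.0, 24.0, 5.0, chunks=c)
                  for i, c in enumerate([3, 3, 4], start=1)]
        s = summarize(visits, burn_in=0.0, total_time=100.0, s=1.0)
        assert s.chunk_histogram == {3: 2, 4: 1}

    def test_empty_window_raises(self):
        visits = [self.make_visit(0.0, 5.0, 40.0, 5.0)]
        with pytest.raises(ValueError):
            summarize(visits, burn_in=50.0, total_time=60.0, s=1.0)


class TestSweep:
    def test_grid_rows_and_determinism(self, medium_env):
        grid = [
            (medium_env, StrategyConfig("density_adaptive"), None, SDEConfig(sigma=0.5)),
            (medium_env, StrategyConfig("counting"), None, SDEConfig(sigma=0.5)),
        ]
        df1 = sweep(grid, replicates=2, base_seed=3, total_time=300.0, burn_in=50.0)
        df2 = sweep(grid, replicates=2, base_seed=3, total_time=300.0, burn_in=50.0)
        assert len(df1) == 4
        assert (df1["error"] == "").all()
        assert df1.equals(df2)
        assert df1["seed"].nunique() == 4

    def test_cell_failure_is_recorded_not_raised(self, medium_env):
        bad_env = dataclasses.replace(medium_env, Ttr_dist=type(medium_env.Ttr_dist)(1000.0))
        grid = [
            (bad_env, StrategyConfig("density_adaptive"), None, SDEConfig()),
            (medium_env, StrategyConfig("density_adaptive"), None, SDEConfig()),
        ]
        df = sweep(grid, replicates=1, total_time=300.0, burn_in=50.0)
        assert df.loc[0, "error"] != ""
        assert df.loc[1, "error"] == ""

    def test_labels_join_cells(self, medium_env):
        grid = [(medium_env, StrategyConfig("density_adaptive"), None, SDEConfig())]
        df = sweep(grid, replicates=1, labels=[{"preset": "medium-default"}],
                   total_time=300.0, burn_in=50.0)
        assert (df["preset"] == "medium-default").all()


class TestSweepSeed:
    def test_deterministic_and_distinct(self):
        seeds = {sweep_seed(0, i, j) for i in range(10) for j in range(10)}
        assert len(seeds) == 100
        assert sweep_seed(0, 3, 1) == sweep_seed(0, 3, 1)
        assert all(0 <= s < 2**31 for s in seeds)

    def test_base_seed_changes_everything(self):
        a = [sweep_seed(0, i, 0) for i in range(5)]
        b = [sweep_seed(1, i, 0) for i in range(5)]
        assert set(a).isdisjoint(b)


class TestPresets:
    def test_grid_size_and_alias(self):
        presets = environment_presets()
        assert len(presets) == 3 * 3 * 2 + 1
        assert presets["medium-default"] is presets["medium-medium-large"]

    def test_each_preset_is_self_consistent(self):
        """Every preset's rho0 solves the MVT self-consistency for its
        nominal E*."""
        presets = environment_presets()
        for e_label, e in PRESET_GRID["E_star"].items():
            for t_label, ttr in PRESET_GRID["T_tr"].items():
                for a_label, a in PRESET_GRID["A"].items():
                    env = presets[f"{e_label}-{t_label}-{a_label}"]
                    sol = solve_environment(a, ttr, 1.0, rho0=env.rho0_mean)
                    assert sol.E_star == pytest.approx(e, abs=1e-8)

    def test_low_preset_density(self):
        env = preset_environment(0.5, 1.0, 1.5)
        assert env.rho0_mean == pytest.approx(3.954, abs=5e-4)

    def test_richer_environments_need_richer_patches(self):
        r_low = preset_environment(0.5, TTR_MED, A_MED).rho0_mean
        r_med = preset_environment(2.0, TTR_MED, A_MED).rho0_mean
        r_high = preset_environment(5.0, TTR_MED, A_MED).rho0_mean
        assert r_low < r_med < r_high


class TestPrtRegression:
    def test_recovers_planted_slope(self, rng):
        rho0s = 9.439 + rng.normal(0.0, 1.0, size=200)
        visits = [
            PatchVisit(
                t_enter=10.0 * i, t_leave=10.0 * i + 5, prt=5.0 + 0.53 * (r - 9.439),
                chunks=0, food=30.0, E_exit=2.0, travel_after=5.0,
                rho0_actual=float(r), A_actual=5.0,
            )
            for i, r in enumerate(rho0s)
        ]
        assert prt_regression(visits) == pytest.approx(0.53, abs=1e-9)

    def test_requires_enough_visits_and_variation(self):
        v = PatchVisit(0.0, 5.0, 5.0, 0, 30.0, 2.0, 5.0, 9.439, 5.0)
        with pytest.raises(ValueError):
            prt_regression([v] * 10)
        with pytest.raises(ValueError):
            prt_regression([v] * 50)  # constant rho0


class TestSerialization:
    def test_visits_round_trip(self, medium_env_chunks, tmp_path):
        visits, _ = run_session(medium_env_chunks, sigma=0.5, seed=5,
                                total_time=300.0, burn_in=50.0)
        path = tmp_path / "visits.csv"
        write_visits(visits, path, config={"seed": 5}, seed=5)
        df = read_visits(path)
        assert len(df) == len(visits)
        assert list(df.columns) == [
            "t_enter", "t_leave", "prt", "chunks", "food", "E_exit",
            "travel_after", "rho0_actual", "A_actual", "degenerate",
        ]
        np.testing.assert_allclose(df["prt"], [v.prt for v in visits])
        first = path.read_text().splitlines()[0]
        assert first.startswith("# fddm-visits config_hash=") and "seed=5" in first

    def test_summary_round_trip_and_schema(self, medium_env, tmp_path):
        _, summary = run_session(medium_env, total_time=300.0, burn_in=50.0)
        path = tmp_path / "summary.json"
        write_summary(summary, path, config={"x": 1}, seed=3)
        d = read_summary(path)
        assert d["mean_prt"] == pytest.approx(summary.mean_prt)
        assert d["seed"] == 3
        validate_summary(d)

    def test_schema_rejects_missing_and_mistyped(self):
        with pytest.raises(ValueError, match="missing"):
            validate_summary({"mean_energy_rate": 1.0})
        good = {
            "mean_energy_rate": 1.0, "sd_energy_rate": 0.1, "mean_prt": 5.0,
            "sd_prt": 0.2, "chunk_histogram": {}, "n_patches": 10,
            "window": [0.0, 1.0], "total_food": 3.0, "degenerate_exits": 0,
        }
        validate_summary(good)
        bad = dict(good, n_patches="ten")
        with pytest.raises(ValueError, match="type"):
            validate_summary(bad)

    def test_config_hash_is_stable_and_sensitive(self):
        a = SDEConfig(sigma=0.5, seed=1)
        assert config_hash(a) == config_hash(SDEConfig(sigma=0.5, seed=1))
        assert config_hash(a) != config_hash(SDEConfig(sigma=0.5, seed=2))
        assert len(config_hash(a)) == 16


class TestEnergyRateOrdering:
    def test_noise_degrades_performance(self, medium_env):
        """The long-run net rate under heavy accumulator noise falls below
        the noiseless rate (stochastic leaving times are suboptimal)."""
        _, quiet = run_session(medium_env, sigma=0.0, seed=11,
                               total_time=2000.0, burn_in=200.0)
        _, noisy = run_session(medium_env, sigma=3.0, seed=11,
                               total_time=2000.0, burn_in=200.0)
        assert noisy.mean_energy_rate < quiet.mean_energy_rate
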
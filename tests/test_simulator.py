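"""Epidemic dynamics: state machine contracts, conservation, R0 measurement."""

import math

import numpy as np
import pytest

import walkepi
from walkepi import kernel, simulator


def _python_run(cfg, seed):
    """Drive the pure-Python engine to extinction (small cases only)."""
    rng = np.random.default_rng(seed)
    state = simulator.init_outbreak(cfg)
    while state.walkers and state.time < cfg.resolved_max_time:
        simulator.step(state, cfg, rng)
    return state


class TestInitOutbreak:
    def test_single_index_case_at_origin(self):
        cfg = walkepi.SimConfig.uniform(0.3, 5)
        state = simulator.init_outbreak(cfg)
        assert state.active_count == 1
        assert state.site_status == {(0, 0): simulator.REMOVED}
        assert state.walkers[0].steps_remaining == 5
        assert state.time == 0 and state.cumulative_infections == 0

    def test_p_zero_config_is_valid(self):
        simulator.init_outbreak(walkepi.SimConfig.uniform(0.0, 3))

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            walkepi.SimConfig.uniform(1.5, 3)
        with pytest.raises(ValueError):
            walkepi.SimConfig.uniform(0.5, 0)
        with pytest.raises(TypeError):
            simulator.init_outbreak("not a config")

    def test_two_region_start_cell_offset_from_border(self):
        cfg = walkepi.SimConfig.two_region(0.1, 0.3, 50, boundary_y=100, start_distance=25)
        assert cfg.start_cell == (0, 75)


class TestStep:
    def test_p_zero_dies_out_at_tau_with_only_origin_removed(self):
        tau = 6
        cfg = walkepi.SimConfig.uniform(0.0, tau)
        state = _python_run(cfg, seed=1)
        assert state.time == tau and not state.walkers
        assert state.cumulative_infections == 0
        removed = [c for c, s in state.site_status.items() if s == simulator.REMOVED]
        assert removed == [(0, 0)]

    def test_stepping_dead_state_raises(self):
        cfg = walkepi.SimConfig.uniform(0.0, 1)
        state = _python_run(cfg, seed=1)
        with pytest.raises(RuntimeError):
            simulator.step(state, cfg, np.random.default_rng(0))

    def test_conservation_every_step(self):
        """removed sites = cumulative infections + 1 (index case), always."""
        cfg = walkepi.SimConfig.uniform(0.4, 6)
        rng = np.random.default_rng(8)
        state = simulator.init_outbreak(cfg)
        while state.walkers and state.time < 60:
            simulator.step(state, cfg, rng)
            assert state.removed_count == state.cumulative_infections + 1

    def test_p_one_tau_one_index_infects_exactly_once_unless_same_cell(self):
        """First sweep at p=1: the index walker infects its landing site
        unless it stayed in its own (removed) cell."""
        cfg = walkepi.SimConfig.uniform(1.0, 1)
        hits = []
        for seed in range(400):
            state = simulator.init_outbreak(cfg)
            simulator.step(state, cfg, np.random.default_rng(seed))
            assert state.cumulative_infections in (0, 1)
            hits.append(state.cumulative_infections)
        # same-cell landings are ~7e-4, so nearly every first sweep infects
        assert 0.99 <= np.mean(hits) <= 1.0


class TestRun:
    def test_determinism_same_config_same_seed(self):
        cfg = walkepi.SimConfig.uniform(0.6, 4)
        a = simulator.run(cfg, seed=99)
        b = simulator.run(cfg, seed=99)
        np.testing.assert_array_equal(a.removed, b.removed)
        np.testing.assert_array_equal(a.active, b.active)
        assert a.outcome == b.outcome
        assert a.final_state.site_status == b.final_state.site_status

    def test_p_zero_outcome_died_out_at_tau(self):
        tr = simulator.run(walkepi.SimConfig.uniform(0.0, 4), seed=5)
        assert tr.died_out and tr.time[-1] == 4
        assert tr.removed[-1] == 1

    def test_supercritical_mostly_censored_subcritical_always_dies(self):
        # (p=1, tau=2): R0 ~ 1.86, indefinite spreading for most runs
        cfg_super = walkepi.SimConfig.uniform(1.0, 2, max_time=400, max_removed=5000)
        outcomes = [simulator.run(cfg_super, seed=s, keep_state=False).died_out
                    for s in range(40)]
        assert np.mean(outcomes) < 0.5
        # (p=1/2, tau=2): R0 ~ 0.93 < 1, extinction almost surely
        cfg_sub = walkepi.SimConfig.uniform(0.5, 2, max_time=5000, max_removed=10**6)
        assert all(simulator.run(cfg_sub, seed=s, keep_state=False).died_out
                   for s in range(60))

    def test_trace_invariants_and_active_bookkeeping(self):
        """R(t) non-decreasing; I(t) = infections in the last tau steps
        (+ index case while alive), by construction of walker lifetimes."""
        tau = 5
        tr = simulator.run(
            walkepi.SimConfig.uniform(0.45, tau, max_time=80, max_removed=10**6),
            seed=17,
        )
        assert np.all(np.diff(tr.removed) >= 0)
        assert np.all(tr.active >= 0)
        for t in range(len(tr.time)):
            if t < tau:
                expected = tr.removed[t]  # infections so far + live index
            else:
                expected = tr.removed[t] - tr.removed[t - tau]
            assert tr.active[t] == expected

    def test_cumulative_infections_monotone_in_p(self):
        """Seed-averaged final size at fixed horizon is non-decreasing in p."""
        seeds = range(150)
        means = []
        for p in (0.1, 0.3, 0.6):
            cfg = walkepi.SimConfig.uniform(p, 4, max_time=25, max_removed=10**6)
            means.append(
                np.mean([simulator.run(cfg, seed=s, keep_state=False).removed[-1]
                         for s in seeds])
            )
        assert means[0] < means[1] < means[2]


class TestIndexCaseR0:
    def test_p_zero_measures_exactly_zero(self):
        mean, _ = simulator.measure_r0_index_case(0.0, 5, 1000, seed=1)
        assert mean == 0.0

    def test_tau_one_closed_form_p_times_not_same_cell(self):
        """One jump: R0 = p (1 - P_same_cell), same-cell prob from the kernel."""
        n = 300_000
        stats = kernel.jump_statistics(n, np.random.default_rng(2))
        p = 0.6
        mean, se = simulator.measure_r0_index_case(p, 1, n, seed=3)
        expected = p * (1.0 - stats.frac_same_cell)
        assert abs(mean - expected) < 4 * (se + p * stats.stderr(stats.frac_same_cell))

    def test_table_diagonal_not_constant(self):
        """R0 at equal p*tau differs: (1/2, 4) vs (1/4, 8) split measurably."""
        n = 400_000
        a, se_a = simulator.measure_r0_index_case(0.5, 4, n, seed=4)
        b, se_b = simulator.measure_r0_index_case(0.25, 8, n, seed=5)
        assert abs(a - 1.8042) < 3 * se_a
        assert abs(b - 1.8251) < 3 * se_b
        assert b > a


class TestTwoRegion:
    def test_requires_two_region_field(self):
        with pytest.raises(ValueError):
            simulator.run_two_region(walkepi.SimConfig.uniform(0.2, 3), seed=1)

    def test_equal_probabilities_near_symmetric_counts_on_border(self):
        """With p1 = p2 and the index case on the border, the split is
        even up to the discrete boundary row: region 1 owns the walker's
        starting row (y <= boundary), which holds an O(1/sqrt(c tau))
        share of the visited sites, so the residual asymmetry must favor
        region 1 and shrink with tau."""
        ratios = {}
        for tau in (8, 128):
            res = simulator.measure_r0_index_case_two_region(
                0.3, 0.3, tau, 100_000, seed=6, boundary_y=0, start_distance=0
            )
            ratios[tau] = res["r0_region1"] / res["r0_region2"]
            assert ratios[tau] > 1.0  # extra row always favors region 1
        assert ratios[128] < ratios[8]  # and fades as the walk spreads
        assert ratios[128] < 1.25

    def test_region_counts_sum_to_total(self):
        cfg = walkepi.SimConfig.two_region(
            0.1, 0.3, 20, boundary_y=10, start_distance=5, max_time=80,
            max_removed=10**6,
        )
        tr = simulator.run_two_region(cfg, seed=11)
        np.testing.assert_array_equal(
            tr.removed, tr.removed_region1 + tr.removed_region2
        )

    def test_outbreak_accelerates_after_crossing_into_infectious_region(self):
        """Low-p region feeds the border; growth explodes in the high-p region."""
        cfg = walkepi.SimConfig.two_region(
            0.1, 0.3, 50, boundary_y=25, start_distance=25,
            max_time=300, max_removed=10**9,
        )
        for seed in range(30):
            tr = simulator.run_two_region(cfg, seed=seed, keep_state=False)
            crossed = np.nonzero(tr.removed_region2 > 0)[0]
            if len(crossed) == 0 or tr.died_out:
                continue
            t0 = crossed[0]
            rate1 = (tr.removed_region1[-1] - tr.removed_region1[t0]) / (len(tr.time) - t0)
            rate2 = (tr.removed_region2[-1] - tr.removed_region2[t0]) / (len(tr.time) - t0)
            if tr.removed_region2[-1] > 500:
                assert rate2 > rate1
                return
        pytest.fail("no realization crossed the border and kept growing")


class TestSnapshot:
    def test_initial_state_single_center_cell(self):
        state = simulator.init_outbreak(walkepi.SimConfig.uniform(0.5, 3))
        grid = simulator.export_snapshot(state, ((-1, 1), (-1, 1)))
        assert grid.shape == (3, 3)
        assert grid[1, 1] == simulator.ACTIVE  # removed origin hosting the index case
        assert (grid != 0).sum() == 1

    def test_p_zero_final_state_one_removed_rest_visited(self):
        cfg = walkepi.SimConfig.uniform(0.0, 8)
        tr = simulator.run(cfg, seed=21)
        grid = simulator.export_snapshot(tr.final_state, ((-200, 200), (-200, 200)))
        assert (grid == simulator.REMOVED).sum() == 1
        assert (grid == simulator.ACTIVE).sum() == 0
        touched = set(tr.final_state.site_status.values())
        assert touched <= {simulator.VISITED, simulator.REMOVED}

    def test_raster_counts_match_state(self):
        cfg = walkepi.SimConfig.uniform(0.5, 5, max_time=40, max_removed=2000)
        tr = simulator.run(cfg, seed=33)
        state = tr.final_state
        span = 300
        grid = simulator.export_snapshot(state, ((-span, span), (-span, span)))
        n_removed_grid = int(((grid == simulator.REMOVED) | (grid == simulator.ACTIVE)).sum())
        assert n_removed_grid == state.removed_count
        assert int((grid == simulator.VISITED).sum()) == sum(
            1 for s in state.site_status.values() if s == simulator.VISITED
        )

    def test_empty_window_rejected(self):
        state = simulator.init_outbreak(walkepi.SimConfig.uniform(0.5, 3))
        with pytest.raises(ValueError):
            simulator.export_snapshot(state, ((2, 1), (0, 0)))
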
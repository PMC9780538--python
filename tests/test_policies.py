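"""Habitual-policy and backward-induction solver tests."""

import numpy as np
import pytest

from awaremdp import (
    HabitualParams,
    StateGrid,
    bellman_backup,
    habitual_action,
    habitual_actions,
    preset,
    solve_sdp,
    terminal_reward,
    transition_matrix,
)
from awaremdp.policies import q_values


class TestHabitualPolicy:
    def test_zero_noise_returns_propensity(self, rng):
        params = HabitualParams(p_r=0.6, sigma=0.0)
        assert habitual_action(params, rng) == pytest.approx(0.6)

    def test_draws_clipped_to_action_range(self, rng):
        params = HabitualParams(p_r=0.5, sigma=5.0)
        draws = habitual_actions(params, rng, 2000)
        assert draws.min() >= 0.01 and draws.max() <= 0.99

    def test_draws_on_action_grid(self, rng):
        draws = habitual_actions(HabitualParams(p_r=0.6, sigma=0.08), rng, 2000)
        np.testing.assert_allclose(draws, np.round(draws, 2), atol=1e-12)

    def test_monte_carlo_mean(self, rng):
        n = 100_000
        draws = habitual_actions(HabitualParams(p_r=0.6, sigma=0.08), rng, n)
        # grid snapping and clipping bias are negligible at this sigma
        assert abs(draws.mean() - 0.6) < 3 * 0.08 / np.sqrt(n) + 0.005


class TestBellmanBackup:
    def test_single_step_hand_computation(self, symmetric_shape):
        cfg = preset(
            "fig6", seed=1, T=3,
            shape={"sharp_intuitive": 5.0, "sharp_analytical": 5.0},
        )
        grid = cfg.grid()
        params = cfg.reward_params()
        v_terminal = terminal_reward(grid.levels, params)
        got = bellman_backup(0.5, 0.5, v_terminal, tau=2, config=cfg)
        # independent arithmetic from the printed backup formula
        p_up = 0.35517578125
        p_down = 1.0 - 0.1 - p_up
        term = lambda s: 10.0 * np.expm1(5.0 * s) / np.expm1(5.0)
        expected = (1.0 * 0.5 - 1.5 * 0.5) + 0.75 * (
            3.0 * term(0.51) * p_up + 1.0 * term(0.50) * 0.1 + 0.1 * term(0.49) * p_down
        )
        assert got == pytest.approx(expected, abs=1e-12)

    def test_stay_only_kernel_collapses_expectation(self):
        # with a degenerate stay row and unit gamma the backup is r + delta*V(s)
        v_next = np.linspace(0.0, 5.0, 9)
        r_as = np.full((1, 9), 2.0)
        rows = np.array([[0.0, 1.0, 0.0]])
        q = q_values(v_next, r_as, rows, np.ones(3), np.full(9, 0.75))
        np.testing.assert_allclose(q[0], 2.0 + 0.75 * v_next)

    def test_emotion_backup_is_myopic_at_stage_zero(self):
        cfg = preset("fig7b", seed=1, T=10)
        v_next = np.full(99, 1e6)  # enormous continuation value
        got = bellman_backup(0.5, 0.3, v_next, tau=0, config=cfg)
        assert got == pytest.approx(10.0 * 0.5 - 20.0 * 0.3)


class TestSolveSdp:
    def test_horizon_one_equals_direct_scan(self):
        cfg = preset("fig6", seed=1, T=1)
        policy, values = solve_sdp(cfg)
        grid = cfg.grid()
        params = cfg.reward_params()
        rows = transition_matrix(grid.levels, cfg.p_r, cfg.curve_shape(), cfg.p_stay)
        term = terminal_reward(grid.levels, params)
        iup = np.minimum(np.arange(99) + 1, 98)
        idn = np.maximum(np.arange(99) - 1, 0)
        g1, g2, g3 = params.gamma
        for si in range(0, 99, 7):
            q = (
                params.alpha * grid.levels[si]
                - params.beta * grid.levels
                + params.delta
                * (
                    g1 * term[iup[si]] * rows[:, 0]
                    + g2 * term[si] * rows[:, 1]
                    + g3 * term[idn[si]] * rows[:, 2]
                )
            )
            assert policy.action_index[si, 0] == np.argmax(q)
            assert values.values[si, 0] == pytest.approx(q.max())

    def test_terminal_column_is_terminal_reward(self):
        cfg = preset("fig6", seed=1, T=5)
        _, values = solve_sdp(cfg)
        np.testing.assert_allclose(
            values.values[:, -1], terminal_reward(cfg.grid().levels, cfg.reward_params())
        )

    def test_costfree_analyticity_maximises_forward_mass(self):
        # with beta = 0 and an increasing continuation, the optimal action
        # maximises the gamma-weighted chance of moving up
        cfg = preset("fig6", seed=1, T=1)
        cfg = cfg.model_copy(
            update={"rewards": cfg.rewards.model_copy(update={"beta": 0.0})}
        )
        policy, _ = solve_sdp(cfg)
        rows = transition_matrix(
            cfg.grid().levels, cfg.p_r, cfg.curve_shape(), cfg.p_stay
        )
        best_forward = np.argmax(rows[:, 0])
        # interior states (boundary rows clamp and can shift the argmax)
        assert np.all(policy.action_index[1:-1, 0] == best_forward)

    def test_bit_reproducible(self):
        cfg = preset("fig6", seed=1, T=30)
        p1, v1 = solve_sdp(cfg)
        p2, v2 = solve_sdp(cfg)
        assert np.array_equal(p1.decisions, p2.decisions)
        assert np.array_equal(v1.values, v2.values)

    def test_policy_table_shape_and_grid(self):
        cfg = preset("fig6", seed=1, T=12)
        policy, values = solve_sdp(cfg)
        assert policy.decisions.shape == (99, 12)
        assert values.values.shape == (99, 13)
        assert np.all(np.isin(np.round(policy.decisions, 2), np.round(policy.actions, 2)))
        assert np.all((policy.decisions > 0) & (policy.decisions < 1))

    def test_value_bounded_with_contracting_weights(self):
        # the additivity bound needs delta * max(gamma) < 1, i.e. the
        # direction weights inside (0, 1) the model text prescribes
        cfg = preset("fig6", seed=1, T=20)
        cfg = cfg.model_copy(
            update={"rewards": cfg.rewards.model_copy(update={"gamma": (0.9, 0.5, 0.2)})}
        )
        policy, values = solve_sdp(cfg)
        grid = StateGrid()
        params = cfg.reward_params()
        r_max = max(
            abs(params.alpha * s - params.beta * u)
            for s in (0.01, 0.99)
            for u in (0.01, 0.99)
        )
        bound = cfg.T * r_max + terminal_reward(0.99, params)
        assert np.all(np.isfinite(values.values))
        assert np.max(np.abs(values.values)) <= bound
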
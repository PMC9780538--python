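"""Transition-kernel unit and property tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from awaremdp import (
    ConfigurationError,
    CurveShape,
    StateGrid,
    TransitionRow,
    base_forward_analytical,
    base_forward_intuitive,
    forward_prob,
    sample_shock,
    step_state,
    transition_matrix,
    transition_row,
)

U_GRID = np.round(np.arange(1, 100) * 0.01, 2)


class TestBaseCurves:
    def test_analytical_closed_form_with_unit_exponents(self):
        # sharpness 5 at peak 0.8 gives exponents (a, b) = (4, 1):
        # p(0.5) = 0.05 + 0.80 * 0.5^5 / (0.8^4 * 0.2)
        shape = CurveShape(sharp_analytical=5.0)
        expected = 0.05 + 0.80 * 0.5**5 / (0.8**4 * 0.2)
        assert base_forward_analytical(0.5, shape) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.35517578125)

    def test_peaks_attain_p_peak(self):
        shape = CurveShape()
        assert base_forward_analytical(shape.peak_analytical, shape) == pytest.approx(0.85)
        assert base_forward_intuitive(shape.peak_intuitive, shape) == pytest.approx(0.85)

    def test_floor_limits(self):
        shape = CurveShape()
        assert base_forward_analytical(1e-12, shape) == pytest.approx(0.05, abs=1e-6)
        assert base_forward_analytical(1 - 1e-12, shape) == pytest.approx(0.05, abs=1e-6)
        # the intuitive hump is broad, so approach the endpoints harder
        assert base_forward_intuitive(1e-200, shape) == pytest.approx(0.05, abs=1e-8)
        assert base_forward_intuitive(1 - 1e-12, shape) == pytest.approx(0.05, abs=1e-4)

    def test_mirror_symmetry_of_symmetric_shapes(self, symmetric_shape):
        a = base_forward_analytical(U_GRID, symmetric_shape)
        i = base_forward_intuitive(U_GRID, symmetric_shape)
        np.testing.assert_allclose(i, a[::-1], atol=1e-12)

    @pytest.mark.parametrize("fn", [base_forward_analytical, base_forward_intuitive])
    def test_unimodal_on_grid(self, fn):
        vals = fn(U_GRID, CurveShape())
        d = np.diff(vals)
        # exactly one sign change from rising to falling
        rising = d > 0
        assert rising[0] and not rising[-1]
        assert np.sum(rising[:-1] & ~rising[1:]) == 1

    @pytest.mark.parametrize("u", [0.0, 1.0, -0.2, 1.7])
    def test_domain_errors(self, u):
        with pytest.raises(ValueError):
            base_forward_analytical(u)


class TestForwardMixture:
    def test_convex_combination_endpoints(self):
        shape = CurveShape()
        np.testing.assert_allclose(
            forward_prob(U_GRID, 1.0, shape), base_forward_analytical(U_GRID, shape)
        )
        np.testing.assert_allclose(
            forward_prob(U_GRID, 0.0, shape), base_forward_intuitive(U_GRID, shape)
        )

    def test_symmetric_midpoint_value(self, symmetric_shape):
        # at u = 0.5 both mirrored curves coincide, so any mixture equals them
        assert forward_prob(0.5, 0.5, symmetric_shape) == pytest.approx(
            0.35517578125, abs=1e-12
        )

    def test_p_r_domain_error(self):
        with pytest.raises(ValueError):
            forward_prob(0.5, 1.2)

    def test_mixture_monotone_in_p_r_beyond_the_peaks(self):
        shape = CurveShape()
        prs = np.round(np.arange(11) * 0.1, 1)
        for u in U_GRID[U_GRID < shape.peak_intuitive]:
            vals = [forward_prob(float(u), float(p), shape) for p in prs]
            assert np.all(np.diff(vals) <= 1e-12)
        for u in U_GRID[U_GRID > shape.peak_analytical]:
            vals = [forward_prob(float(u), float(p), shape) for p in prs]
            assert np.all(np.diff(vals) >= -1e-12)


class TestTransitionRow:
    def test_stationary_probability_is_constant(self):
        for u in (0.05, 0.5, 0.95):
            assert transition_row(u, 0.6).p_stay == 0.1

    def test_symmetric_midpoint_row(self, symmetric_shape):
        row = transition_row(0.5, 0.5, symmetric_shape)
        assert row.p_up == pytest.approx(0.35517578125, abs=1e-12)
        assert row.p_down == pytest.approx(1 - 0.1 - 0.35517578125, abs=1e-12)

    def test_row_stochastic_everywhere(self):
        for p_r in np.round(np.arange(11) * 0.1, 1):
            rows = transition_matrix(U_GRID, float(p_r))
            assert np.all(rows >= 0) and np.all(rows <= 1)
            np.testing.assert_allclose(rows.sum(axis=1), 1.0, atol=1e-12)

    def test_budget_violation_raises(self):
        shape = CurveShape(p_peak=0.95)
        with pytest.raises(ConfigurationError):
            transition_row(0.8, 1.0, shape, p_stay=0.1)

    def test_invalid_row_rejected(self):
        with pytest.raises(ConfigurationError):
            TransitionRow(0.5, 0.2, 0.4)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        u=st.floats(min_value=0.001, max_value=0.999),
        p_r=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_row_property(self, u, p_r):
        row = transition_row(u, p_r)
        assert 0.0 <= row.p_up <= 1.0 and 0.0 <= row.p_down <= 1.0
        assert row.p_up + row.p_stay + row.p_down == pytest.approx(1.0, abs=1e-12)


class TestShockAndStep:
    def test_degenerate_rows(self, rng):
        up = TransitionRow(1.0, 0.0, 0.0)
        down = TransitionRow(0.0, 0.0, 1.0)
        assert all(sample_shock(up, rng) == 1 for _ in range(50))
        assert all(sample_shock(down, rng) == -1 for _ in range(50))

    def test_empirical_frequencies(self, rng):
        row = transition_row(0.5, 0.5, CurveShape(sharp_intuitive=5.0))
        n = 100_000
        draws = np.array([sample_shock(row, rng) for _ in range(n)])
        for value, p in ((1, row.p_up), (0, row.p_stay), (-1, row.p_down)):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(np.mean(draws == value) - p) < 3 * se

    def test_single_step_and_clamps(self):
        grid = StateGrid()
        assert step_state(0.20, 1, grid) == pytest.approx(0.21)
        assert step_state(0.99, 1, grid) == pytest.approx(0.99)
        assert step_state(0.01, -1, grid) == pytest.approx(0.01)

    def test_off_grid_snaps_with_warning(self):
        grid = StateGrid()
        with pytest.warns(RuntimeWarning, match="off-grid"):
            assert step_state(0.204, 0, grid) == pytest.approx(0.20)

    def test_grid_levels(self):
        grid = StateGrid()
        assert grid.n == 99
        assert grid.levels[0] == pytest.approx(0.01)
        assert grid.levels[-1] == pytest.approx(0.99)
        np.testing.assert_allclose(np.diff(grid.levels), 0.01)
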
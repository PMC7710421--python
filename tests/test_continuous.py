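"""Continuous sparseness optimization of entropy per unit energy."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sparsenergy import (
    binary_entropy,
    cap_per_cost,
    continuous_optima_table,
    cost_per_cap,
    naive_cost_map,
    optimize_p,
    sweep_grid,
)


class TestObjectives:
    @pytest.mark.parametrize(
        "p, r, expected",
        [(0.353, 1.4, 0.1887), (0.341, 1.6, 0.1803), (0.329, 1.8, 0.1728)],
    )
    def test_cap_per_cost_spot_values(self, p, r, expected):
        assert cap_per_cost(p, r, fc=1.0, base=10.0) == pytest.approx(expected, abs=5e-5)

    def test_cost_is_exact_reciprocal(self):
        cap = cap_per_cost(0.3, 1.7)
        assert cost_per_cap(0.3, 1.7) == pytest.approx(1.0 / cap, rel=1e-15)

    def test_continuity_endpoints(self):
        assert cap_per_cost(0.0, 1.5) == 0.0
        assert cap_per_cost(1.0, 1.5) == 0.0
        assert cost_per_cap(0.0, 1.5) == math.inf

    def test_fc_scales_cap_inversely(self):
        assert cap_per_cost(0.3, 1.5, fc=2.0) == pytest.approx(
            cap_per_cost(0.3, 1.5, fc=1.0) / 2.0
        )

    @given(p=st.floats(0.01, 0.99), r=st.floats(0.0, 100.0))
    @settings(max_examples=100, deadline=None)
    def test_reciprocal_identity(self, p, r):
        assert cap_per_cost(p, r) * cost_per_cap(p, r) == pytest.approx(1.0, rel=1e-12)


class TestOptimizer:
    # true maximizers of H(p)/(1+rp); frozen from the first-order condition
    # log((1-p)/p)(1+rp) = r H(p) solved to 40 digits with mpmath.findroot
    TRUE_P = {1.4: 0.3524353699, 1.6: 0.3397775727, 1.8: 0.3282425815, 2.0: 0.3176721962}

    @pytest.mark.parametrize("r", [1.4, 1.6, 1.8, 2.0])
    def test_p_star_against_root_finding_oracle(self, r):
        assert optimize_p(r).p_star == pytest.approx(self.TRUE_P[r], abs=1e-6)

    def test_zero_ratio_gives_half(self):
        assert optimize_p(0.0).p_star == 0.5

    @pytest.mark.parametrize("r", [1.3, 1.7, 2.1])
    def test_base_invariance(self, r):
        p10 = optimize_p(r, base=10.0).p_star
        pe = optimize_p(r, base=math.e).p_star
        assert abs(p10 - pe) < 1e-6

    @pytest.mark.parametrize("r", [1.3, 1.4, 1.5, 1.6, 1.7, 1.8, 1.9, 2.0, 2.1])
    def test_two_modes_agree(self, r):
        p_cap = optimize_p(r, mode="maximize-cap").p_star
        p_cost = optimize_p(r, mode="minimize-cost").p_star
        assert abs(p_cap - p_cost) < 1e-6
        cap = optimize_p(r, mode="maximize-cap").objective_value
        cost = optimize_p(r, mode="minimize-cost").objective_value
        assert cap * cost == pytest.approx(1.0, rel=1e-9)

    def test_p_star_strictly_decreasing_in_r(self):
        rs = np.concatenate([np.linspace(0.1, 5, 25), np.linspace(5.5, 100, 20)])
        ps = [optimize_p(float(r)).p_star for r in rs]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize("r", [1.3, 1.57, 1.8, 2.09])
    def test_first_order_condition(self, r):
        p = optimize_p(r).p_star
        lhs = math.log((1 - p) / p) * (1 + r * p)
        rhs = r * binary_entropy(p, math.e)
        assert lhs == pytest.approx(rhs, abs=1e-6)

    def test_headline_band(self):
        """For every calibrated ratio, optimal sparseness is 30-40%."""
        for r in np.arange(1.3, 2.1 + 1e-9, 0.01):
            assert 0.3 <= optimize_p(float(r)).p_star <= 0.4

    def test_table_columns(self):
        df = continuous_optima_table([1.4, 2.0])
        assert list(df.columns) == ["r", "p_star", "cap_max", "cost_min", "base"]
        assert (df["cap_max"] * df["cost_min"]).round(12).eq(1.0).all()


class TestGrids:
    def test_single_cell_matches_objective(self):
        grid = sweep_grid(np.array([0.353]), np.array([1.4]), mode="cap")
        assert grid.values[0, 0] == pytest.approx(0.1887, abs=5e-5)

    def test_row_argmax_agrees_with_optimizer(self):
        p_axis = np.round(np.arange(0.001, 0.5 + 1e-12, 0.001), 6)
        r_axis = np.round(np.arange(1.3, 2.1 + 1e-12, 0.1), 6)
        ext = sweep_grid(p_axis, r_axis, mode="cap").row_extremum()
        for _, row in ext.iterrows():
            assert abs(row["p_opt"] - optimize_p(row["r"]).p_star) <= 0.001 + 1e-12
            assert 0.3 <= row["p_opt"] <= 0.4

    def test_cap_and_cost_grids_are_reciprocal(self):
        p_axis = np.array([0.1, 0.3, 0.5])
        r_axis = np.array([1.5, 2.0])
        cap = sweep_grid(p_axis, r_axis, mode="cap").values
        cost = sweep_grid(p_axis, r_axis, mode="cost").values
        assert np.allclose(cap * cost, 1.0, rtol=1e-12)

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            sweep_grid(np.array([0.5, 0.1]), np.array([1.0]))
        with pytest.raises(ValueError):
            sweep_grid(np.array([0.6]), np.array([1.0]))

    def test_naive_cost_map_is_affine_and_monotone(self):
        p_axis = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        r_axis = np.array([1.0, 50.0, 100.0])
        grid = naive_cost_map(p_axis, r_axis, fc=1.0, N=100)
        assert grid.values[0, 0] == 100.0  # p=0: fixed costs only
        assert grid.values[2, -1] == 10100.0  # p=1, r=100
        diffs = np.diff(grid.values, axis=1)
        # affine in p along each r row: constant increments
        assert np.allclose(diffs, diffs[:, :1])
        assert (diffs > 0).all()
        # increasing in r wherever signaling is present (p > 0)
        assert (np.diff(grid.values[:, 1:], axis=0) > 0).all()

    def test_long_format_frame(self):
        grid = sweep_grid(np.array([0.2, 0.4]), np.array([1.5]), mode="cost")
        df = grid.to_frame()
        assert len(df) == 2
        assert set(df["mode"]) == {"cost"}
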
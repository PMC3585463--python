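"""Fixed points, Jacobian entries, and stability classification."""

import numpy as np
import pytest

from isletcycle.dynamics import rhs_full
from isletcycle.parameters import STATE_FIELDS
from isletcycle.steady_state import (
    classify_stability,
    glucose_threshold,
    jacobian,
    nontrivial_steady_state,
    trivial_steady_state,
)
from isletcycle.storage import provision_steady_state, xmax

IDX = {f: i for i, f in enumerate(STATE_FIELDS)}


class TestGlucoseThreshold:
    def test_default_value_rounds_to_80(self, params):
        Ghat = glucose_threshold(params)
        assert Ghat == pytest.approx(79.8235, abs=1e-3)
        assert round(Ghat) == 80

    def test_algebraic_example(self, params):
        p = params.replace(p4=2 * params.p1, p5=1.0)
        assert glucose_threshold(p) == pytest.approx(1.0, rel=1e-14)

    def test_inverse_proportionality_in_p5(self, params):
        base = glucose_threshold(params)
        bumped = glucose_threshold(params.replace(p5=1.1 * params.p5))
        assert bumped == pytest.approx(base / 1.1, rel=1e-12)

    def test_requires_p4_above_p1(self, params):
        with pytest.raises(ValueError):
            glucose_threshold(params.replace(p4=params.p1 / 2))


class TestTrivialSteadyState:
    def test_coordinates(self, params):
        rep = trivial_steady_state(params, classify=False)
        assert rep.state[IDX["G"]] == pytest.approx(100.0, rel=1e-14)
        assert rep.state[IDX["P"]] == pytest.approx(
            provision_steady_state(100.0, params), rel=1e-12
        )
        assert np.all(rep.state[[0, 1, 2, 4, 5, 6]] == 0.0)

    def test_residual_below_tolerance(self, params):
        rep = trivial_steady_state(params, classify=False)
        assert rep.converged
        assert rep.residual_norm < 1e-12


class TestNontrivialSteadyState:
    def test_glucose_pinned_at_threshold(self, params):
        rep = nontrivial_steady_state(params, classify=False)
        assert rep.state[IDX["G"]] == glucose_threshold(params)

    def test_pinned_closed_forms(self, params):
        rep = nontrivial_steady_state(params, classify=False)
        p = params
        Gs = glucose_threshold(p)
        Is = (p.p6 - p.p7 * Gs) / (p.p8 * Gs)
        assert rep.state[IDX["I"]] == pytest.approx(Is, rel=1e-14)
        assert rep.state[IDX["X1"]] == pytest.approx(p.bv * p.p10 * Is / p.p9, rel=1e-14)
        assert rep.state[IDX["P"]] == pytest.approx(
            provision_steady_state(Gs, p), rel=1e-14
        )

    def test_converged_residual(self, params):
        rep = nontrivial_steady_state(params, classify=False)
        assert rep.converged
        assert rep.residual_norm < 1e-8

    def test_cell_cycle_balance_at_root(self, params):
        rep = nontrivial_steady_state(params, classify=False)
        s = rep.state
        assert params.p2 * s[IDX["S"]] == pytest.approx(
            params.p3 * s[IDX["G2M"]], rel=1e-10
        )
        r = rhs_full(0.0, s, params)
        assert abs(r[IDX["S"]]) < 1e-8 * max(1.0, s[IDX["S"]])

    def test_capacity_bound_holds_at_root(self, params):
        """The redistribution construction enforces X1*+X2* <= Xmax(G1*)."""
        rep = nontrivial_steady_state(params, classify=False)
        s = rep.state
        cap = xmax(s[IDX["G1"]], params)
        assert s[IDX["X1"]] + s[IDX["X2"]] <= cap * (1 + 1e-6)

    def test_rejects_regime_without_insulin_demand(self, params):
        # Ghat above p6/p7 would force negative steady-state insulin
        bad = params.replace(p5=0.001)
        with pytest.raises(ValueError, match="p6/p7"):
            nontrivial_steady_state(bad, classify=False)


class TestJacobian:
    def test_bilinear_glucose_insulin_entry(self, params, init):
        x = init.as_array()
        J = jacobian(x, params)
        assert J[IDX["G"], IDX["I"]] == pytest.approx(-params.p8 * x[IDX["G"]], rel=1e-6)

    def test_linear_cycle_entry(self, params, init):
        x = init.as_array()
        J = jacobian(x, params)
        expected = params.p1 * (1 + params.p5 * x[IDX["G"]])
        assert J[IDX["S"], IDX["G1"]] == pytest.approx(expected, rel=1e-6)

    def test_provision_row_sparsity(self, params, init):
        J = jacobian(init.as_array(), params)
        row = J[IDX["P"]]
        assert row[IDX["P"]] == pytest.approx(-params.p11, rel=1e-6)
        nonzero = np.flatnonzero(np.abs(row) > 1e-12 * np.abs(row).max())
        assert set(nonzero) == {IDX["G"], IDX["P"]}

    def test_step_size_bounds_enforced(self, params, init):
        with pytest.raises(ValueError):
            jacobian(init.as_array(), params, eps_rel=1.0)


class TestStability:
    def test_trivial_point_is_unstable(self, params):
        rep = trivial_steady_state(params)
        assert rep.classification == "unstable"
        assert rep.eigenvalues.real.max() > 0

    def test_nontrivial_point_is_stable(self, params):
        rep = nontrivial_steady_state(params)
        assert rep.classification == "stable"
        assert rep.eigenvalues.real.max() < 0

    @pytest.mark.parametrize("eps_rel", [1e-7, 1e-6, 1e-5, 1e-4])
    def test_classification_robust_to_step_size(self, params, eps_rel):
        f1 = trivial_steady_state(params, classify=False)
        f2 = nontrivial_steady_state(params, classify=False)
        assert classify_stability(f1, params, eps_rel=eps_rel) == "unstable"
        assert classify_stability(f2, params, eps_rel=eps_rel) == "stable"

    def test_cycle_block_balances_at_threshold(self, params):
        """The frozen 3x3 cell-cycle block at G = Ghat has a zero dominant mode."""
        from conftest import cell_cycle_matrix

        M = cell_cycle_matrix(glucose_threshold(params), params)
        lam = np.linalg.eigvals(M)
        assert abs(lam.real.max()) < 1e-12
        assert abs(np.linalg.det(M)) < 1e-20

    def test_long_run_glucose_approach_is_monotone(self, params, long_traj_1e5):
        """|G - G*| shrinks monotonically over the last decade of a 1e5-min run."""
        rep = nontrivial_steady_state(params, classify=False)
        Gs = rep.state[IDX["G"]]
        mask = long_traj_1e5.t >= 1e4
        gap = np.abs(long_traj_1e5.column("G")[mask] - Gs)
        assert np.all(np.diff(gap) < 0)
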
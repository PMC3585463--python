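"""Closed-form storage algebra against quadrature and identity oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isletcycle.parameters import DEFAULT_G1_INITIAL
from isletcycle.storage import (
    StorageFunctions,
    compartment_integrals,
    provision_steady_state,
    redistribution_factor,
    target_cumulative,
    target_density,
    transition_functions,
    xmax,
)

G1_0 = DEFAULT_G1_INITIAL

glucose = st.floats(min_value=1.0, max_value=600.0)
cellmass = st.floats(min_value=1.0, max_value=1e9)


class TestProvisionSteadyState:
    def test_half_saturation_at_michaelis_constant(self, params):
        assert provision_steady_state(params.P0, params) == pytest.approx(0.5)

    def test_zero_at_zero_glucose(self, params):
        assert provision_steady_state(0.0, params) == 0.0

    def test_reference_values(self, params):
        # independently recomputed from the Hill form with h=5, P0=186.506
        assert provision_steady_state(80.0, params) == pytest.approx(0.0143128, rel=1e-5)
        assert provision_steady_state(79.8235, params) == pytest.approx(0.0141590, rel=1e-4)

    def test_rejects_negative(self, params):
        with pytest.raises(ValueError):
            provision_steady_state(-1.0, params)

    @given(G=glucose)
    @settings(max_examples=50, deadline=None)
    def test_bounded_in_unit_interval(self, params, G):
        v = provision_steady_state(G, params)
        assert 0.0 < v < 1.0


class TestTargetDistribution:
    def test_half_max_at_michaelis_constant(self, params):
        v = target_cumulative(params.C, G1_0, params)
        assert v == pytest.approx(params.Xbar_max / 2, rel=1e-12)
        assert v == pytest.approx(0.825e-3, rel=1e-9)

    def test_zero_cell_mass_gives_empty_store(self, params):
        assert target_cumulative(200.0, 0.0, params) == 0.0

    def test_cumulative_matches_density_quadrature(self, params):
        theta = np.linspace(0.0, 200.0, 200_001)
        quad = np.trapezoid(target_density(theta, G1_0, params), theta)
        assert quad == pytest.approx(target_cumulative(200.0, G1_0, params), rel=1e-8)

    def test_density_vanishes_at_origin(self, params):
        assert target_density(0.0, G1_0, params) == 0.0

    def test_density_normalizes_to_capacity(self, params):
        theta = np.linspace(0.0, 50_000.0, 500_001)
        quad = np.trapezoid(target_density(theta, G1_0, params), theta)
        assert quad == pytest.approx(xmax(G1_0, params), rel=1e-3)

    def test_density_peaks_between_100_and_200(self, params):
        theta = np.linspace(1.0, 500.0, 5000)
        peak = theta[np.argmax(target_density(theta, G1_0, params))]
        assert 100.0 < peak < 200.0


class TestCompartmentIntegrals:
    def test_symmetric_split_at_michaelis_constant(self, params):
        A, B = compartment_integrals(params.C, G1_0, params)
        assert A == pytest.approx(B, rel=1e-12)
        assert A == pytest.approx(xmax(G1_0, params) / 2, rel=1e-12)

    def test_limits(self, params):
        A, B = compartment_integrals(0.0, G1_0, params)
        assert A == 0.0
        assert B == pytest.approx(xmax(G1_0, params), rel=1e-12)

    def test_matches_quadrature(self, params):
        G = 120.0
        t1 = np.linspace(0.0, G, 100_001)
        t2 = np.linspace(G, 30_000.0, 600_001)
        A, B = compartment_integrals(G, G1_0, params)
        assert np.trapezoid(target_density(t1, G1_0, params), t1) == pytest.approx(A, rel=1e-7)
        assert np.trapezoid(target_density(t2, G1_0, params), t2) == pytest.approx(B, rel=1e-3)

    @given(G=glucose, G1=cellmass)
    @settings(max_examples=100, deadline=None)
    def test_conservation_exact(self, params, G, G1):
        """A + B = Xmax holds as an exact algebraic identity."""
        A, B = compartment_integrals(G, G1, params)
        assert A + B == pytest.approx(xmax(G1, params), rel=1e-14)


class TestRedistributionFactor:
    def test_positive_and_finite_at_reference_point(self, params):
        v = redistribution_factor(100.0, G1_0, params)
        assert np.isfinite(v) and v > 0

    def test_inverse_cell_mass_scaling(self, params):
        a = redistribution_factor(140.0, G1_0, params)
        b = redistribution_factor(140.0, 2 * G1_0, params)
        assert b == pytest.approx(a / 2, rel=1e-12)

    def test_rejects_boundary_inputs(self, params):
        with pytest.raises(ValueError):
            redistribution_factor(0.0, G1_0, params)
        with pytest.raises(ValueError):
            redistribution_factor(100.0, 0.0, params)


class TestTransitionFunctionIdentities:
    """The u-form and the integral form are the same algebra."""

    def test_u3_times_cells_is_provision_inflow(self, params):
        rng = np.random.default_rng(7)
        for G, G1 in zip(rng.uniform(1, 600, 100), rng.uniform(1, 1e9, 100)):
            _, _, u3, u4 = transition_functions(G, params)
            A, B = compartment_integrals(G, G1, params)
            assert u3 * G1 == pytest.approx(params.f * A, rel=1e-12)
            assert u4 * G1 == pytest.approx(params.f * B, rel=1e-12)

    def test_u1_u2_are_redistribution_rates(self, params):
        rng = np.random.default_rng(11)
        for G, G1 in zip(rng.uniform(1, 600, 100), rng.uniform(1, 1e9, 100)):
            u1, u2, _, _ = transition_functions(G, params)
            ft = redistribution_factor(G, G1, params)
            A, B = compartment_integrals(G, G1, params)
            assert u1 == pytest.approx(ft * B, rel=1e-10)
            assert u2 == pytest.approx(ft * A, rel=1e-10)

    def test_u3_u4_ratio(self, params):
        for G in (50.0, 149.78, 300.0):
            _, _, u3, u4 = transition_functions(G, params)
            assert u3 / u4 == pytest.approx((G / params.C) ** params.k, rel=1e-10)


@given(G=glucose, G1=st.floats(min_value=1.0, max_value=1e8))
@settings(max_examples=60, deadline=None)
def test_scale_equivariance_in_cell_mass(params, G, G1):
    """Doubling G1 doubles Xmax, A, B, xi*; halves f_tilde; fixes u1..u4."""
    sf = StorageFunctions(params)
    assert sf.Xmax(2 * G1) == pytest.approx(2 * sf.Xmax(G1), rel=1e-14)
    assert sf.A(G, 2 * G1) == pytest.approx(2 * sf.A(G, G1), rel=1e-14)
    assert sf.xi_star(G, 2 * G1) == pytest.approx(2 * sf.xi_star(G, G1), rel=1e-14)
    assert sf.f_tilde(G, 2 * G1) == pytest.approx(sf.f_tilde(G, G1) / 2, rel=1e-12)
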
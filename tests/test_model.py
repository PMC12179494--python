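"""Unit and property tests for the four-pool model core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from essoil import (
    ModelParameters,
    PoolState,
    TemperatureLocalParameters,
    apply_temperature,
    equilibrium_doc,
    feasible_trait_range,
    phi_star,
    respiration_flux,
    rhs,
    solve_equilibrium,
)
from essoil.model import jacobian_stability

from .conftest import draw_feasible_setup, random_positive_state


def integrate_to_equilibrium(eq, tp, params, phi, factors=(1.3, 0.7, 1.2, 0.8), t_end=3e6):
    x0 = eq.state.as_array() * np.array(factors)

    def f(_, x):
        return rhs(PoolState(*np.maximum(x, 0.0)), tp, params, phi)

    sol = solve_ivp(f, (0.0, t_end), x0, method="LSODA", rtol=1e-10, atol=1e-14)
    assert sol.success
    return sol.y[:, -1]


class TestRHS:
    def test_origin_only_litter_flux(self, tp20, params):
        d = rhs(PoolState(0, 0, 0, 0), tp20, params, 0.1)
        assert d == pytest.approx([params.I, 0.0, 0.0, 0.0])

    def test_equilibrium_is_fixed_point(self, tp20, params, kernel):
        phi = phi_star(tp20, params, kernel).phi_star
        eq = solve_equilibrium(tp20, params, phi)
        assert eq.feasible
        assert np.max(np.abs(rhs(eq.state, tp20, params, phi))) < 1e-9

    @given(
        c=st.floats(1e-9, 1e3),
        d=st.floats(1e-9, 1e2),
        m=st.floats(1e-9, 1e2),
        z=st.floats(1e-9, 1e2),
        phi=st.floats(0.0, 0.99),
    )
    @settings(max_examples=200, deadline=None)
    def test_mass_balance_identity(self, c, d, m, z, phi):
        params = ModelParameters(
            I=5e-3, eC=1e-5, eD=1e-4, v0D=1e8, EvD=47, K0D=1e8, EKD=30,
            v0U=1e5, EvU=38, K0U=20, EKU=10, dM=3.8e-4, dZ=1e-3, gM=0.5, gZ=0.5,
        )
        tp = apply_temperature(params, 15.0)
        state = PoolState(c, d, m, z)
        derivs = rhs(state, tp, params, phi)
        total = float(np.sum(derivs))
        expected = params.I - params.eC * c - params.eD * d - respiration_flux(state, tp, params, phi)
        # machine precision relative to the magnitude of the summed fluxes
        scale = float(np.sum(np.abs(derivs))) + abs(expected)
        assert abs(total - expected) <= 1e-13 * max(scale, 1e-30)

    def test_negative_pool_rejected(self, tp20, params):
        with pytest.raises(ValueError, match="pools"):
            rhs(PoolState(-1.0, 0, 0, 0), tp20, params, 0.1)

    def test_phi_out_of_range_rejected(self, tp20, params):
        with pytest.raises(ValueError, match="phi"):
            rhs(PoolState(1, 1, 1, 1), tp20, params, 1.0)


class TestRespiration:
    def test_perfect_efficiency_respires_nothing(self, tp20, params):
        from dataclasses import replace

        p = replace(params, gM=1.0, gZ=1.0)
        tp = TemperatureLocalParameters(
            vmaxD=tp20.vmaxD, KmD=tp20.KmD, vmaxU=tp20.vmaxU, KmU=tp20.KmU,
            dM_T=tp20.dM_T, gM_T=1.0, T=tp20.T,
        )
        assert respiration_flux(PoolState(5, 1, 2, 0.5), tp, p, 0.3) == pytest.approx(0.0, abs=1e-18)

    def test_zero_biomass_zero_flux(self, tp20, params):
        assert respiration_flux(PoolState(5, 1, 0, 0.5), tp20, params, 0.3) == 0.0

    def test_equilibrium_flux_closes_mass_balance(self, tp20, params, kernel):
        phi = phi_star(tp20, params, kernel).phi_star
        eq = solve_equilibrium(tp20, params, phi)
        flux = respiration_flux(eq.state, tp20, params, phi)
        assert flux == pytest.approx(params.I - params.eC * eq.state.C - params.eD * eq.state.D, rel=1e-9)

    def test_two_equivalent_forms(self, tp20, params, rng):
        for _ in range(20):
            state = random_positive_state(rng)
            phi = rng.uniform(0, 0.95)
            upt = tp20.vmaxU * state.D / (tp20.KmU + state.D) * state.M
            alt = upt * (phi * (1 - params.gZ) + (1 - phi) * (1 - tp20.gM_T))
            assert respiration_flux(state, tp20, params, phi) == pytest.approx(alt, rel=1e-12)


class TestEquilibriumDoc:
    def test_half_saturation_construction(self, params):
        # (1-phi)*gM*vmaxU == 2*dM  =>  D* == KmU
        tp = TemperatureLocalParameters(
            vmaxD=1.0, KmD=1.0, vmaxU=4.0 * params.dM, KmU=0.7, dM_T=params.dM, gM_T=0.5, T=20.0
        )
        assert equilibrium_doc(tp, params, 0.0) == pytest.approx(0.7)

    def test_infeasible_when_denominator_nonpositive(self, tp20, params):
        phi_bound = 1.0 - tp20.dM_T / (tp20.gM_T * tp20.vmaxU)
        assert equilibrium_doc(tp20, params, phi_bound + 1e-9) is None
        assert equilibrium_doc(tp20, params, min(phi_bound + 0.01, 0.999)) is None

    def test_back_substitution(self, tp20, params, rng):
        phi_bound = 1.0 - tp20.dM_T / (tp20.gM_T * tp20.vmaxU)
        for _ in range(20):
            phi = rng.uniform(0, phi_bound * 0.999)
            D = equilibrium_doc(tp20, params, phi)
            lhs = (1 - phi) * tp20.gM_T * tp20.vmaxU * D / (tp20.KmU + D)
            assert lhs == pytest.approx(tp20.dM_T, rel=1e-12)


class TestSolveEquilibrium:
    def test_residual_below_tolerance(self, tp20, params, kernel):
        eq = solve_equilibrium(tp20, params, phi_star(tp20, params, kernel).phi_star)
        assert eq.feasible
        assert eq.residual < 1e-9

    def test_mass_balance_at_equilibrium(self, tp20, params, kernel):
        eq = solve_equilibrium(tp20, params, phi_star(tp20, params, kernel).phi_star)
        assert params.I == pytest.approx(
            params.eC * eq.state.C + params.eD * eq.state.D + eq.shr, rel=1e-9
        )

    def test_decay_rate_definition(self, tp20, params, kernel):
        eq = solve_equilibrium(tp20, params, phi_star(tp20, params, kernel).phi_star)
        assert eq.decay_rate == pytest.approx((params.I - params.eC * eq.state.C) / eq.state.C)

    def test_vanishing_allocation_is_infeasible(self, tp20, params):
        for phi in (0.0, 1e-8, 1e-5):
            assert not solve_equilibrium(tp20, params, phi).feasible

    def test_ode_integration_agrees(self, tp20, params, kernel):
        phi = phi_star(tp20, params, kernel).phi_star
        eq = solve_equilibrium(tp20, params, phi)
        assert eq.stable
        final = integrate_to_equilibrium(eq, tp20, params, phi)
        np.testing.assert_allclose(final, eq.state.as_array(), rtol=1e-6)

    def test_soc_strictly_decreasing_in_phi(self, tp20, params):
        phis = np.linspace(0.02, 0.5, 25)
        cs = [solve_equilibrium(tp20, params, p).state.C for p in phis]
        assert all(np.isfinite(cs))
        assert np.all(np.diff(cs) < 0)

    def test_invalid_phi_raises(self, tp20, params):
        with pytest.raises(ValueError, match="phi"):
            solve_equilibrium(tp20, params, -0.1)


class TestStability:
    def test_default_equilibrium_stable(self, tp20, params, kernel):
        eq = solve_equilibrium(tp20, params, phi_star(tp20, params, kernel).phi_star)
        assert eq.stable

    def test_classification_invariant_under_step_tightening(self, tp20, params, kernel):
        phi = phi_star(tp20, params, kernel).phi_star
        eq = solve_equilibrium(tp20, params, phi)
        coarse = jacobian_stability(eq, tp20, params, phi, rel_step=1e-5)
        fine = jacobian_stability(eq, tp20, params, phi, rel_step=1e-6)
        assert coarse == fine

    def test_infeasible_equilibrium_rejected(self, tp20, params):
        eq = solve_equilibrium(tp20, params, 1e-6)
        with pytest.raises(ValueError, match="feasible"):
            jacobian_stability(eq, tp20, params, 1e-6)

    @pytest.mark.parametrize("draw", range(5))
    def test_agrees_with_integration_oracle(self, draw, params, rng):
        rng = np.random.default_rng(900 + draw)
        p, tp, kern, phi, eq = draw_feasible_setup(rng, params, require_stable=False)
        x0 = eq.state.as_array() * 1.001  # small perturbation, linear regime
        final = integrate_to_equilibrium(eq, tp, p, phi, factors=(1.001, 1.001, 1.001, 1.001), t_end=5e5)
        returned = np.max(np.abs(final / eq.state.as_array() - 1.0)) < 5e-4
        assert returned == eq.stable


class TestFeasibleTraitRange:
    def test_empty_when_growth_infeasible(self, params):
        tp = TemperatureLocalParameters(
            vmaxD=1.0, KmD=1.0, vmaxU=params.dM, KmU=1.0, dM_T=params.dM, gM_T=0.5, T=5.0
        )
        assert feasible_trait_range(tp, params) is None

    def test_midpoint_feasible_ends_infeasible(self, tp20, params):
        rng_ = feasible_trait_range(tp20, params)
        assert rng_ is not None
        phi_min, phi_max = rng_
        mid = 0.5 * (phi_min + phi_max)
        eq_mid = solve_equilibrium(tp20, params, mid)
        assert eq_mid.feasible and eq_mid.stable
        assert not solve_equilibrium(tp20, params, phi_min / 2).feasible
        hi = min((phi_max + 1.0) / 2.0, 0.999999)
        assert not solve_equilibrium(tp20, params, hi).feasible

    def test_phi_max_monotone_in_vmaxu(self, tp20, params):
        from dataclasses import replace

        faster = replace(tp20, vmaxU=tp20.vmaxU * 2)
        lo = feasible_trait_range(tp20, params)
        hi = feasible_trait_range(faster, params)
        assert hi[1] > lo[1]
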
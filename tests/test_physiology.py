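"""Metabolic bookkeeping, state dynamics, and derived quantities."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from brainlife import (
    BodyState,
    asymptotic_skill,
    brain_metabolic_rate,
    dynamics_rhs,
    encephalization_quotient,
    extraction_efficiency,
    maintenance_rate,
    metabolic_breakdown,
    resting_rate,
)
from brainlife.physiology import NegativeGrowthWarning, effective_allocation


class TestBodyState:
    def test_rejects_negative_masses_and_empty_body(self):
        with pytest.raises(ValueError):
            BodyState(x_b=-0.1, x_r=0.1, x_s=0.1, x_k=0.0)
        with pytest.raises(ValueError):
            BodyState(x_b=0.0, x_r=0.0, x_s=0.0, x_k=1.0)


class TestMaintenanceRate:
    def test_single_tissue_linearity(self, toy_params):
        p = toy_params.replace(B_b=2.0)
        s = BodyState(x_b=1.0, x_r=1e-12, x_s=1e-12, x_k=0.0)
        assert maintenance_rate(s, p) == pytest.approx(2.0, abs=1e-9)

    def test_matches_independent_three_term_sum(self, toy_params, rng):
        for _ in range(20):
            x = rng.uniform(0.01, 10, size=3)
            s = BodyState(x_b=x[0], x_r=x[1], x_s=x[2], x_k=0.0)
            expected = sum(xi * bi for xi, bi in zip(
                x, (toy_params.B_b, toy_params.B_r, toy_params.B_s)))
            assert maintenance_rate(s, toy_params) == pytest.approx(expected, rel=1e-14)


class TestRestingRate:
    def test_zero_efficiency_releases_no_heat(self, toy_params):
        s = BodyState(x_b=1.0, x_r=1.0, x_s=1.0, x_k=0.0)
        assert resting_rate(s, 0.0, toy_params) == 0.0

    def test_linear_scaling_at_unit_exponent(self, toy_params):
        p = toy_params.replace(beta=1.0)
        s = BodyState(x_b=1.0, x_r=1.0, x_s=2.0, x_k=0.0)
        assert resting_rate(s, 1.0, p) == pytest.approx(p.K * 4.0)

    def test_power_law_arithmetic(self, toy_params):
        p = toy_params.replace(K=2.0, beta=0.5)
        s = BodyState(x_b=2.0, x_r=1.0, x_s=1.0, x_k=0.0)  # x_B = 4
        assert resting_rate(s, 0.5, p) == pytest.approx(2.0 * 0.5 * 2.0)

    def test_efficiency_out_of_bounds_rejected(self, toy_params):
        s = BodyState(x_b=1.0, x_r=1.0, x_s=1.0, x_k=0.0)
        with pytest.raises(ValueError):
            resting_rate(s, 1.5, toy_params)


class TestDynamics:
    def test_unallocated_tissue_does_not_move(self, toy_params):
        s = BodyState(x_b=0.2, x_r=0.05, x_s=1.0, x_k=0.5, t=1.0)
        dx = dynamics_rhs(s, (0.0, 0.0, 1.0), toy_params)
        assert dx[0] == 0.0 and dx[1] == 0.0
        assert dx[2] != 0.0

    def test_skill_fixed_point_under_zero_growth(self, flatline_params):
        p = flatline_params
        s = BodyState(x_b=p.x_b0, x_r=p.x_r0, x_s=p.x_s0, x_k=p.x_k0, t=0.0)
        dx = dynamics_rhs(s, (0.0, 0.5, 0.5), p)
        # B_rest == B_maint by construction, so nothing moves, including skill
        assert np.allclose(dx, 0.0, atol=1e-14)

    def test_matches_independent_hand_evaluation(self, toy_params):
        # frozen expectation computed by hand from the defining relations:
        # e = x_k^2/(d + x_k^2), B_rest = K e x_B^beta, B_syn = B_rest - maint
        p = toy_params
        s = BodyState(x_b=0.2, x_r=0.05, x_s=1.5, x_k=1.0, t=2.0)
        u = (0.25, 0.25, 0.5)
        d = p.alpha * (1 - p.phi0 * np.exp(-p.phi_r * 2.0))
        e = 1.0 / (d + 1.0)
        B_rest = p.K * e * (1.75) ** p.beta
        B_maint = 0.2 * p.B_b + 0.05 * p.B_r + 1.5 * p.B_s
        B_syn = B_rest - B_maint
        expected = (
            0.25 * B_syn / p.E_b,
            0.25 * B_syn / p.E_r,
            0.5 * B_syn / p.E_s,
            (p.s_k * (0.2 * p.B_b + 0.25 * B_syn) - 1.0 * p.B_k) / p.E_k,
        )
        got = dynamics_rhs(s, u, p)
        assert got == pytest.approx(expected, rel=1e-13)

    def test_simplex_violation_rejected(self, toy_params):
        s = BodyState(x_b=0.2, x_r=0.05, x_s=1.5, x_k=1.0)
        with pytest.raises(ValueError):
            dynamics_rhs(s, (0.5, 0.5, 0.5), toy_params)
        with pytest.raises(ValueError):
            dynamics_rhs(s, (1.2, -0.2, 0.0), toy_params)

    def test_negative_growth_warns_and_shrinks(self, toy_params):
        # huge body, tiny efficiency: maintenance dwarfs intake
        p = toy_params.replace(alpha=50.0)
        s = BodyState(x_b=5.0, x_r=5.0, x_s=5.0, x_k=0.01, t=30.0)
        with pytest.warns(NegativeGrowthWarning):
            dx = dynamics_rhs(s, (0.0, 0.0, 1.0), p)
        assert dx[2] < 0

    def test_energy_conservation_identity_exact(self, toy_params, rng):
        p = toy_params
        E = np.array([p.E_b, p.E_r, p.E_s])
        for _ in range(40):
            x = rng.uniform(0.01, 5, size=3)
            u = rng.dirichlet((1.0, 1.0, 1.0))
            s = BodyState(x_b=x[0], x_r=x[1], x_s=x[2],
                          x_k=rng.uniform(0, 3), t=rng.uniform(0, p.T))
            mb = metabolic_breakdown(s, u, p, warn_negative=False)
            dx = dynamics_rhs(s, u, p, warn_negative=False)
            assert np.dot(dx[:3], E) == pytest.approx(mb.B_syn, rel=1e-10, abs=1e-12)
            assert mb.B_rest == pytest.approx(mb.B_maint + mb.B_syn, rel=1e-12)

    def test_growth_rate_mass_sensitivity_matches_analytic_form(self, toy_params):
        # d(B_rest - B_maint)/dx_i = K e beta x_B^(beta-1) - B_i
        p = toy_params
        base = dict(x_b=0.3, x_r=0.1, x_s=2.0, x_k=1.2, t=4.0)
        e = extraction_efficiency(base["x_k"], base["t"], p)
        x_B = base["x_b"] + base["x_r"] + base["x_s"]
        h = 1e-7
        for tissue, B_i in (("x_b", p.B_b), ("x_r", p.B_r), ("x_s", p.B_s)):
            up = dict(base);  up[tissue] += h
            dn = dict(base);  dn[tissue] -= h
            def b_syn(kw):
                s = BodyState(**kw)
                mb = metabolic_breakdown(s, (0, 0, 1), p, warn_negative=False)
                return mb.B_syn
            fd = (b_syn(up) - b_syn(dn)) / (2 * h)
            analytic = p.K * e * p.beta * x_B ** (p.beta - 1) - B_i
            assert fd == pytest.approx(analytic, rel=1e-5)


class TestEffectiveAllocation:
    def test_identity_when_masses_positive_or_growth_positive(self):
        u = np.array([0.2, 0.3, 0.5])
        assert np.array_equal(effective_allocation(u, (1, 1, 1), (5, 5, 5), -10.0), u)
        assert np.array_equal(effective_allocation(u, (0, 1, 1), (5, 5, 5), +10.0), u)

    def test_dead_tissue_share_redistributed_by_stored_energy(self):
        u = np.array([0.0, 0.0, 1.0])
        out = effective_allocation(u, (2.0, 1.0, 0.0), (5.0, 10.0, 5.0), -10.0)
        assert out.sum() == pytest.approx(1.0)
        assert out[2] == 0.0
        # weights x*E: brain 10, repro 10 -> equal split
        assert out[0] == pytest.approx(0.5) and out[1] == pytest.approx(0.5)


class TestDerivedQuantities:
    def test_brain_metabolic_rate_adult_limit(self, toy_params):
        assert brain_metabolic_rate(1.3, 0.0, toy_params) == pytest.approx(1.3 * toy_params.B_b)
        assert brain_metabolic_rate(0.0, 0.0, toy_params) == 0.0
        expected = 0.7 * toy_params.B_b + 0.02 * toy_params.E_b
        assert brain_metabolic_rate(0.7, 0.02, toy_params) == pytest.approx(expected)

    def test_asymptotic_skill_formula_and_degenerate_cost(self, toy_params):
        p = toy_params.replace(s_k=0.5, B_b=40.0, B_k=20.0)
        assert asymptotic_skill(1.0, p) == pytest.approx(1.0)
        assert asymptotic_skill(0.0, p) == 0.0

    def test_skill_ode_converges_to_asymptote(self, toy_params):
        # with brain mass fixed and no brain growth allocation the skill ODE
        # is linear; its long-run limit must equal the closed-form asymptote
        p = toy_params
        x_b = 0.8
        target = asymptotic_skill(x_b, p)
        sol = solve_ivp(
            lambda t, y: [(p.s_k * x_b * p.B_b - y[0] * p.B_k) / p.E_k],
            (0, 400), [0.0], rtol=1e-10, atol=1e-12)
        assert sol.y[0, -1] == pytest.approx(target, rel=1e-6)

    def test_encephalization_quotient_of_observed_human(self):
        assert round(encephalization_quotient(1.31, 51.1), 2) == 5.87

    def test_encephalization_quotient_definition_normalizes_to_one(self):
        x_B = 40.0
        x_b = 11.22e-3 * x_B**0.76
        assert encephalization_quotient(x_b, x_B) == pytest.approx(1.0, rel=1e-12)

    def test_encephalization_quotient_direct_arithmetic(self):
        assert encephalization_quotient(1.53, 67.79) == pytest.approx(5.53, abs=0.005)

    def test_encephalization_quotient_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            encephalization_quotient(0.0, 50.0)
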
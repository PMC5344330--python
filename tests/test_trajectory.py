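"""Control representation and forward integration."""

import math

import numpy as np
import pytest

from brainlife import (
    ControlStrategy,
    IntegrationOptions,
    dynamics_rhs,
    evaluate_control,
    integrate,
)
from brainlife.physiology import BodyState
from brainlife._engine import BatchEvaluator


class TestControlStrategy:
    def test_mesh_must_start_at_zero_and_increase(self):
        with pytest.raises(ValueError):
            ControlStrategy(mesh=[1.0, 2.0], values=[[0, 0, 1]])
        with pytest.raises(ValueError):
            ControlStrategy(mesh=[0.0, 2.0, 2.0], values=[[0, 0, 1], [0, 0, 1]])

    def test_triples_must_lie_on_the_simplex(self):
        with pytest.raises(ValueError):
            ControlStrategy(mesh=[0.0, 1.0], values=[[0.5, 0.5, 0.1]])
        with pytest.raises(ValueError):
            ControlStrategy(mesh=[0.0, 1.0], values=[[1.2, -0.2, 0.0]])
        # within 1e-9 tolerance is accepted
        ControlStrategy(mesh=[0.0, 1.0], values=[[0.5, 0.25, 0.25 + 4e-10]])

    def test_single_interval_is_constant_everywhere(self):
        c = ControlStrategy.constant((0.2, 0.3, 0.5), 10.0)
        for t in [0.0, 3.3, 10.0]:
            assert evaluate_control(c, t) == pytest.approx([0.2, 0.3, 0.5])

    def test_right_continuity_at_interior_nodes(self):
        c = ControlStrategy(mesh=[0.0, 5.0, 10.0],
                            values=[[1, 0, 0], [0, 1, 0]])
        assert evaluate_control(c, 0.0) == pytest.approx([1, 0, 0])
        assert evaluate_control(c, 4.999) == pytest.approx([1, 0, 0])
        # exactly at the node: the succeeding interval's value
        assert evaluate_control(c, 5.0) == pytest.approx([0, 1, 0])
        assert evaluate_control(c, 10.0) == pytest.approx([0, 1, 0])

    def test_age_outside_domain_rejected(self):
        c = ControlStrategy.constant((0, 0, 1), 10.0)
        with pytest.raises(ValueError):
            c(-0.5)
        with pytest.raises(ValueError):
            c(10.5)

    def test_json_round_trip(self, tmp_path):
        c = ControlStrategy(mesh=[0.0, 2.5, 10.0], values=[[0.1, 0.2, 0.7], [0, 1, 0]])
        path = tmp_path / "c.json"
        c.to_json(path)
        d = ControlStrategy.from_json(path)
        assert np.array_equal(c.mesh, d.mesh)
        assert np.array_equal(c.values, d.values)
        assert d.interpolation == "constant"

    def test_linear_interpolation_between_nodes(self):
        c = ControlStrategy(mesh=[0.0, 10.0], values=[[1, 0, 0], [0, 1, 0]],
                            interpolation="linear")
        assert c(5.0) == pytest.approx([0.5, 0.5, 0.0])


class TestIntegrate:
    def test_flatline_parameters_hold_states_constant(self, flatline_params):
        p = flatline_params
        c = ControlStrategy.constant((0.2, 0.3, 0.5), p.T)
        traj = integrate(p, c)
        for series, x0 in [(traj.x_b, p.x_b0), (traj.x_r, p.x_r0),
                           (traj.x_s, p.x_s0), (traj.x_k, p.x_k0)]:
            assert np.allclose(series, x0, rtol=1e-8, atol=1e-10)

    def test_initial_state_is_the_newborn_state(self, toy_params):
        c = ControlStrategy.constant((0.1, 0.2, 0.7), toy_params.T)
        traj = integrate(toy_params, c)
        assert traj.x_b[0] == pytest.approx(toy_params.x_b0)
        assert traj.x_r[0] == pytest.approx(toy_params.x_r0)
        assert traj.x_s[0] == pytest.approx(toy_params.x_s0)
        assert traj.x_k[0] == pytest.approx(toy_params.x_k0)

    def test_single_growing_tissue_matches_exponential_solution(self, flatline_params):
        # beta = 1, efficiency pinned at 1, only soma present and allocated:
        # xdot_s = (K - B_s) x_s / E_s  up to the negligible other tissues
        p = flatline_params.replace(
            x_b0=1e-12, x_r0=1e-12, x_k0=0.0, gamma=0.0,
            K=3.0, B_s=2.0, E_s=5.0, B_k=1.0, E_k=1.0, s_k=0.0)
        c = ControlStrategy.constant((0.0, 0.0, 1.0), p.T)
        traj = integrate(p, c)
        rate = (p.K - p.B_s) / p.E_s
        expected = p.x_s0 * np.exp(rate * traj.t)
        assert np.allclose(traj.x_s, expected, rtol=1e-6)

    def test_unallocated_reproductive_tissue_keeps_newborn_mass(self, toy_params):
        p = toy_params
        c = ControlStrategy.constant((0.1, 0.0, 0.9), p.T)
        traj = integrate(p, c)
        assert np.allclose(traj.x_r, p.x_r0, rtol=1e-9)
        expected_r0 = p.C * p.f0 * p.x_r0 * (1 - math.exp(-p.mu * p.T)) / p.mu
        assert traj.R0 == pytest.approx(expected_r0, rel=1e-7)

    def test_metabolic_partition_holds_pointwise(self, toy_params):
        c = ControlStrategy.constant((0.2, 0.2, 0.6), toy_params.T)
        traj = integrate(toy_params, c)
        assert np.allclose(traj.B_rest, traj.B_maint + traj.B_syn, rtol=1e-12)

    def test_energy_conservation_identity_on_reporting_grid(self, toy_params):
        p = toy_params
        c = ControlStrategy.uniform_mesh(
            np.array([[0.3, 0.0, 0.7], [0.1, 0.3, 0.6], [0.0, 1.0, 0.0]]), p.T)
        traj = integrate(p, c)
        E = np.array([p.E_b, p.E_r, p.E_s])
        for i in range(0, traj.t.size, 97):
            s = BodyState(x_b=traj.x_b[i], x_r=max(traj.x_r[i], 0),
                          x_s=traj.x_s[i], x_k=traj.x_k[i], t=traj.t[i])
            dx = dynamics_rhs(s, traj.u[i], p, warn_negative=False)
            assert np.dot(dx[:3], E) == pytest.approx(
                traj.B_syn[i], rel=1e-8, abs=1e-8)

    def test_halving_tolerances_leaves_r0_converged(self, toy_params):
        c = ControlStrategy.uniform_mesh(
            np.array([[0.3, 0.0, 0.7], [0.0, 0.6, 0.4]]), toy_params.T)
        r0_a = integrate(toy_params, c, IntegrationOptions()).R0
        r0_b = integrate(toy_params, c,
                         IntegrationOptions(rtol=5e-9, atol=5e-11)).R0
        assert abs(r0_b - r0_a) / abs(r0_a) < 1e-6

    def test_mesh_must_span_the_parameterized_lifespan(self, toy_params):
        c = ControlStrategy.constant((0, 0, 1), toy_params.T - 1.0)
        with pytest.raises(ValueError):
            integrate(toy_params, c)

    def test_exact_fecundity_mode_carries_offspring_state(self, toy_params):
        from brainlife import OffspringAccounting, fecundity_exact

        p = toy_params
        c = ControlStrategy.constant((0.0, 0.3, 0.7), p.T)
        o = OffspringAccounting(s_o=0.5, E_o=4.0, B_o=0.0)
        traj = integrate(p, c, IntegrationOptions(exact_fecundity=o))
        assert traj.x_o is not None
        assert traj.x_o[0] == pytest.approx(0.0)
        assert np.all(np.diff(traj.x_o) >= -1e-12)
        # post-hoc offspring accounting on the same trajectory agrees (the
        # post-hoc route interpolates B_rest_r linearly on the reporting grid,
        # so agreement is limited by that grid, not by the integrators)
        _, x_o_ref = fecundity_exact(traj, o, p)
        assert np.allclose(traj.x_o, x_o_ref, rtol=1e-3, atol=1e-8)

    def test_csv_export_has_declared_columns(self, toy_params, tmp_path):
        import pandas as pd

        c = ControlStrategy.constant((0.1, 0.3, 0.6), toy_params.T)
        traj = integrate(toy_params, c)
        path = traj.to_csv(tmp_path / "traj.csv")
        df = pd.read_csv(path, comment="#")
        assert list(df.columns) == ["age", "x_b", "x_r", "x_s", "x_k",
                                    "e", "B_rest", "B_maint", "B_syn"]
        assert df["age"].iloc[-1] == pytest.approx(toy_params.T)
        assert df["x_b"].iloc[0] == pytest.approx(toy_params.x_b0)


class TestEngineConsistency:
    def test_batched_engine_agrees_with_adaptive_integrator(self, toy_params, rng):
        # mild environment so random draws stay away from the shrink-to-zero
        # corner, where flooring semantics make the two integrators diverge
        p = toy_params.replace(alpha=0.05)
        mesh = np.linspace(0, p.T, 9)
        U = rng.dirichlet((1.0, 1.0, 1.0), size=(6, 8))
        # fine fixed steps: flooring at the shrink-to-zero corner reduces the
        # scheme to first order, so convergence there needs small dt
        ev = BatchEvaluator(p, mesh, dt_max=0.005)
        r0_engine = ev.evaluate(U)
        for i in range(U.shape[0]):
            c = ControlStrategy(mesh=mesh, values=U[i])
            r0_ref = integrate(p, c).R0
            assert r0_engine[i] == pytest.approx(r0_ref, rel=2e-4)

    def test_engine_batch_rows_are_independent(self, toy_params):
        # a row's result must not depend on what else is in the batch
        p = toy_params
        mesh = np.linspace(0, p.T, 5)
        u_a = np.full((4, 3), [0.2, 0.3, 0.5])
        u_b = np.full((4, 3), [0.0, 0.8, 0.2])
        ev = BatchEvaluator(p, mesh)
        both = ev.evaluate(np.stack([u_a, u_b]))
        alone = ev.evaluate(u_a[None])
        # same step schedule is forced for comparisons inside one batch; for
        # this check use the identical pair to guarantee the schedule matches
        pair = ev.evaluate(np.stack([u_a, u_a]))
        assert pair[0] == pair[1]
        assert both[0] == pytest.approx(alone[0], rel=1e-6)
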
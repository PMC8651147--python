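"""Transcription correctness: feasibility, oracle equivalence,
refinement stability and variant behavior."""
import numpy as np
import pytest

import pogo
from pogo import _kernels
from pogo.collocation import _VARS, _build_nlp, resample_warm_start
from pogo.dynamics import BodyState, stance_derivatives
from pogo.params import GaitTask, ModelParams, TranscriptionConfig


class TestKernelConsistency:
    def test_generated_dynamics_match_reference_implementation(self):
        """The generated normalized kernels and the plain SI
        implementation in pogo.dynamics are independent encodings of the
        same model; they must agree after rescaling."""
        p = ModelParams.nominal()
        sc = p.scales
        rng = np.random.default_rng(7)
        for _ in range(20):
            xn, yn = rng.uniform(-0.4, 0.4), rng.uniform(0.6, 0.98)
            vxn, vyn = rng.uniform(0, 1.5), rng.uniform(-1, 1)
            qn, q1n, q2n = rng.uniform(-0.05, 0.05), rng.uniform(-0.3, 0.3), 0.1
            un = 2.0
            out = _kernels.dyn(xn, yn, vxn, vyn, qn, q1n, q2n, un,
                               p.k_norm, 2 * p.zeta * np.sqrt(p.k_norm),
                               p.epsilon, p.eta_pos, p.eta_neg, 1e-9, 1e-6)
            s = BodyState(xn * sc.L, yn * sc.L, vxn * sc.speed,
                          vyn * sc.speed, qn * sc.L, q1n * sc.speed,
                          q2n * sc.g)
            ds = stance_derivatives(s, un * sc.g / sc.time, p)
            # accelerations, normalized
            assert out[2] == pytest.approx(ds[2] / sc.g, rel=1e-9, abs=1e-9)
            assert out[3] == pytest.approx(ds[3] / sc.g, rel=1e-9, abs=1e-9)


class TestConvergedSolution:
    def test_feasibility_contract(self, nominal_solution):
        """Defects, force positivity, leg-length cap and periodicity all
        within solver tolerance."""
        sol = nominal_solution
        assert sol.converged
        assert sol.diagnostics["constr_violation"] < 1e-6
        p = sol.params
        assert np.all(sol.grf[1] >= -1e-6 * p.M * p.g)
        assert sol.L_l.max() <= p.L * (1 + 1e-8)
        assert sol.t_stance + sol.t_flight == pytest.approx(sol.task.T,
                                                            rel=1e-9)

    def test_unloaded_spring_at_contact_boundaries(self, nominal_solution):
        assert nominal_solution.delta[0] == pytest.approx(0.0, abs=1e-8)
        assert nominal_solution.delta[-1] == pytest.approx(0.0, abs=1e-8)

    def test_periodicity_through_flight_and_collision(self, nominal_solution):
        sol = nominal_solution
        p, task = sol.params, sol.task
        vin = sol.touchdown_incoming_velocity
        assert sol.vx_b[0] == pytest.approx((1 - p.CF) * vin[0], rel=1e-6)
        assert sol.vy_b[0] == pytest.approx((1 - p.CF) * vin[1], rel=1e-6)
        x_fl = sol.x_b[-1] + vin[0] * sol.t_flight
        assert x_fl - sol.x_b[0] == pytest.approx(task.s, rel=1e-6)

    def test_stationarity_of_the_optimum(self, nominal_solution,
                                         default_config):
        """Re-solving from slightly perturbed warm starts does not find
        a meaningfully lower objective (local optimality)."""
        rng = np.random.default_rng(11)
        z = nominal_solution.z_norm
        for _ in range(2):
            zp = z + 1e-4 * rng.standard_normal(z.size)
            sol2 = pogo.solve_stance(nominal_solution.params,
                                     nominal_solution.task,
                                     default_config, warm_start=zp)
            assert sol2.E >= nominal_solution.E * (1 - 2e-3)

    def test_mesh_refinement_stability(self, nominal_solution,
                                       nominal_params):
        """Doubling the node count changes the objective by < 1%."""
        cfg2 = TranscriptionConfig(n_starts=1, n_nodes=60)
        sol2 = pogo.solve_stance(nominal_params, GaitTask(v=3.0, f=2.94),
                                 cfg2, warm_start=nominal_solution)
        assert sol2.E == pytest.approx(nominal_solution.E, rel=1e-2)

    def test_solver_is_deterministic(self, fast_solution, nominal_params,
                                     fast_config):
        """Identical inputs reproduce the solution bit-for-bit."""
        again = pogo.solve_stance(nominal_params, GaitTask(v=3.0, f=2.94),
                                  fast_config)
        assert np.array_equal(again.z_norm, fast_solution.z_norm)

    def test_scaling_invariance(self, nominal_solution):
        """Solving is scale-free: the solution dimensionalized from the
        normalized NLP vector round-trips exactly, and re-solving the
        same task under different base units agrees to solver tolerance
        in normalized terms."""
        sol = nominal_solution
        sc = sol.params.scales
        S, ts = np.asarray(sol.z_norm[:-1]).reshape(-1, _VARS), sol.z_norm[-1]
        # round trip normalized -> SI -> normalized is the identity
        assert np.allclose(sol.x_b / sc.L, S[:, 0], rtol=0, atol=1e-14)
        assert np.allclose(sol.vy_b / sc.speed, S[:, 3], rtol=0, atol=1e-14)
        assert sol.t_stance / sc.time == pytest.approx(ts, rel=1e-14)
        # a dynamically similar body (different M, L) yields the same
        # normalized gait within solver tolerance
        sc_b = pogo.Scales(55.0, 9.81, 1.15)
        p_b = ModelParams(M=sc_b.M, g=sc_b.g, L=sc_b.L,
                          k=sol.params.k_norm * sc_b.stiffness)
        task_b = GaitTask(v=(3.0 / sc.speed) * sc_b.speed,
                          f=(2.94 * sc.time) / sc_b.time)
        sol_b = pogo.solve_stance(p_b, task_b,
                                  TranscriptionConfig(n_starts=1))
        assert sol_b.E / sc_b.energy == pytest.approx(
            sol.E / sc.energy, rel=1e-4)
        Sb = np.asarray(sol_b.z_norm[:-1]).reshape(-1, _VARS)
        assert np.allclose(Sb[:, :4], S[:, :4], atol=5e-4)


class TestConservativeLimit:
    def test_objective_vanishes_without_dissipation(self, fast_config):
        p = ModelParams.nominal(CF=0.0, zeta=0.0, epsilon=0.0)
        sol = pogo.solve_stance(p, GaitTask(v=3.0, f=2.94), fast_config)
        assert sol.E / p.scales.energy < 1e-3

    @pytest.mark.parametrize("k_norm", [25.0, 46.7, 90.0])
    def test_locked_actuator_transcription_matches_shooting(self, k_norm):
        """With the actuator frozen and no losses, the collocation
        solution must reproduce the shooting oracle's state trajectories
        (independent integration) to fine tolerance."""
        sc = pogo.Scales()
        p = ModelParams.nominal(k=k_norm * sc.stiffness, CF=0.0, zeta=0.0,
                                epsilon=0.0)
        task = GaitTask(v=3.0, f=2.94)
        cfg = TranscriptionConfig(n_starts=1, n_nodes=40)
        nlp = _build_nlp(p, task, cfg)
        # freeze the actuator chain: q = dq = ddq = u = 0
        orig = nlp.var_bounds

        def locked():
            lb, ub = orig()
            for j in (4, 5, 6, 7):
                lb[j::_VARS][:cfg.n_nodes] = 0.0
                ub[j::_VARS][:cfg.n_nodes] = 0.0
            return lb, ub

        nlp.var_bounds = locked
        gait = pogo.find_periodic_gait(k_norm, task.v / sc.speed,
                                       task.f * sc.time)
        z0 = np.zeros(nlp.nz)
        states = gait.sample(cfg.n_nodes)
        Z = np.zeros((cfg.n_nodes, _VARS))
        Z[:, :4] = states
        z0[:-1] = Z.ravel()
        z0[-1] = gait.t_stance
        res = nlp.solve(z0)
        assert res.constr_violation < 1e-6
        S, ts = nlp.split(res.x)
        assert ts == pytest.approx(gait.t_stance, abs=1e-3)
        # compare on scaled stance time to separate the O(h^2) stance-
        # duration discretization error from the trajectory shapes
        tau = np.linspace(0.0, 1.0, cfg.n_nodes)
        oracle = gait.stance.sol(tau * gait.t_stance).T
        rms = np.sqrt(np.mean((S[:, :4] - oracle) ** 2))
        assert rms < 1e-4


class TestVariants:
    def test_actuator_only_has_no_elastic_return(self, fast_config):
        p = ModelParams.nominal(variant="actuator_only", zeta=0.0, CF=0.0)
        sol = pogo.solve_stance(p, GaitTask(v=3.0, f=2.94), fast_config)
        a = pogo.energy_audit(sol)
        assert a.elastic_return_fraction < 0.05
        assert sol.converged

    def test_actuator_only_tends_impulsive_without_force_rate_cost(self):
        """Work-only cost drives the spring-free runner toward the
        impulsive limit: as the stiff-spring emulation sharpens, the
        optimal stance shrinks toward an instantaneous impulse while the
        cost does not increase."""
        p = ModelParams.nominal(variant="actuator_only", zeta=0.0, CF=0.0,
                                epsilon=0.0)
        task = GaitTask(v=3.0, f=2.94)
        ts = []
        for k_emul in (200.0, 500.0, 1200.0):
            cfg = TranscriptionConfig(n_starts=1, n_nodes=20,
                                      stiff_emulation=k_emul)
            sol = pogo.solve_stance(p, task, cfg)
            ts.append(sol.t_stance)
        assert ts[0] > ts[1] > ts[2]

    def test_spring_mass_variant_returns_passive_gait(self, fast_config):
        p = ModelParams.nominal(variant="spring_mass", zeta=0.0, CF=0.0)
        sol = pogo.solve_stance(p, GaitTask(v=3.0, f=2.94), fast_config)
        assert sol.E == 0.0
        assert np.allclose(sol.q, 0.0)


class TestContinuation:
    def test_single_point_grid_matches_solve_stance(self, nominal_params,
                                                    fast_config,
                                                    fast_solution):
        out = pogo.continuation_sweep(
            [(nominal_params, GaitTask(v=3.0, f=2.94))], fast_config)
        assert len(out) == 1
        assert out[0].E == pytest.approx(fast_solution.E, rel=1e-3)

    def test_warm_start_resampling_round_trip(self, fast_solution):
        z48 = resample_warm_start(fast_solution, 48)
        assert z48.size == _VARS * 48 + 1
        assert z48[-1] == fast_solution.z_norm[-1]

    def test_failure_is_explicit(self, nominal_params, fast_config):
        with pytest.raises(pogo.SolveError) as err:
            # unreachable: speed beyond any admissible stance state
            pogo.solve_stance(nominal_params, GaitTask(v=15.0, f=1.1),
                              fast_config)
        assert err.value.diagnostics.get("attempts")
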
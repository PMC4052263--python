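"""Mass-action model: fixed points, dynamics, chain/network builders."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cernet as cn
from cernet.kinetics import jacobian, rhs

from conftest import random_params

GOLDEN = (np.sqrt(5) - 1) / 2  # fixed point of x = 1/(1+x)


class TestPairSteadyState:
    def test_decoupled_when_binding_off(self):
        p = cn.KineticParams(g_R=2.0, g_T=3.0, d_R=0.5, d_T=0.25, b=0.0)
        ss = cn.pair_steady_state(p)
        assert ss.R[0] == pytest.approx(4.0)
        assert ss.T[0] == pytest.approx(12.0)
        assert ss.C[0] == 0.0

    def test_catalytic_mirna_unaffected_by_target(self):
        p = cn.KineticParams(g_R=1.5, d_R=0.3, alpha=0.0, b=0.8)
        ss = cn.pair_steady_state(p)
        assert ss.R[0] == pytest.approx(1.5 / 0.3, rel=1e-12)
        # the target is still repressed below its unbound level
        assert ss.T[0] < p.g_T / p.d_T

    def test_symmetric_golden_ratio_fixed_point(self, golden_pair_params):
        ss = cn.pair_steady_state(golden_pair_params)
        assert ss.R[0] == pytest.approx(GOLDEN, abs=1e-12)
        assert ss.T[0] == pytest.approx(GOLDEN, abs=1e-12)
        assert ss.C[0] == pytest.approx(1 - GOLDEN, abs=1e-12)

    def test_rejects_nonpositive_degradation(self):
        with pytest.raises(ValueError):
            cn.pair_steady_state(cn.KineticParams(d_T=0.0))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_zeroes_the_rhs(self, seed):
        """The closed form is a true fixed point of the pair ODEs."""
        p = random_params(np.random.default_rng(seed))
        ss = cn.pair_steady_state(p)
        system = cn.build_chain(1, p)
        resid = rhs(system, ss.to_vector())
        assert np.max(np.abs(resid)) < 1e-9 * max(1.0, ss.to_vector().max())
        assert ss.to_vector().min() >= 0


class TestChainClosedForm:
    def test_symmetric_half_level_fixed_point(self):
        p = cn.KineticParams(g_R=1, g_T=1, d_R=1, d_T=1, d_C=1, u_C=0, b=1, alpha=1)
        R, T = cn.chain_steady_state_closed_form(p)
        assert R == pytest.approx(0.5, abs=1e-12)
        assert T == pytest.approx(0.5, abs=1e-12)

    def test_decoupled_when_binding_off(self):
        p = cn.KineticParams(b=0.0, g_R=2.0, d_R=0.4, g_T=1.0, d_T=0.2)
        R, T = cn.chain_steady_state_closed_form(p)
        assert (R, T) == (pytest.approx(5.0), pytest.approx(5.0))

    def test_catalytic_limit_is_continuous(self):
        p0 = cn.KineticParams(alpha=0.0)
        p1 = cn.KineticParams(alpha=1e-9)
        R0, T0 = cn.chain_steady_state_closed_form(p0)
        R1, T1 = cn.chain_steady_state_closed_form(p1)
        assert R0 == pytest.approx(R1, rel=1e-6)
        assert T0 == pytest.approx(T1, rel=1e-6)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_zeroes_the_circular_chain_rhs(self, seed):
        p = random_params(np.random.default_rng(seed))
        R, T = cn.chain_steady_state_closed_form(p)
        system = cn.build_chain(20, p, boundary="circular")
        C = p.b * R * T / (p.u_C + p.d_C)
        y = np.concatenate([np.full(20, R), np.full(20, T), np.full(40, C)])
        resid = rhs(system, y)
        assert np.max(np.abs(resid)) < 1e-9 * max(1.0, y.max())


class TestBuilders:
    def test_single_pair_chain_matches_pair_dynamics(self, default_params):
        system = cn.build_chain(1, default_params)
        assert system.n_mirna == system.n_mrna == system.n_edges == 1
        ss = cn.pair_steady_state(default_params)
        assert np.max(np.abs(rhs(system, ss.to_vector()))) < 1e-12

    def test_open_chain_structure(self, default_params):
        system = cn.build_chain(3, default_params)
        assert set(system.topology.mirnas) == {"R1", "R3", "R5"}
        assert set(system.topology.mrnas) == {"T0", "T2", "T4"}
        assert system.n_edges == 5  # R5's right neighbour T6 does not exist
        circ = cn.build_chain(3, default_params, boundary="circular")
        assert circ.n_edges == 6

    def test_circular_chain_is_two_regular(self, default_params):
        system = cn.build_chain(100, default_params, boundary="circular")
        degree = {}
        for r, t in system.topology.edges:
            degree[r] = degree.get(r, 0) + 1
            degree[t] = degree.get(t, 0) + 1
        assert set(degree.values()) == {2}

    def test_degree_proportional_star(self, default_params):
        topo = cn.BipartiteTopology(("R",), ("a", "b", "c"),
                                    (("R", "a"), ("R", "b"), ("R", "c")))
        system = cn.build_network(topo, default_params,
                                  generation_mode="degree_proportional", base_rate=2.0)
        assert system.g_R[0] == pytest.approx(6.0)
        assert np.all(system.g_T == 2.0)

    def test_uniform_mode_equalizes_generation(self, default_params):
        topo = cn.BipartiteTopology(("R",), ("a", "b"), (("R", "a"), ("R", "b")))
        system = cn.build_network(topo, default_params, base_rate=1.3)
        assert np.all(system.g_R == 1.3) and np.all(system.g_T == 1.3)

    def test_isolated_node_warns_under_degree_proportional(self, default_params):
        topo = cn.BipartiteTopology(("R",), ("a", "lonely"), (("R", "a"),))
        with pytest.warns(UserWarning, match="isolated"):
            system = cn.build_network(topo, default_params,
                                      generation_mode="degree_proportional")
        assert system.g_T[list(topo.mrnas).index("lonely")] == 0.0

    def test_fig2_like_subnetwork_shape(self):
        topo = cn.fig2_like_subnetwork()
        assert len(topo.mirnas) == 15
        assert len(topo.mrnas) == 6

    def test_topology_rejects_within_side_edges(self):
        with pytest.raises(ValueError):
            cn.BipartiteTopology(("R1", "R2"), ("t",), (("R1", "R2"),))


class TestPerturb:
    def test_identity_and_knockout(self, default_params):
        system = cn.build_chain(2, default_params)
        same = cn.perturb_generation_rate(system, "T0", 1.0)
        assert np.array_equal(same.g_T, system.g_T)
        ko = cn.perturb_generation_rate(system, "R1", 0.0)
        assert ko.g_R[0] == 0.0
        assert system.g_R[0] > 0  # original untouched

    def test_unknown_node_raises(self, default_params):
        system = cn.build_chain(2, default_params)
        with pytest.raises(KeyError):
            cn.perturb_generation_rate(system, "nope", 0.5)


class TestDynamics:
    def test_zero_system_has_zero_derivative(self):
        p = cn.KineticParams(g_R=0, g_T=0)
        system = cn.build_chain(2, p)
        assert np.all(rhs(system, np.zeros(system.n_state)) == 0)

    def test_binding_only_conservation(self):
        """With no generation, degradation or unbinding, R_i + sum_j C_ij and
        T_j + sum_i C_ij are conserved along the trajectory."""
        p = cn.KineticParams(g_R=0, g_T=0, d_R=0, d_T=0, d_C=0, u_C=0, b=0.7)
        system = cn.build_chain(3, p)
        rng = np.random.default_rng(0)
        y0 = rng.uniform(0.2, 1.0, system.n_state)
        traj = cn.integrate(system, y0, 50.0)
        ei, ej = system.edge_mirna_idx, system.edge_mrna_idx
        nm, nt = system.n_mirna, system.n_mrna

        def totals(y):
            R, T, C = y[:nm], y[nm:nm + nt], y[nm + nt:]
            return (R + np.bincount(ei, weights=C, minlength=nm),
                    T + np.bincount(ej, weights=C, minlength=nt))

        ref_R, ref_T = totals(traj.states[0])
        end_R, end_T = totals(traj.states[-1])
        assert np.max(np.abs(end_R - ref_R)) < 1e-6
        assert np.max(np.abs(end_T - ref_T)) < 1e-6

    def test_uncoupled_target_relaxes_with_closed_form(self):
        p = cn.KineticParams(b=0.0, g_T=1.0, d_T=0.2)
        system = cn.build_chain(1, p)
        y0 = np.array([p.g_R / p.d_R, 0.0, 0.0])  # target starts empty
        t_eval = np.linspace(0, 30, 61)
        traj = cn.integrate(system, y0, 30.0, t_eval=t_eval)
        expected = (p.g_T / p.d_T) * (1 - np.exp(-p.d_T * t_eval))
        assert np.max(np.abs(traj.node_levels("T0") - expected)) < 1e-6

    def test_steady_start_stays_constant(self, default_params):
        system = cn.build_chain(4, default_params)
        ss = cn.steady_state(system)
        traj = cn.integrate(system, ss, 100.0)
        assert np.max(np.abs(traj.states - ss.to_vector())) < 1e-6

    def test_levels_stay_nonnegative(self, default_params):
        system = cn.build_chain(5, default_params)
        rng = np.random.default_rng(1)
        traj = cn.integrate(system, rng.uniform(0, 3, system.n_state), 200.0)
        assert traj.states.min() >= 0.0

    def test_rhs_dimension_mismatch(self, default_params):
        system = cn.build_chain(2, default_params)
        with pytest.raises(ValueError):
            rhs(system, np.zeros(3))

    def test_jacobian_matches_finite_differences(self, default_params):
        system = cn.build_chain(3, default_params)
        rng = np.random.default_rng(2)
        y = rng.uniform(0.1, 1.0, system.n_state)
        J = jacobian(system, y)
        eps = 1e-7
        for k in range(system.n_state):
            dy = np.zeros_like(y)
            dy[k] = eps
            col = (rhs(system, y + dy) - rhs(system, y - dy)) / (2 * eps)
            assert np.max(np.abs(J[:, k] - col)) < 1e-5


class TestSteadyState:
    def test_pair_agrees_with_closed_form(self, golden_pair_params):
        system = cn.build_chain(1, golden_pair_params)
        ss = cn.steady_state(system)
        assert ss.R[0] == pytest.approx(GOLDEN, abs=1e-9)

    def test_circular_chain_agrees_with_closed_form(self, default_params):
        R, T = cn.chain_steady_state_closed_form(default_params)
        system = cn.build_chain(30, default_params, boundary="circular")
        ss = cn.steady_state(system)
        assert np.max(np.abs(ss.R - R)) / R < 1e-6
        assert np.max(np.abs(ss.T - T)) / T < 1e-6

    def test_independent_of_initial_condition(self, default_params):
        system = cn.build_chain(10, default_params)
        a = cn.steady_state(system, state0=np.zeros(system.n_state))
        b = cn.steady_state(system, state0=np.full(system.n_state, 10.0))
        assert np.max(np.abs(a.to_vector() - b.to_vector())) < 1e-6

    def test_zero_generation_gives_empty_state(self):
        p = cn.KineticParams(g_R=0.0, g_T=0.0)
        system = cn.build_chain(3, p)
        ss = cn.steady_state(system)
        assert np.max(ss.to_vector()) < 1e-9

    def test_target_knockdown_sign_structure(self, default_params):
        """Lowering one target's generation rate raises every miRNA and
        lowers every other target at the new steady state."""
        system = cn.build_chain(5, default_params)
        ss0 = cn.steady_state(system)
        pert = cn.perturb_generation_rate(system, "T4", 0.5)
        ss1 = cn.steady_state(pert, state0=ss0)
        assert np.all(ss1.R > ss0.R)
        others = [j for j, t in enumerate(system.topology.mrnas) if t != "T4"]
        assert np.all(ss1.T[others] < ss0.T[others])


class TestResponseTime:
    def test_exponential_relaxation_half_life(self):
        p = cn.KineticParams(b=0.0, g_T=1.0, d_T=0.2)
        system = cn.build_chain(1, p)
        y0 = np.array([p.g_R / p.d_R, 0.0, 0.0])
        traj = cn.integrate(system, y0, 60.0, t_eval=np.linspace(0, 60, 601))
        t_half = cn.response_time(traj, "T0", 0.0, p.g_T / p.d_T)
        assert t_half == pytest.approx(np.log(2) / p.d_T, rel=1e-3)

    def test_source_normalizes_to_one(self, default_params):
        system = cn.build_chain(6, default_params)
        ss0 = cn.steady_state(system)
        pert = cn.perturb_generation_rate(system, "T0", 0.9)  # linear regime
        ss1 = cn.steady_state(pert, state0=ss0)
        traj = cn.integrate(pert, ss0, 600.0, t_eval=np.linspace(0, 600, 1201))
        from cernet.kinetics import relative_response_times
        rel = relative_response_times(traj, "T0", ss0, ss1, nodes=["T0", "R1", "T2"])
        assert rel["T0"] == pytest.approx(1.0)
        assert rel["R1"] >= 1.0 and rel["T2"] >= rel["R1"] - 1e-9

    def test_never_crossing_returns_nan(self, default_params):
        system = cn.build_chain(1, default_params)
        ss = cn.steady_state(system)
        traj = cn.integrate(system, ss, 10.0)
        with pytest.warns(UserWarning, match="never crosses"):
            t = cn.response_time(traj, "T0", ss.T[0], 5 * ss.T[0] + 1)
        assert np.isnan(t)
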
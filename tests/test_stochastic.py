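import numpy as np
import pytest

from mpsir import (AssociationModel, NodeInit, TimeGrid, estimate_marginals,
                   exponential_recovery, forward_equations_markov,
                   make_symmetric_graph, markovian_kernel, node_marginals,
                   sample_individual, simulate_epidemic, solve_message_system)
from mpsir.stochastic import _percolate


def markov_model(beta=1.0, gamma=1.0):
    return AssociationModel(pi=0.0, beta_base=beta, beta_slow=beta,
                            gamma_base=gamma, gamma_fast=gamma)


SHOCK = AssociationModel(pi=0.5, beta_base=1.0, beta_slow=0.5,
                         gamma_base=1.0, gamma_fast=2.0)


class TestSampleIndividual:
    def test_pure_markovian_marginals(self, rng):
        draws = np.array([sample_individual(markov_model(), 2, rng).mu
                          for _ in range(2000)])
        assert np.mean(draws) == pytest.approx(1.0, abs=0.1)

    def test_initial_status_probabilities(self, rng):
        ys = [sample_individual(markov_model(), 1, rng, z=0.5, y=0.3).Y
              for _ in range(3000)]
        ys = np.array(ys)
        assert np.mean(ys == 2) == pytest.approx(0.5, abs=0.04)
        assert np.mean(ys == 3) == pytest.approx(0.3, abs=0.04)

    def test_association_positive_correlations(self):
        from mpsir.stochastic import _shock_draws
        rng = np.random.default_rng(7)
        mu, omega = _shock_draws(SHOCK, 100_000, 1, np.array([2]), rng)
        mu, om = mu[:, 0], omega[0]
        for a, b in ((-mu, om[:, 0]), (-mu, om[:, 1]), (om[:, 0], om[:, 1])):
            assert np.corrcoef(a, b)[0, 1] > 0

    def test_transmission_probability_closed_form(self):
        from mpsir.stochastic import _shock_draws
        rng = np.random.default_rng(11)
        n = 100_000
        mu, omega = _shock_draws(SHOCK, n, 1, np.array([1]), rng)
        p_hat = np.mean(omega[0][:, 0] < mu[:, 0])
        # p = pi b1/(b1+g1) + (1-pi) b0/(b0+g0) = 0.35
        assert abs(p_hat - 0.35) <= 3 * np.sqrt(0.35 * 0.65 / n)


class TestPercolation:
    def test_deterministic_single_edge(self):
        net = make_symmetric_graph("path", length=2)
        Y = np.array([[1, 2]])
        mu = np.array([[np.inf, np.inf]])
        omega = np.array([[0.5, 9.9]])  # edges (0->1), (1->0)
        T = _percolate(net, Y, mu, omega, np.array([0, 1]), np.array([1, 0]))
        np.testing.assert_allclose(T, [[0.0, 0.5]])

    def test_blocked_when_recovery_precedes_contact(self):
        net = make_symmetric_graph("path", length=2)
        Y = np.array([[1, 2]])
        mu = np.array([[0.4, np.inf]])  # recovers before omega = 0.5
        omega = np.array([[0.5, 9.9]])
        T = _percolate(net, Y, mu, omega, np.array([0, 1]), np.array([1, 0]))
        assert T[0, 1] == np.inf

    def test_exhaustive_shortest_paths_on_path4(self):
        # hand-computable chain: infection times accumulate along the path
        net = make_symmetric_graph("path", length=4)
        src = np.array([0, 1, 1, 2, 2, 3])
        dst = np.array([1, 0, 2, 1, 3, 2])
        for w01, w12, w23 in [(0.2, 0.3, 0.1), (1.0, 0.5, 2.0)]:
            Y = np.array([[1, 2, 2, 2]])
            mu = np.full((1, 4), np.inf)
            omega = np.array([[w01, 9., w12, 9., w23, 9.]])
            T = _percolate(net, Y, mu, omega, src, dst)
            np.testing.assert_allclose(
                T, [[0.0, w01, w01 + w12, w01 + w12 + w23]])

    def test_all_initially_infected(self, rng):
        net = make_symmetric_graph("cycle", length=3)
        real = simulate_epidemic(net, markov_model(),
                                 NodeInit.homogeneous(3, 0.0, 0.0), rng)
        np.testing.assert_array_equal(real.infection_time, 0.0)
        assert real.final_size == 0  # no initially susceptible node

    def test_vaccinated_never_infected(self, rng):
        net = make_symmetric_graph("complete", m=4)
        init = NodeInit(z=np.zeros(4) + 1e-9,
                        y=np.ones(4) - 1e-9)
        real = simulate_epidemic(net, markov_model(), init, rng)
        assert np.all(np.isinf(real.infection_time))


class TestEstimateMarginals:
    def test_isolated_node_exponential_decay(self):
        net = make_symmetric_graph("path", length=1)
        grid = TimeGrid(t_max=3.0, dt=0.05)
        reps = 20_000
        est = estimate_marginals(net, markov_model(),
                                 NodeInit.homogeneous(1, 0.0, 0.0),
                                 grid, reps, seed=3)
        exact = np.exp(-grid.times)
        se = np.sqrt(exact * (1 - exact) / reps) + 1e-12
        assert np.max(np.abs(est.P_I[0] - exact) / (4 * se)) <= 1.0

    def test_same_seed_reproducible(self, path3, coarse_grid):
        init = NodeInit.homogeneous(3, 0.9, 0.0)
        a = estimate_marginals(path3, markov_model(), init, coarse_grid,
                               500, seed=5)
        b = estimate_marginals(path3, markov_model(), init, coarse_grid,
                               500, seed=5)
        np.testing.assert_array_equal(a.P_S, b.P_S)
        np.testing.assert_array_equal(a.P_R, b.P_R)

    def test_states_partition_exactly(self, path3, coarse_grid):
        init = NodeInit.homogeneous(3, 0.9, 0.0)
        est = estimate_marginals(path3, markov_model(), init, coarse_grid,
                                 300, seed=9)
        np.testing.assert_allclose(est.P_S + est.P_I + est.P_R, 1.0,
                                   atol=1e-12)

    def test_matches_tree_message_solution(self, path3):
        # reduced-replicate version of the simulator/solver cross-check,
        # at the widened 4-sigma band appropriate for 10^4 replicates
        grid = TimeGrid(t_max=3.0, dt=0.05)
        init = NodeInit.homogeneous(3, 0.9, 0.0)
        reps = 10_000
        est = estimate_marginals(path3, markov_model(), init, grid, reps,
                                 seed=17)
        sol = solve_message_system(path3, init, markovian_kernel(1.0, 1.0),
                                   grid)
        mes = node_marginals(sol, init, exponential_recovery(1.0))
        se = np.sqrt(mes.S * (1 - mes.S) / reps) + 1e-12
        assert np.max(np.abs(est.P_S - mes.S) / (4 * se)) <= 1.0


class TestForwardEquations:
    def test_single_node_closed_form(self):
        net = make_symmetric_graph("path", length=1)
        grid = TimeGrid(t_max=2.0, dt=0.02)
        init = NodeInit.homogeneous(1, 0.3, 0.2)
        traj = forward_equations_markov(net, 1.0, 1.5, init, grid)
        t = grid.times
        np.testing.assert_allclose(traj.I[0], 0.5 * np.exp(-1.5 * t),
                                   atol=1e-9)
        np.testing.assert_allclose(traj.S[0], 0.3, atol=1e-12)

    def test_disconnected_nodes_factorize(self, tmp_path):
        p = tmp_path / "edges.csv"
        p.write_text("u,v\n")
        from mpsir import load_edge_list
        net = load_edge_list(p, node_count=2)
        grid = TimeGrid(t_max=1.0, dt=0.1)
        init = NodeInit(z=np.array([0.5, 0.7]), y=np.array([0.1, 0.0]))
        traj = forward_equations_markov(net, 2.0, 1.0, init, grid)
        single = make_symmetric_graph("path", length=1)
        for i in range(2):
            ref = forward_equations_markov(
                single, 2.0, 1.0,
                NodeInit(z=init.z[[i]], y=init.y[[i]]), grid)
            np.testing.assert_allclose(traj.I[i], ref.I[0], atol=1e-10)

    def test_rejects_large_state_space(self, coarse_grid):
        net = make_symmetric_graph("cycle", length=11)
        init = NodeInit.homogeneous(11, 0.9, 0.0)
        with pytest.raises(ValueError, match="10 nodes"):
            forward_equations_markov(net, 1.0, 1.0, init, coarse_grid)

    def test_simulator_agrees_with_master_equation(self, path3):
        grid = TimeGrid(t_max=2.0, dt=0.1)
        init = NodeInit.homogeneous(3, 0.9, 0.0)
        reps = 20_000
        est = estimate_marginals(path3, markov_model(), init, grid, reps,
                                 seed=23)
        oracle = forward_equations_markov(path3, 1.0, 1.0, init, grid)
        for emp, exact in ((est.P_S, oracle.S), (est.P_I, oracle.I),
                           (est.P_R, oracle.R)):
            se = np.sqrt(exact * (1 - exact) / reps) + 1e-12
            assert np.max(np.abs(emp - exact) / (4 * se)) <= 1.0
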
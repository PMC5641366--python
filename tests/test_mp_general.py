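import numpy as np
import pytest

from mpsir import (NodeInit, TimeGrid, expected_epidemic_size,
                   exponential_recovery, forward_equations_markov,
                   make_symmetric_graph, markovian_kernel, node_marginals,
                   solve_message_system, tabulate, uniqueness_check,
                   verify_feasibility, zero_kernel, fixed_recovery_kernel)


class TestSolveMessageSystem:
    def test_zero_kernel_messages_stay_at_one(self, path3, coarse_grid,
                                              init_z09):
        sol = solve_message_system(path3, init_z09, zero_kernel(), coarse_grid)
        for vals in sol.F.values():
            np.testing.assert_array_equal(vals, 1.0)

    def test_all_initially_infected_gives_envelope(self, path3, coarse_grid,
                                                   unit_markovian):
        # z = y = 0: the product term vanishes and F = 1 - int_0^t f
        init = NodeInit.homogeneous(3, 0.0, 0.0)
        sol = solve_message_system(path3, init, unit_markovian, coarse_grid)
        _, cum = tabulate(unit_markovian, coarse_grid)
        for vals in sol.F.values():
            np.testing.assert_allclose(vals, 1.0 - cum, atol=1e-12)

    def test_tree_marginals_match_forward_oracle(self, path3, fine_grid,
                                                 init_z09, unit_markovian,
                                                 unit_recovery):
        sol = solve_message_system(path3, init_z09, unit_markovian, fine_grid)
        traj = node_marginals(sol, init_z09, unit_recovery)
        oracle = forward_equations_markov(path3, 1.0, 1.0, init_z09, fine_grid)
        assert np.max(np.abs(traj.S[1] - oracle.S[1])) <= 2e-3

    def test_heterogeneous_directional_kernels(self, coarse_grid):
        # one-way transmission: node 1 can never be infected by node 0
        net = make_symmetric_graph("path", length=2)
        init = NodeInit.homogeneous(2, 0.5, 0.0)
        kernels = {(0, 1): markovian_kernel(1.0, 1.0),  # 1 -> 0 transmits
                   (1, 0): zero_kernel()}               # 0 -> 1 silenced
        sol = solve_message_system(net, init, kernels, coarse_grid)
        np.testing.assert_array_equal(sol.F[(1, 0)], 1.0)
        assert sol.F[(0, 1)][-1] < 1.0

    def test_message_count_is_twice_edges(self, triangle, coarse_grid):
        init = NodeInit.homogeneous(3, 0.9, 0.0)
        sol = solve_message_system(triangle, init, markovian_kernel(1, 1),
                                   coarse_grid)
        assert len(sol.F) == 2 * triangle.edge_count


class TestNodeMarginals:
    def test_isolated_node_closed_form(self, fine_grid):
        net = make_symmetric_graph("path", length=1)
        init = NodeInit(z=np.array([0.7]), y=np.array([0.1]))
        sol = solve_message_system(net, init, zero_kernel(), fine_grid)
        traj = node_marginals(sol, init, exponential_recovery(1.0))
        t = fine_grid.times
        np.testing.assert_allclose(traj.S[0], 0.7, atol=1e-12)
        np.testing.assert_allclose(traj.R[0], 0.1 + 0.2 * (1 - np.exp(-t)),
                                   atol=1e-6)

    def test_initial_state_is_z_i_y(self, path3, coarse_grid, unit_markovian,
                                    unit_recovery):
        init = NodeInit.homogeneous(3, 0.8, 0.1)
        sol = solve_message_system(path3, init, unit_markovian, coarse_grid)
        traj = node_marginals(sol, init, unit_recovery)
        np.testing.assert_allclose(traj.S[:, 0], 0.8, atol=1e-12)
        np.testing.assert_allclose(traj.I[:, 0], 0.1, atol=1e-12)
        np.testing.assert_allclose(traj.R[:, 0], 0.1, atol=1e-12)

    def test_star_centre_is_leaf_message_cubed(self, coarse_grid,
                                               unit_markovian, unit_recovery):
        star = make_symmetric_graph("star", leaves=3)
        init = NodeInit.homogeneous(4, 0.9, 0.0)
        sol = solve_message_system(star, init, unit_markovian, coarse_grid)
        traj = node_marginals(sol, init, unit_recovery)
        F_leaf = sol.F[(0, 1)]  # identical leaves: one shared message
        np.testing.assert_allclose(traj.S[0], 0.9 * F_leaf ** 3, atol=1e-12)

    def test_conservation_and_monotonicity(self, triangle, coarse_grid,
                                           unit_markovian, unit_recovery):
        init = NodeInit.homogeneous(3, 0.9, 0.0)
        sol = solve_message_system(triangle, init, unit_markovian, coarse_grid)
        traj = node_marginals(sol, init, unit_recovery)
        traj.validate()  # S+I+R = 1, S down, R up


class TestVerifyFeasibility:
    def test_solver_output_passes(self, path3, coarse_grid, unit_markovian,
                                  init_z09):
        sol = solve_message_system(path3, init_z09, unit_markovian,
                                   coarse_grid)
        report = verify_feasibility(sol)
        assert all(item["pass"] for item in report.values())

    def _bump(v):
        v = v.copy()
        v[5] = v[4] + 1e-3  # a genuine local increase
        return v

    @pytest.mark.parametrize("corrupt,key", [
        (_bump, "non_increasing"),
        (lambda v: np.where(np.arange(v.size) == 1, 1.2, v),
         "in_unit_interval"),
    ])
    def test_hand_built_violations_flagged(self, path3, coarse_grid,
                                           unit_markovian, init_z09, corrupt,
                                           key):
        sol = solve_message_system(path3, init_z09, unit_markovian,
                                   coarse_grid)
        pair = next(iter(sol.F))
        sol.F[pair] = corrupt(sol.F[pair])
        assert not verify_feasibility(sol)[key]["pass"]


class TestUniqueness:
    def test_zero_kernel_distance_zero(self, triangle, coarse_grid):
        init = NodeInit.homogeneous(3, 0.9, 0.0)
        assert uniqueness_check(triangle, init, zero_kernel(),
                                coarse_grid) == 0.0

    @pytest.mark.parametrize("kernel", [
        markovian_kernel(1.0, 1.0), fixed_recovery_kernel(1.0, 1.0)])
    def test_two_starts_agree(self, coarse_grid, kernel):
        net = make_symmetric_graph("complete", m=4)
        init = NodeInit.homogeneous(4, 0.9, 0.0)
        d = uniqueness_check(net, init, kernel, coarse_grid, tol=1e-10)
        assert d <= 1e-8


class TestExpectedEpidemicSize:
    def test_zero_kernel_size_zero(self, path3, coarse_grid, init_z09,
                                   unit_recovery):
        sol = solve_message_system(path3, init_z09, zero_kernel(), coarse_grid)
        traj = node_marginals(sol, init_z09, unit_recovery)
        np.testing.assert_allclose(expected_epidemic_size(traj, init_z09),
                                   0.0, atol=1e-12)

    def test_no_susceptibles_size_zero(self, path3, coarse_grid,
                                       unit_markovian, unit_recovery):
        init = NodeInit.homogeneous(3, 0.0, 0.0)
        sol = solve_message_system(path3, init, unit_markovian, coarse_grid)
        traj = node_marginals(sol, init, unit_recovery)
        np.testing.assert_allclose(expected_epidemic_size(traj, init), 0.0,
                                   atol=1e-12)

    def test_non_decreasing_and_bounds_oracle_on_tree(self, path3, fine_grid,
                                                      init_z09,
                                                      unit_markovian,
                                                      unit_recovery):
        sol = solve_message_system(path3, init_z09, unit_markovian, fine_grid)
        traj = node_marginals(sol, init_z09, unit_recovery)
        size = expected_epidemic_size(traj, init_z09)
        assert size[0] == pytest.approx(0.0, abs=1e-12)
        assert np.min(np.diff(size)) >= -1e-9
        oracle = forward_equations_markov(path3, 1.0, 1.0, init_z09, fine_grid)
        size_oracle = expected_epidemic_size(oracle, init_z09)
        # upper bound, with equality on trees up to quadrature error
        np.testing.assert_allclose(size, size_oracle, atol=5e-3)
        assert np.min(size - size_oracle) >= -5e-3
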
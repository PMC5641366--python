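import numpy as np
import pytest

from mpsir import (HomogeneousParams, TimeGrid, exponential_recovery,
                   final_size, fixed_recovery, fixed_recovery_kernel,
                   major_outbreak_impossible, markovian_kernel,
                   meanfield_final_size, r0, solve_homogeneous,
                   solve_homogeneous_dde, solve_homogeneous_ode, zero_kernel)


def make_params(n=3, z=0.99, y=0.0, beta=1.0, gamma=1.0):
    return HomogeneousParams(n=n, z=z, y=y,
                             kernel=markovian_kernel(beta, gamma),
                             recovery=exponential_recovery(gamma))


class TestVolterraRoute:
    def test_zero_kernel_keeps_susceptibles(self, coarse_grid):
        params = HomogeneousParams(n=3, z=0.9, y=0.0, kernel=zero_kernel(),
                                   recovery=exponential_recovery(1.0))
        res = solve_homogeneous(params, coarse_grid)
        np.testing.assert_array_equal(res.F_sym, 1.0)
        np.testing.assert_allclose(res.trajectory.S, 0.9, atol=1e-12)

    def test_S_is_z_F_to_the_n(self, coarse_grid):
        res = solve_homogeneous(make_params(), coarse_grid)
        np.testing.assert_allclose(res.trajectory.S,
                                   0.99 * res.F_sym ** 3, atol=1e-12)

    def test_envelope_lower_bound(self, coarse_grid):
        # F >= 1 - int f implies S >= z (1 - p)^n for all t
        params = make_params(n=2, z=0.99, beta=0.2, gamma=1.0)
        res = solve_homogeneous(params, coarse_grid)
        p = params.kernel.total_mass
        assert res.trajectory.S[-1] >= 0.99 * (1 - p) ** 2 - 1e-9


class TestOdeRoute:
    def test_no_transmission(self, coarse_grid):
        res = solve_homogeneous_ode(make_params(beta=1e-12), coarse_grid)
        np.testing.assert_allclose(res.F_sym, 1.0, atol=1e-9)
        np.testing.assert_allclose(res.trajectory.S, 0.99, atol=1e-9)

    def test_matches_volterra(self, fine_grid):
        params = make_params()
        volt = solve_homogeneous(params, fine_grid)
        ode = solve_homogeneous_ode(params, fine_grid)
        assert np.max(np.abs(volt.trajectory.S - ode.trajectory.S)) <= 2e-4

    def test_equilibrium_residual(self):
        # slowest decay mode of this instance has rate ~0.2, so a long
        # horizon is needed before dF/dt is at round-off level
        grid = TimeGrid(t_max=160.0, dt=0.02)
        params = make_params()
        res = solve_homogeneous_ode(params, grid)
        F = res.F_sym[-1]
        resid = abs(1.0 * (1 - F) - 1.0 * (F - 0.0 - 0.99 * F ** 2))
        assert resid < 1e-10

    def test_long_time_hits_final_size(self):
        grid = TimeGrid(t_max=80.0, dt=0.01)
        params = make_params()
        res = solve_homogeneous_ode(params, grid)
        assert res.trajectory.S[-1] == pytest.approx(final_size(params),
                                                     abs=1e-4)

    def test_rejects_mismatched_recovery(self, coarse_grid):
        params = HomogeneousParams(n=3, z=0.99, y=0.0,
                                   kernel=markovian_kernel(1.0, 1.0),
                                   recovery=exponential_recovery(2.0))
        with pytest.raises(ValueError, match="matching"):
            solve_homogeneous_ode(params, coarse_grid)


class TestDdeRoute:
    def make(self, beta=1.0, R=1.0, n=3, z=0.99, y=0.0):
        return HomogeneousParams(n=n, z=z, y=y,
                                 kernel=fixed_recovery_kernel(beta, R),
                                 recovery=fixed_recovery(R))

    def test_recovered_flat_before_delay(self, coarse_grid):
        res = solve_homogeneous_dde(self.make(y=0.0), coarse_grid)
        m = coarse_grid.index_of(1.0)
        np.testing.assert_array_equal(res.trajectory.R[:m], 0.0)

    def test_no_transmission_step_recovery(self, coarse_grid):
        res = solve_homogeneous_dde(self.make(beta=1e-12), coarse_grid)
        np.testing.assert_allclose(res.F_sym, 1.0, atol=1e-9)
        m = coarse_grid.index_of(1.0)
        np.testing.assert_allclose(res.trajectory.R[m:], 1 - 0.99, atol=1e-9)

    def test_matches_volterra(self, fine_grid):
        params = self.make()
        volt = solve_homogeneous(params, fine_grid)
        dde = solve_homogeneous_dde(params, fine_grid)
        assert np.max(np.abs(volt.trajectory.S - dde.trajectory.S)) <= 5e-4
        assert np.max(np.abs(volt.trajectory.R - dde.trajectory.R)) <= 5e-4

    def test_rejects_misaligned_delay(self):
        grid = TimeGrid(t_max=2.0, dt=0.08)  # 0.08 does not divide 1.0
        with pytest.raises(ValueError):
            solve_homogeneous_dde(self.make(R=1.0), grid)


class TestFinalSize:
    def test_zero_mass_returns_z(self):
        params = HomogeneousParams(n=3, z=0.9, y=0.0, kernel=zero_kernel(),
                                   recovery=exponential_recovery(1.0))
        assert final_size(params) == pytest.approx(0.9, abs=1e-12)

    def test_certain_transmission_n2_forces_extinction(self):
        # p = 1, y = 0, z = 0.5, n = 2: u = z u has only u = 0
        k = fixed_recovery_kernel(50.0, 10.0)  # p = 1 - e^{-500} ~ 1
        params = HomogeneousParams(n=2, z=0.5, y=0.0, kernel=k,
                                   recovery=fixed_recovery(10.0))
        assert final_size(params) == pytest.approx(0.0, abs=1e-10)

    def test_r0(self):
        assert r0(make_params(n=3)) == pytest.approx(1.0)  # p=1/2, n=3
        assert r0(make_params(n=5)) == pytest.approx(2.0)

    @pytest.mark.parametrize("n,y,beta,impossible", [
        (3, 0.0, 0.82, True),    # R0 = 2 * 0.82/1.82 < 1
        (5, 0.5, 1.0, True),     # R0 = 2, y = 0.5 >= 1 - 1/2
        (5, 0.2, 1.0, False),    # R0 = 2, y = 0.2 < 1 - 1/2
    ])
    def test_outbreak_threshold_branches(self, n, y, beta, impossible):
        z = 1.0 - y - 1e-6
        params = make_params(n=n, z=z, y=y, beta=beta)
        assert major_outbreak_impossible(params) is impossible

    def test_no_outbreak_final_size_is_z(self):
        params = make_params(n=3, z=1.0 - 1e-12, y=0.0, beta=0.82)
        assert abs(final_size(params) - params.z) < 1e-10

    def test_outbreak_root_strictly_below_z(self):
        params = make_params(n=5, z=0.8 - 1e-4, y=0.2)
        assert final_size(params) < params.z - 1e-3


class TestMeanField:
    def test_no_transmission(self):
        assert meanfield_final_size(0.0, 0.3) == pytest.approx(0.7)

    def test_subcritical_no_outbreak(self):
        assert meanfield_final_size(0.9, 0.0) == pytest.approx(1.0)

    def test_classic_supercritical_root(self):
        s = meanfield_final_size(2.0, 0.0)
        assert s == pytest.approx(np.exp(-2.0 * (1 - s)), abs=1e-12)

    def test_network_final_size_converges_to_meanfield(self):
        mf = meanfield_final_size(2.0, 0.0)
        gaps = []
        for n in (10, 100, 1000):
            p = 2.0 / (n - 1)
            params = make_params(n=n, z=1 - 1e-6, y=0.0,
                                 beta=p / (1 - p), gamma=1.0)
            gaps.append(abs(final_size(params) - mf))
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 1e-2
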
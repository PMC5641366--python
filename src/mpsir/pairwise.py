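"""Population-level pairwise SIR model and its message-passing correspondence.

For the homogeneous model with Poisson contact processes (rate beta)
independent of recovery, the singles/pairs system

    d[S]/dt  = -beta [SI]
    d[I]/dt  =  beta [SI] - int_0^t r(tau) beta [SI](t-tau) dtau
               - r(t) N (1 - y - z)
    d[SS]/dt = -2 beta ((n-1)/n) [SS][SI]/[S]
    d[SI]/dt = -beta ((n-1)/n) [SI]^2/[S] - beta [SI]
               + beta ((n-1)/n) [SS][SI]/[S]
               - int_0^t e^{-beta tau} r(tau) beta ((n-1)/n)
                   ([SS][SI]/[S])(t-tau)
                   exp(-int_{t-tau}^t beta ((n-1)/n) [SI]/[S]) dtau
               - n N z e^{-beta t} r(t) (1 - y - z)
                   exp(-int_0^t beta ((n-1)/n) [SI]/[S])

is exactly equivalent to the homogeneous message passing system through

    [S]  = N S_mes,                [I]  = N I_mes,
    [SS] = n N z^2 F^{2(n-1)},     [SI] = n N z F^{n-1} (-dF/dt) / beta.

The cheap route (:func:`pairwise_from_messages`) reads the pair series off a
solved message system; :func:`solve_pairwise_direct` integrates the closed
integro-differential system independently so that the equivalence can be
verified numerically.  With exponential recovery the memory integrals
collapse and the classic Poisson pairwise ODE model is recovered; with a
point-mass infectious period the direct route is rejected (the delta-source
terms are not implemented) and the message route must be used.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_io import TimeGrid
from .mp_homogeneous import HomogeneousParams, HomogeneousResult, final_size

__all__ = [
    "PairwiseTrajectory",
    "pairwise_from_messages",
    "solve_pairwise_direct",
    "pairwise_final_size",
]

_POISSON_FAMILIES = ("markovian", "fixed_recovery", "poisson_contact")


@dataclass
class PairwiseTrajectory:
    """Singles [S], [I] and pairs [SS], [SI] on a grid, at population scale N."""

    grid: TimeGrid
    S: np.ndarray
    I: np.ndarray
    SS: np.ndarray
    SI: np.ndarray
    N: float
    n: int


def _contact_rate(params: HomogeneousParams) -> float:
    if params.kernel.family not in _POISSON_FAMILIES:
        raise ValueError(
            "pairwise correspondence requires Poisson contacts independent of "
            f"recovery; kernel family {params.kernel.family!r} does not "
            "guarantee the form f(tau) = beta exp(-beta tau) P(mu > tau)")
    return float(params.kernel.params[0])


def pairwise_from_messages(result: HomogeneousResult,
                           params: HomogeneousParams,
                           N: float, beta: float) -> PairwiseTrajectory:
    """Pair series from a solved homogeneous message system.

    ``-dF/dt`` is taken by centred differences in the interior and one-sided
    second-order differences at the ends of the grid.
    """
    kernel_beta = _contact_rate(params)
    if abs(kernel_beta - beta) > 1e-12:
        raise ValueError("beta disagrees with the kernel's contact rate")
    F = result.F_sym
    dt = result.grid.dt
    dF = np.gradient(F, dt, edge_order=2)
    z, y, n = params.z, params.y, params.n
    S = N * result.trajectory.S
    I = N * result.trajectory.I
    SS = n * N * z ** 2 * F ** (2 * (n - 1))
    SI = n * N * z * F ** (n - 1) * (-dF / beta)
    return PairwiseTrajectory(result.grid, S, I, SS, SI, N, n)


def solve_pairwise_direct(params: HomogeneousParams, N: float,
                          grid: TimeGrid) -> PairwiseTrajectory:
    """Integrate the closed pairwise system with its two memory integrals.

    Heun (trapezoidal predictor-corrector) stepping; each memory integral is
    accumulated on the grid, the exp(-int ...) weight in log space via the
    running integral Q(t) of beta ((n-1)/n) [SI]/[S], so a step costs O(t)
    and a solve O(T^2).  Requires a continuous recovery density.
    """
    beta = _contact_rate(params)
    if params.recovery.atom_at is not None:
        raise ValueError("direct pairwise route requires a continuous recovery "
                         "density; use pairwise_from_messages with the DDE "
                         "route for a fixed infectious period")
    n, z, y = params.n, params.z, params.y
    kappa = (n - 1) / n
    times = grid.times
    dt = grid.dt
    T = times.size
    r_vals = np.asarray(params.recovery.evaluate(times), dtype=float)
    ebt = np.exp(-beta * times)
    seed = N * (1.0 - y - z)  # initially infected mass

    # state columns: [S], [I], [SS], [SI]
    state = np.empty((T, 4))
    state[0] = (N * z, seed, n * N * z ** 2, n * N * z * (1.0 - y - z))

    # histories on the grid
    bsi = np.zeros(T)    # beta [SI]
    q = np.zeros(T)      # beta kappa [SI]/[S]
    Q = np.zeros(T)      # int_0^t q
    gh = np.zeros(T)     # beta kappa [SS][SI]/[S] * e^{Q}

    def hist_entries(s):
        S, _, SS, SI = s
        if S <= 0.0:
            return beta * SI, 0.0, 0.0
        qv = beta * kappa * SI / S
        return beta * SI, qv, beta * kappa * SS * SI / S

    bsi[0], q[0], g0 = hist_entries(state[0])
    gh[0] = g0  # e^{Q(0)} = 1

    def trap_dot(weights, series, k):
        # trapezoid of sum_{j=0..k} weights[j] * series[k-j]
        if k == 0:
            return 0.0
        acc = float(np.dot(weights[1:k], series[k - 1:0:-1])) if k > 1 else 0.0
        acc += 0.5 * (weights[0] * series[k] + weights[k] * series[0])
        return dt * acc

    def rhs(k, s):
        S, I, SS, SI = s
        b_si, qv, g = hist_entries(s)
        eQ = np.exp(-Q[k])
        conv_r = trap_dot(r_vals, bsi, k)
        conv_g = trap_dot(ebt * r_vals, gh, k)
        dS = -b_si
        dI = b_si - conv_r - r_vals[k] * seed
        if S <= 0.0:
            dSS = 0.0
            dSI = 0.0
        else:
            dSS = -2.0 * qv * SS
            dSI = (-qv * SI - beta * SI + g
                   - eQ * conv_g
                   - n * N * z * ebt[k] * r_vals[k] * (1.0 - y - z) * eQ)
        return np.array([dS, dI, dSS, dSI])

    for k in range(T - 1):
        sk = state[k]
        f0 = rhs(k, sk)
        pred = sk + dt * f0
        # predicted history entries at k+1
        bsi[k + 1], q[k + 1], g1 = hist_entries(pred)
        Q[k + 1] = Q[k] + 0.5 * dt * (q[k] + q[k + 1])
        gh[k + 1] = g1 * np.exp(Q[k + 1])
        f1 = rhs(k + 1, pred)
        new = sk + 0.5 * dt * (f0 + f1)
        state[k + 1] = new
        bsi[k + 1], q[k + 1], g1 = hist_entries(new)
        Q[k + 1] = Q[k] + 0.5 * dt * (q[k] + q[k + 1])
        gh[k + 1] = g1 * np.exp(Q[k + 1])

    return PairwiseTrajectory(grid, state[:, 0], state[:, 1],
                              state[:, 2], state[:, 3], N, n)


def pairwise_final_size(params: HomogeneousParams, N: float) -> float:
    """[S](infinity) = N * S_mes(infinity): the pairwise model shares the
    message-passing final-size equation with p = int beta e^{-beta tau}
    P(mu > tau) dtau."""
    _contact_rate(params)
    return N * final_size(params)
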
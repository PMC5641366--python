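"""Message passing on an arbitrary finite graph.

One message ``F[i <- j](t)`` per ordered neighbour pair approximates the
probability that node i, held in the cavity state (its own outgoing
transmissions cancelled), has received no infectious contact from j by time
t.  The messages solve the coupled Volterra system

    F[i<-j](t) = 1 - int_0^t f_ij(tau) (1 - y_j - z_j *
                  prod_{k in N(j) \\ i} F[j<-k](t - tau)) dtau,

discretized with trapezoid quadrature on a uniform grid and solved by Picard
(fixed-point) iteration from the constant-1 start.  The iteration map is
monotone: starting from F = 1 successive sweeps are pointwise non-increasing
and converge to the maximal (and, under a finite sup bound on every kernel,
unique) feasible solution.

Node marginals follow from the messages:

    S_i(t) = z_i * prod_{j in N(i)} F[i<-j](t)
    R_i(t) = y_i + int_0^t r_i(tau) (1 - y_i - S_i(t - tau)) dtau
    I_i(t) = 1 - S_i(t) - R_i(t).

On trees these marginals are exact for the stochastic model; on graphs with
cycles S_i is a lower bound for P(node i susceptible) and R_i an upper bound
for P(node i recovered), so the summed epidemic size is never
underestimated.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .model_io import NetworkModel, NodeInit, TimeGrid, Trajectory
from .kernels import TransmissionKernel, RecoveryDensity, tabulate
from ._quadrature import trap_convolve

__all__ = [
    "MessageSolution",
    "solve_message_system",
    "node_marginals",
    "verify_feasibility",
    "uniqueness_check",
    "expected_epidemic_size",
    "NonConvergenceError",
]


class NonConvergenceError(RuntimeError):
    def __init__(self, residual: float, max_iter: int):
        super().__init__(
            f"message iteration did not reach tolerance in {max_iter} sweeps "
            f"(residual {residual:.3e})")
        self.residual = residual
        self.max_iter = max_iter


@dataclass
class MessageSolution:
    """Solved messages on a grid.

    ``F`` maps the ordered pair ``(i, j)`` — read "i listening to j" — to the
    message values on the grid.
    """

    network: NetworkModel
    grid: TimeGrid
    F: dict
    iterations_used: int
    residual: float


def _kernel_table(network: NetworkModel,
                  kernels,
                  grid: TimeGrid) -> dict:
    """Tabulated f values per directed pair (i, j): transmission j -> i."""
    pairs = network.directed_edges
    if isinstance(kernels, TransmissionKernel):
        f_vals, _ = tabulate(kernels, grid)
        if not np.isfinite(kernels.sup_bound):
            raise ValueError("kernel lacks a finite sup bound")
        return {pair: f_vals for pair in pairs}
    table = {}
    cache: dict[int, np.ndarray] = {}
    for pair in pairs:
        try:
            ker = kernels[pair]
        except KeyError:
            raise KeyError(f"no kernel supplied for directed pair {pair}")
        if not np.isfinite(ker.sup_bound):
            raise ValueError(f"kernel for {pair} lacks a finite sup bound")
        key = id(ker)
        if key not in cache:
            cache[key], _ = tabulate(ker, grid)
        table[pair] = cache[key]
    return table


def _picard(network: NetworkModel, init: NodeInit, f_table: Mapping,
            grid: TimeGrid, tol: float, max_iter: int,
            start: dict, expect_decreasing: bool) -> tuple[dict, int, float]:
    pairs = sorted(f_table.keys())
    if not pairs:  # edgeless graph: nothing to solve
        return {}, 0, 0.0
    nbrs = network.neighbours
    z, y = init.z, init.y
    F = {pair: start[pair].copy() for pair in pairs}
    residual = np.inf
    for sweep in range(1, max_iter + 1):
        new = {}
        for (i, j) in pairs:
            prod = np.ones(grid.times.size)
            for k in nbrs[j]:
                if k != i:
                    prod *= F[(j, k)]
            g = 1.0 - y[j] - z[j] * prod
            new[(i, j)] = 1.0 - trap_convolve(f_table[(i, j)], g, grid.dt)
        residual = max(float(np.max(np.abs(new[p] - F[p]))) for p in pairs)
        if expect_decreasing:
            overshoot = max(float(np.max(new[p] - F[p])) for p in pairs)
            if overshoot > 1e-12:
                raise AssertionError(
                    f"monotone Picard iteration increased by {overshoot:.3e}")
        F = new
        if residual <= tol:
            return F, sweep, residual
    raise NonConvergenceError(residual, max_iter)


def solve_message_system(network: NetworkModel, init: NodeInit,
                         kernels, grid: TimeGrid,
                         tol: float = 1e-10,
                         max_iter: int = 500) -> MessageSolution:
    """Solve the message system by monotone Picard iteration from F = 1.

    ``kernels`` is either one :class:`TransmissionKernel` shared by all
    directed pairs or a mapping ``(i, j) -> kernel`` where the kernel for
    ``(i, j)`` governs transmission from j to i (heterogeneous directions
    allowed).
    """
    if init.node_count != network.node_count:
        raise ValueError("initial conditions and network disagree on node count")
    f_table = _kernel_table(network, kernels, grid)
    ones = np.ones(grid.times.size)
    start = {pair: ones for pair in f_table}
    F, sweeps, residual = _picard(network, init, f_table, grid, tol, max_iter,
                                  start, expect_decreasing=True)
    return MessageSolution(network=network, grid=grid, F=F,
                           iterations_used=sweeps, residual=residual)


def node_marginals(solution: MessageSolution, init: NodeInit,
                   recovery) -> Trajectory:
    """Per-node S/I/R trajectories from solved messages.

    ``recovery`` is one :class:`RecoveryDensity` shared by all nodes or a
    sequence with one entry per node.
    """
    net, grid = solution.network, solution.grid
    n = net.node_count
    if isinstance(recovery, RecoveryDensity):
        recovery = [recovery] * n
    S = np.empty((n, grid.times.size))
    R = np.empty_like(S)
    for i in range(n):
        prod = np.ones(grid.times.size)
        for j in net.neighbours[i]:
            prod *= solution.F[(i, j)]
        S[i] = init.z[i] * prod
        R[i] = init.y[i] + recovery[i].convolve(1.0 - init.y[i] - S[i], grid)
    I = 1.0 - S - R
    return Trajectory(grid, S, I, R)


def verify_feasibility(solution: MessageSolution,
                       monotone_tol: float = 1e-9,
                       range_tol: float = 1e-12) -> dict:
    """Check the defining properties of a feasible message solution.

    Returns a report with a pass flag and the worst violating magnitude for
    each of: values in [0, 1], F(0) = 1, non-increasing in t.
    """
    worst_range = 0.0
    worst_start = 0.0
    worst_increase = 0.0
    for vals in solution.F.values():
        worst_range = max(worst_range,
                          float(np.max(vals - 1.0)), float(np.max(-vals)))
        worst_start = max(worst_start, abs(float(vals[0]) - 1.0))
        worst_increase = max(worst_increase, float(np.max(np.diff(vals))))
    return {
        "in_unit_interval": {"pass": worst_range <= range_tol,
                             "worst": worst_range},
        "starts_at_one": {"pass": worst_start <= range_tol,
                          "worst": worst_start},
        "non_increasing": {"pass": worst_increase <= monotone_tol,
                           "worst": worst_increase},
    }


def uniqueness_check(network: NetworkModel, init: NodeInit, kernels,
                     grid: TimeGrid, tol: float = 1e-10,
                     max_iter: int = 500) -> float:
    """Sup distance between the fixed points reached from the two extreme starts.

    The Picard map is monotone, so iterates from the upper start F = 1
    decrease to the maximal fixed point while iterates from the lower start
    F = 1 - int_0^t f (the all-infected envelope, below every feasible
    solution) increase to the minimal one.  A small distance certifies
    numerical uniqueness on this instance.
    """
    f_table = _kernel_table(network, kernels, grid)
    ones = np.ones(grid.times.size)
    upper_start = {pair: ones for pair in f_table}
    lower_start = {}
    for pair, f_vals in f_table.items():
        from ._quadrature import trap_cumulative
        lower_start[pair] = np.clip(1.0 - trap_cumulative(f_vals, grid.dt),
                                    0.0, 1.0)
    F_hi, _, _ = _picard(network, init, f_table, grid, tol, max_iter,
                         upper_start, expect_decreasing=True)
    F_lo, _, _ = _picard(network, init, f_table, grid, tol, max_iter,
                         lower_start, expect_decreasing=False)
    if not F_hi:
        return 0.0
    return max(float(np.max(np.abs(F_hi[p] - F_lo[p]))) for p in F_hi)


def expected_epidemic_size(trajectories: Trajectory,
                           init: NodeInit) -> np.ndarray:
    """Upper bound on the expected cumulative number of infection events.

    ``sum_i z_i - sum_i S_i(t)``: a non-decreasing series starting at 0.
    The stochastic model's expected epidemic size never exceeds it, with
    equality on trees.
    """
    S = np.atleast_2d(trajectories.S)
    return float(np.sum(init.z)) - S.sum(axis=0)
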
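"""The homogeneous message passing system for symmetric (arc-transitive) graphs.

On an n-regular symmetric graph with identical individuals all messages
coincide, and the whole system collapses to one scalar Volterra equation
plus the marginal definitions:

    F(t)     = 1 - int_0^t f(tau) [1 - y - z F(t - tau)^{n-1}] dtau
    S_mes(t) = z F(t)^n
    R_mes(t) = y + int_0^t r(tau) [1 - y - S_mes(t - tau)] dtau
    I_mes(t) = 1 - S_mes(t) - R_mes(t).

Two classical special cases admit (delay) differential forms and are
implemented as independent routes used for cross-validation:

* Poisson contacts + exponential recovery (f = beta e^{-(beta+gamma) tau}):
      dF/dt = gamma (1 - F) - beta (F - y - z F^{n-1}),   dR/dt = gamma I.
* Poisson contacts + fixed infectious period R (f truncated at R):
      dF/dt = -beta (F - y - z F^{n-1}
              - theta(t - R) e^{-beta R} (1 - y - z F(t-R)^{n-1})),
      R_mes(t) = y + theta(t - R) (1 - y - S_mes(t - R)).

Final-size and threshold results: with p = int_0^inf f, the limit
u = F(infinity) is the largest root in [0, 1] of
u = 1 - p + p y + p z u^{n-1}, S_mes(inf) = z u^n, and a major outbreak is
impossible (in the small-initial-infection regime z -> 1 - y) when
R0 = (n - 1) p <= 1 or the vaccinated fraction satisfies y >= 1 - 1/R0.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model_io import TimeGrid, Trajectory
from .kernels import TransmissionKernel, RecoveryDensity, tabulate
from .mp_general import NonConvergenceError
from ._quadrature import trap_convolve

__all__ = [
    "HomogeneousParams",
    "HomogeneousResult",
    "solve_homogeneous",
    "solve_homogeneous_ode",
    "solve_homogeneous_dde",
    "final_size",
    "r0",
    "major_outbreak_impossible",
    "meanfield_final_size",
]


@dataclass(frozen=True)
class HomogeneousParams:
    """Shared parameters of the homogeneous stochastic model.

    n: regular degree (>= 2); z / y: per-individual probabilities of being
    initially susceptible / vaccinated; kernel: transmission kernel f;
    recovery: infectious-period density r.
    """

    n: int
    z: float
    y: float
    kernel: TransmissionKernel
    recovery: RecoveryDensity

    def __post_init__(self):
        if int(self.n) != self.n or self.n < 2:
            raise ValueError("regular degree n must be an integer >= 2")
        if not (0 < self.z < 1):
            raise ValueError("need 0 < z < 1")
        if not (0 <= self.y < 1 - self.z + 1e-15):
            raise ValueError("need 0 <= y < 1 - z")


@dataclass
class HomogeneousResult:
    grid: TimeGrid
    F_sym: np.ndarray
    trajectory: Trajectory
    method: str
    iterations_used: int = 0
    residual: float = 0.0


def _finish(params: HomogeneousParams, grid: TimeGrid, F: np.ndarray,
            method: str, R: np.ndarray | None = None,
            iterations: int = 0, residual: float = 0.0) -> HomogeneousResult:
    S = params.z * F ** params.n
    if R is None:
        R = params.y + params.recovery.convolve(1.0 - params.y - S, grid)
    I = 1.0 - S - R
    traj = Trajectory(grid, S, I, R)
    return HomogeneousResult(grid=grid, F_sym=F, trajectory=traj,
                             method=method, iterations_used=iterations,
                             residual=residual)


def solve_homogeneous(params: HomogeneousParams, grid: TimeGrid,
                      tol: float = 1e-10,
                      max_iter: int = 500) -> HomogeneousResult:
    """Solve the scalar Volterra message equation by Picard iteration from F = 1.

    Works for any kernel with a finite sup bound; this is the reference
    route against which the ODE/DDE special cases are checked.
    """
    if not np.isfinite(params.kernel.sup_bound):
        raise ValueError("kernel lacks a finite sup bound")
    f_vals, _ = tabulate(params.kernel, grid)
    z, y, n = params.z, params.y, params.n
    F = np.ones(grid.times.size)
    residual = np.inf
    for sweep in range(1, max_iter + 1):
        g = 1.0 - y - z * F ** (n - 1)
        new = 1.0 - trap_convolve(f_vals, g, grid.dt)
        residual = float(np.max(np.abs(new - F)))
        F = new
        if residual <= tol:
            return _finish(params, grid, F, "volterra",
                           iterations=sweep, residual=residual)
    raise NonConvergenceError(residual, max_iter)


def solve_homogeneous_ode(params: HomogeneousParams,
                          grid: TimeGrid) -> HomogeneousResult:
    """Markovian special case via fixed-step RK4 on (F, R)."""
    if params.kernel.family != "markovian":
        raise ValueError("ODE route requires a markovian kernel")
    beta, gamma = params.kernel.params
    if params.recovery.family != "exponential" or \
            abs(params.recovery.params[0] - gamma) > 1e-12:
        raise ValueError("ODE route requires Exp(gamma) recovery matching the kernel")
    z, y, n = params.z, params.y, params.n
    dt = grid.dt
    T = grid.times.size

    def rhs(state):
        F, R = state
        dF = gamma * (1.0 - F) - beta * (F - y - z * F ** (n - 1))
        dR = gamma * (1.0 - z * F ** n - R)
        return np.array([dF, dR])

    out = np.empty((T, 2))
    out[0] = (1.0, y)
    s = out[0].copy()
    for k in range(T - 1):
        k1 = rhs(s)
        k2 = rhs(s + 0.5 * dt * k1)
        k3 = rhs(s + 0.5 * dt * k2)
        k4 = rhs(s + dt * k3)
        s = s + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        out[k + 1] = s
    return _finish(params, grid, out[:, 0], "ode", R=out[:, 1])


def solve_homogeneous_dde(params: HomogeneousParams,
                          grid: TimeGrid) -> HomogeneousResult:
    """Fixed-infectious-period special case via RK4 method of steps.

    Requires the delay R to be a multiple of dt so the delayed argument
    stays grid-aligned (half-step stage values are linearly interpolated
    from the already-computed history).
    """
    if params.kernel.family != "fixed_recovery":
        raise ValueError("DDE route requires a fixed_recovery kernel")
    beta, delay = params.kernel.params
    if params.recovery.atom_at is None or \
            abs(params.recovery.atom_at - delay) > 1e-12:
        raise ValueError("DDE route requires a point-mass infectious period "
                         "matching the kernel truncation")
    m = grid.index_of(delay)  # raises if dt does not divide R
    if m < 1:
        raise ValueError("delay must be at least one grid step")
    z, y, n = params.z, params.y, params.n
    dt = grid.dt
    decay = math.exp(-beta * delay)
    T = grid.times.size
    F = np.empty(T)
    F[0] = 1.0

    def lagged(idx_float: float) -> float:
        """Linear interpolation of F at fractional grid index (history only)."""
        lo = int(math.floor(idx_float))
        frac = idx_float - lo
        if frac == 0.0:
            return F[lo]
        return (1.0 - frac) * F[lo] + frac * F[lo + 1]

    def rhs(Fv: float, stage_idx: float) -> float:
        val = Fv - y - z * Fv ** (n - 1)
        lag_idx = stage_idx - m
        if lag_idx >= 0.0:
            Fd = lagged(lag_idx)
            val -= decay * (1.0 - y - z * Fd ** (n - 1))
        return -beta * val

    for k in range(T - 1):
        fk = F[k]
        k1 = rhs(fk, k)
        k2 = rhs(fk + 0.5 * dt * k1, k + 0.5)
        k3 = rhs(fk + 0.5 * dt * k2, k + 0.5)
        k4 = rhs(fk + dt * k3, k + 1.0)
        F[k + 1] = fk + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)

    S = z * F ** n
    R = np.full(T, y)
    R[m:] = y + (1.0 - y - S[: T - m])
    return _finish(params, grid, F, "dde", R=R)


def _final_u(n: int, p: float, z: float, y: float,
             tol: float = 1e-14) -> float:
    """Largest root in [0, 1] of u = 1 - p + p y + p z u^{n-1} (bisection).

    phi(u) = 1 - p + p y + p z u^{n-1} - u is convex on [0, 1] with
    phi(0) >= 0 and phi(1) = p (y + z - 1) <= 0, so there is exactly one
    sign change unless phi(1) = 0 (p = 0 or z = 1 - y), where the largest
    root is u = 1 — the no-outbreak branch, which is the epidemiologically
    relevant one at criticality.
    """
    def phi(u: float) -> float:
        return 1.0 - p + p * y + p * z * u ** (n - 1) - u

    if phi(1.0) >= -1e-15:
        return 1.0
    lo, hi = 0.0, 1.0  # phi(lo) >= 0 > phi(hi)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if phi(mid) >= 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def final_size(params: HomogeneousParams) -> float:
    """S_mes(infinity): the surviving susceptible fraction.

    Equal to z u^n where u solves the scalar final-size equation; the
    expected final epidemic fraction is bounded by z - S_mes(infinity) and
    R_mes(infinity) = 1 - S_mes(infinity).
    """
    u = _final_u(params.n, params.kernel.total_mass, params.z, params.y)
    return params.z * u ** params.n


def r0(params: HomogeneousParams) -> float:
    """Threshold parameter R0 = (n - 1) p."""
    return (params.n - 1) * params.kernel.total_mass


def major_outbreak_impossible(params: HomogeneousParams) -> bool:
    """Sufficient condition for no major outbreak as z -> 1 - y from below.

    True iff R0 <= 1 or the vaccination coverage satisfies y >= 1 - 1/R0;
    then the final-size equation at z = 1 - y has only the trivial root and
    S_mes(infinity) = z.
    """
    R0 = r0(params)
    return R0 <= 1.0 or params.y >= 1.0 - 1.0 / R0


def meanfield_final_size(R0: float, y: float = 0.0) -> float:
    """Mean-field final-size relation S/(1-y) = exp(-R0 (1 - S - y)).

    The n -> infinity limit of the network final size with p = R0/(n-1).
    Returns the epidemiologically relevant root: 1 - y when
    R0 (1 - y) <= 1 (no outbreak), otherwise the unique root in (0, 1 - y).
    """
    if R0 < 0 or not (0 <= y < 1):
        raise ValueError("need R0 >= 0 and 0 <= y < 1")
    s_max = 1.0 - y
    if R0 * s_max <= 1.0:
        return s_max

    from scipy.optimize import brentq
    def g(S):
        return S - s_max * math.exp(-R0 * (1.0 - S - y))
    hi = s_max * (1.0 - 1e-9)
    return float(brentq(g, 0.0, hi, xtol=1e-14))
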
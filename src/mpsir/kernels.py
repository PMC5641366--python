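"""Transmission kernels and recovery densities.

The central object is the transmission kernel ``f(tau)``: the (possibly
defective) density of the time from a node's infection to its infectious
contact of a given neighbour, jointly with that contact happening before the
node recovers.  Its total mass ``p = int_0^inf f`` is the marginal
probability that the edge ever transmits.

Parametric families:

* ``markovian_kernel(beta, gamma)`` — Poisson contacts at rate beta,
  exponential recovery at rate gamma: ``f(tau) = beta * exp(-(beta+gamma) tau)``,
  ``p = beta / (beta + gamma)``.
* ``fixed_recovery_kernel(beta, R)`` — Poisson contacts, non-random
  infectious period R: ``f(tau) = beta * exp(-beta tau)`` for ``tau < R``,
  zero after, ``p = 1 - exp(-beta R)``.
* ``independent_kernel(h, r)`` — arbitrary contact density h independent of
  recovery: ``f(tau) = h(tau) * P(mu > tau)``.
* ``common_shock_kernel(model)`` — contact times and infectious period
  positively correlated through a shared Bernoulli shock (e.g. infecteds who
  adopt disease-combating behaviour contact more slowly AND recover faster);
  the induced kernel is a two-component exponential mixture.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import integrate

from .model_io import TimeGrid
from ._quadrature import trap_cumulative

__all__ = [
    "TransmissionKernel",
    "RecoveryDensity",
    "AssociationModel",
    "markovian_kernel",
    "fixed_recovery_kernel",
    "independent_kernel",
    "common_shock_kernel",
    "poisson_contact_kernel",
    "tabulated_kernel",
    "zero_kernel",
    "exponential_recovery",
    "gamma_recovery",
    "fixed_recovery",
    "tabulate",
]


@dataclass(frozen=True)
class TransmissionKernel:
    """f(tau), its running integral, total mass p, and a finite sup bound.

    ``family``/``params`` identify closed-form special cases so the ODE/DDE
    fast paths can recognise them.
    """

    evaluate: Callable[[np.ndarray], np.ndarray]
    cumulative: Callable[[np.ndarray], np.ndarray]
    total_mass: float
    sup_bound: float
    family: str = "custom"
    params: tuple = ()

    def __post_init__(self):
        if not (-1e-12 <= self.total_mass <= 1 + 1e-12):
            raise ValueError("total mass p must lie in [0, 1]")
        if not math.isfinite(self.sup_bound):
            raise ValueError("kernel must come with a finite sup bound")

    @property
    def p(self) -> float:
        return self.total_mass

    def scaled(self, factor: float) -> "TransmissionKernel":
        """Kernel ``factor * f`` (frequency scaling f_n = f*/n)."""
        if factor < 0 or factor * self.total_mass > 1 + 1e-12:
            raise ValueError("scaled mass must stay in [0, 1]")
        return TransmissionKernel(
            evaluate=lambda tau, _f=self.evaluate: factor * np.asarray(_f(tau)),
            cumulative=lambda t, _c=self.cumulative: factor * np.asarray(_c(t)),
            total_mass=factor * self.total_mass,
            sup_bound=factor * self.sup_bound,
            family="scaled",
            params=(factor, self.family) + tuple(self.params),
        )


@dataclass(frozen=True)
class RecoveryDensity:
    """Density r(tau) of the infectious period, or an atom at a fixed R.

    ``survival(tau) = P(mu > tau)``.  When ``atom_at`` is set the law is the
    point mass at R and ``evaluate`` is None.
    """

    evaluate: Callable[[np.ndarray], np.ndarray] | None
    survival: Callable[[np.ndarray], np.ndarray]
    atom_at: float | None = None
    family: str = "custom"
    params: tuple = ()

    def convolve(self, series: np.ndarray, grid: TimeGrid) -> np.ndarray:
        """``int_0^t r(tau) series(t - tau) dtau`` on the grid.

        For an atom at R this is the exact shift ``theta(t - R) series(t - R)``
        (R must lie on the grid); otherwise trapezoid quadrature.
        """
        series = np.asarray(series, dtype=float)
        if self.atom_at is not None:
            m = grid.index_of(self.atom_at)
            out = np.zeros_like(series)
            out[m:] = series[: series.size - m]
            return out
        from ._quadrature import trap_convolve
        r_vals = np.asarray(self.evaluate(grid.times), dtype=float)
        return trap_convolve(r_vals, series, grid.dt)


@dataclass(frozen=True)
class AssociationModel:
    """Common-shock mixture creating associated {-mu, omega_j (all j)}.

    With probability ``pi`` the individual adopts disease-combating
    behaviour: contacts slow to rate ``beta_slow <= beta_base`` and recovery
    speeds up to ``gamma_fast >= gamma_base``.  Conditional on the shock the
    contact times and infectious period are independent exponentials drawn
    by inverse CDF, so every member of {-mu, omega_j} is a non-decreasing
    function of independent variables sharing the one shock — hence the set
    is associated (closure of association under non-decreasing transforms).
    """

    pi: float
    beta_base: float   # contact rate without the shock (beta_0)
    beta_slow: float   # contact rate under the shock (beta_1 <= beta_0)
    gamma_base: float  # recovery rate without the shock (gamma_0)
    gamma_fast: float  # recovery rate under the shock (gamma_1 >= gamma_0)

    def __post_init__(self):
        if not 0 <= self.pi <= 1:
            raise ValueError("mixture weight pi must lie in [0, 1]")
        if min(self.beta_base, self.beta_slow,
               self.gamma_base, self.gamma_fast) <= 0:
            raise ValueError("all rates must be positive")
        if self.beta_slow > self.beta_base + 1e-12:
            raise ValueError("need beta_slow <= beta_base (association ordering)")
        if self.gamma_fast < self.gamma_base - 1e-12:
            raise ValueError("need gamma_fast >= gamma_base (association ordering)")


def _require_positive(**kwargs):
    for name, val in kwargs.items():
        if not (val > 0):
            raise ValueError(f"{name} must be positive, got {val}")


def markovian_kernel(beta: float, gamma: float) -> TransmissionKernel:
    """Poisson contacts (rate beta) independent of Exp(gamma) recovery."""
    _require_positive(beta=beta, gamma=gamma)
    rate = beta + gamma
    return TransmissionKernel(
        evaluate=lambda tau: beta * np.exp(-rate * np.asarray(tau, dtype=float)),
        cumulative=lambda t: (beta / rate) * (-np.expm1(-rate * np.asarray(t, dtype=float))),
        total_mass=beta / rate,
        sup_bound=beta,
        family="markovian",
        params=(beta, gamma),
    )


def fixed_recovery_kernel(beta: float, R: float) -> TransmissionKernel:
    """Poisson contacts (rate beta), non-random infectious period R.

    f jumps to zero at tau = R; ``evaluate`` returns the midpoint value
    ``beta e^{-beta R} / 2`` exactly at the jump so that trapezoid sums over
    a grid containing R retain O(dt^2) accuracy.
    """
    _require_positive(beta=beta, R=R)

    def f(tau):
        tau = np.asarray(tau, dtype=float)
        vals = beta * np.exp(-beta * tau)
        vals = np.where(tau > R, 0.0, vals)
        return np.where(tau == R, 0.5 * beta * math.exp(-beta * R), vals)

    def cum(t):
        t = np.asarray(t, dtype=float)
        return -np.expm1(-beta * np.minimum(t, R))

    return TransmissionKernel(
        evaluate=f, cumulative=cum,
        total_mass=1.0 - math.exp(-beta * R),
        sup_bound=beta,
        family="fixed_recovery",
        params=(beta, R),
    )


def independent_kernel(h: Callable[[np.ndarray], np.ndarray],
                       r: RecoveryDensity,
                       horizon: float | None = None) -> TransmissionKernel:
    """Kernel for a contact density h independent of recovery: f = h * survival.

    ``p`` is computed by adaptive quadrature up to ``horizon`` (default: the
    time where the transmission survival probability drops below 1e-12,
    capped at 1e4 with a warning).
    """

    def f(tau):
        tau = np.asarray(tau, dtype=float)
        hv = np.asarray(h(tau), dtype=float)
        if np.any(hv < -1e-12):
            raise ValueError("contact density h is negative where sampled")
        return hv * np.asarray(r.survival(tau), dtype=float)

    if horizon is None:
        horizon = 1e4
        t = 1.0
        while t < 1e4:
            if f(np.array([t]))[0] < 1e-12 and np.asarray(r.survival(t)) < 1e-12:
                horizon = t
                break
            t *= 2.0
        else:
            warnings.warn("kernel mass integrated to capped horizon 1e4")
    p, _ = integrate.quad(lambda x: float(f(np.array([x]))[0]), 0.0, horizon,
                          limit=200)
    p = min(max(p, 0.0), 1.0)
    # grid-free sup estimate: sample densely on [0, horizon]
    probe = np.linspace(0.0, min(horizon, 50.0), 2001)
    sup = float(np.max(f(probe)))

    def cum(t, _horizon=horizon):
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.array([
            integrate.quad(lambda x: float(f(np.array([x]))[0]),
                           0.0, float(tt), limit=200)[0]
            for tt in t_arr
        ])
        return out if np.ndim(t) else float(out[0])

    return TransmissionKernel(evaluate=f, cumulative=cum, total_mass=p,
                              sup_bound=sup, family="independent")


def poisson_contact_kernel(beta: float, recovery: RecoveryDensity,
                           horizon: float | None = None) -> TransmissionKernel:
    """Poisson contacts at rate beta independent of an arbitrary recovery law.

    ``f(tau) = beta e^{-beta tau} P(mu > tau)``; the family tag records beta
    so the pairwise routes can verify their Poisson-contact precondition.
    Exponential recovery reduces to :func:`markovian_kernel` and a point-mass
    recovery to :func:`fixed_recovery_kernel`; those closed forms are
    returned directly.
    """
    _require_positive(beta=beta)
    if recovery.family == "exponential":
        return markovian_kernel(beta, recovery.params[0])
    if recovery.atom_at is not None:
        return fixed_recovery_kernel(beta, recovery.atom_at)
    base = independent_kernel(
        lambda tau: beta * np.exp(-beta * np.asarray(tau, dtype=float)),
        recovery, horizon=horizon)
    return TransmissionKernel(
        evaluate=base.evaluate, cumulative=base.cumulative,
        total_mass=base.total_mass, sup_bound=base.sup_bound,
        family="poisson_contact", params=(beta, recovery))


def common_shock_kernel(model: AssociationModel) -> TransmissionKernel:
    """Induced kernel of the common-shock sampler: an exponential mixture.

    Conditional on the shock the pair (contact rate, recovery rate) is
    (beta_slow, gamma_fast) with probability pi, else
    (beta_base, gamma_base), and within a component contacts and recovery are
    independent, so f is the mixture of the two Markovian kernels.  This is
    exactly the marginal kernel of :func:`mpsir.stochastic.sample_individual`.
    """
    k1 = markovian_kernel(model.beta_slow, model.gamma_fast)
    k0 = markovian_kernel(model.beta_base, model.gamma_base)
    pi = model.pi

    return TransmissionKernel(
        evaluate=lambda tau: pi * k1.evaluate(tau) + (1 - pi) * k0.evaluate(tau),
        cumulative=lambda t: pi * k1.cumulative(t) + (1 - pi) * k0.cumulative(t),
        total_mass=pi * k1.total_mass + (1 - pi) * k0.total_mass,
        sup_bound=pi * k1.sup_bound + (1 - pi) * k0.sup_bound,
        family="common_shock",
        params=(model.pi, model.beta_base, model.beta_slow,
                model.gamma_base, model.gamma_fast),
    )


def tabulated_kernel(tau: np.ndarray, f_vals: np.ndarray) -> TransmissionKernel:
    """Kernel from tabulated (tau, f) pairs; piecewise-linear interpolation.

    The table must start at tau = 0; f is taken as 0 beyond the last point.
    The sup bound is the max of the tabulated values (values between grid
    points are not checked).
    """
    tau = np.asarray(tau, dtype=float)
    f_vals = np.asarray(f_vals, dtype=float)
    if tau.ndim != 1 or tau.shape != f_vals.shape or tau[0] != 0.0:
        raise ValueError("need 1-d tables starting at tau = 0")
    if np.any(np.diff(tau) <= 0):
        raise ValueError("tau grid must be strictly increasing")
    if np.any(f_vals < 0):
        raise ValueError("f must be non-negative")
    cum_table = integrate.cumulative_trapezoid(f_vals, tau, initial=0.0)
    p = float(min(cum_table[-1], 1.0))

    return TransmissionKernel(
        evaluate=lambda x: np.interp(np.asarray(x, dtype=float), tau, f_vals,
                                     right=0.0),
        cumulative=lambda t: np.interp(np.asarray(t, dtype=float), tau, cum_table,
                                       right=cum_table[-1]),
        total_mass=p,
        sup_bound=float(f_vals.max(initial=0.0)),
        family="tabulated",
    )


def zero_kernel() -> TransmissionKernel:
    """Kernel of an edge that never transmits (f = 0)."""
    return TransmissionKernel(
        evaluate=lambda tau: np.zeros_like(np.asarray(tau, dtype=float)),
        cumulative=lambda t: np.zeros_like(np.asarray(t, dtype=float)),
        total_mass=0.0, sup_bound=0.0, family="zero",
    )


def exponential_recovery(gamma: float) -> RecoveryDensity:
    _require_positive(gamma=gamma)
    return RecoveryDensity(
        evaluate=lambda tau: gamma * np.exp(-gamma * np.asarray(tau, dtype=float)),
        survival=lambda tau: np.exp(-gamma * np.asarray(tau, dtype=float)),
        family="exponential", params=(gamma,),
    )


def gamma_recovery(shape: float, rate: float) -> RecoveryDensity:
    """Gamma(shape, rate) infectious period (continuous, vanishing at 0 for shape>1)."""
    _require_positive(shape=shape, rate=rate)
    from scipy.stats import gamma as gamma_dist
    dist = gamma_dist(a=shape, scale=1.0 / rate)
    return RecoveryDensity(
        evaluate=lambda tau: dist.pdf(np.asarray(tau, dtype=float)),
        survival=lambda tau: dist.sf(np.asarray(tau, dtype=float)),
        family="gamma", params=(shape, rate),
    )


def fixed_recovery(R: float) -> RecoveryDensity:
    """Non-random infectious period: point mass at R (survival = 1{tau < R})."""
    _require_positive(R=R)
    return RecoveryDensity(
        evaluate=None,
        survival=lambda tau: np.where(np.asarray(tau, dtype=float) < R, 1.0, 0.0),
        atom_at=R, family="fixed", params=(R,),
    )


def tabulate(kernel: TransmissionKernel, grid: TimeGrid):
    """Sample f on the grid and accumulate its integral by trapezoid.

    Returns ``(f_vals, cumulative)``; the trapezoid cumulative is what every
    solver in the package uses, so discretization errors are shared.
    """
    f_vals = np.asarray(kernel.evaluate(grid.times), dtype=float)
    return f_vals, trap_cumulative(f_vals, grid.dt)
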
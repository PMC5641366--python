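"""Stochastic network SIR: percolation simulator and exact small-network oracle.

Each individual i draws, once, an initial status Y_i (infective /
susceptible / recovered-vaccinated), an infectious period mu_i, and a
contact delay omega_{ji} for each neighbour j (the time from i's infection
to its contact of j).  i makes an infectious contact to j iff
omega_{ji} < mu_i, in which case the edge i -> j carries delay omega_{ji};
otherwise the edge never transmits.  Because all behaviour is drawn at
infection and fixed, infection times are exactly shortest-path (first
passage) times from the seed set through these delays — the simulator is a
static percolation computation, not an event queue.

Dependence within an individual is generated by a common Bernoulli shock
(:class:`mpsir.kernels.AssociationModel`): conditional on the shock the
delays and the infectious period are independent exponentials drawn by
inverse CDF, making each of {-mu, omega_j} a monotone function of
independent uniforms plus the one shared shock — an associated set.

For Markovian dynamics on at most 10 nodes,
:func:`forward_equations_markov` integrates the Kolmogorov forward (master)
equation over all 3^N network states and returns the exact per-node
marginals; it is the oracle used throughout the test-suite bound and
exactness checks.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import expm_multiply

from .model_io import NetworkModel, NodeInit, TimeGrid, Trajectory
from .kernels import AssociationModel

__all__ = [
    "IndividualDraw",
    "EpidemicRealization",
    "MarginalEstimate",
    "sample_individual",
    "simulate_epidemic",
    "estimate_marginals",
    "forward_equations_markov",
]


@dataclass
class IndividualDraw:
    """One individual's draw: initial status, infectious period, contact delays."""

    Y: int               # 1 infective, 2 susceptible, 3 recovered/vaccinated
    mu: float            # infectious period, in [0, inf]
    omega: np.ndarray    # per-neighbour contact delays, in [0, inf]


@dataclass
class EpidemicRealization:
    """Per-node infection/recovery times (inf = never) and the epidemic size."""

    infection_time: np.ndarray
    recovery_time: np.ndarray
    final_size: int  # initially susceptible nodes ever infected


@dataclass
class MarginalEstimate:
    """Replicate-averaged marginals with binomial Monte-Carlo standard errors."""

    grid: TimeGrid
    P_S: np.ndarray  # (nodes, T)
    P_I: np.ndarray
    P_R: np.ndarray
    replicates: int

    def stderr(self, which: str) -> np.ndarray:
        p = {"S": self.P_S, "I": self.P_I, "R": self.P_R}[which]
        return np.sqrt(p * (1.0 - p) / self.replicates)


def _shock_draws(model: AssociationModel, reps: int, node_count: int,
                 out_degrees: np.ndarray, rng: np.random.Generator):
    """Vectorized common-shock draws for all replicates and nodes.

    Returns (mu, omega) with mu shaped (reps, nodes) and omega a list of
    (reps, degree_i) arrays per node.
    """
    shock = rng.random((reps, node_count)) < model.pi
    gam = np.where(shock, model.gamma_fast, model.gamma_base)
    bet = np.where(shock, model.beta_slow, model.beta_base)
    # inverse-CDF from independent uniforms: monotone in the shared shock
    mu = -np.log(rng.random((reps, node_count))) / gam
    omega = []
    for i in range(node_count):
        d = int(out_degrees[i])
        u = rng.random((reps, d))
        omega.append(-np.log(u) / bet[:, [i]])
    return mu, omega


def sample_individual(model: AssociationModel, degree: int,
                      rng: np.random.Generator,
                      z: float = 0.0, y: float = 0.0) -> IndividualDraw:
    """Draw one individual's behaviour (and initial status from (z, y))."""
    mu, omega = _shock_draws(model, 1, 1, np.array([degree]), rng)
    u = rng.random()
    Y = 2 if u < z else (3 if u < z + y else 1)
    return IndividualDraw(Y=Y, mu=float(mu[0, 0]), omega=omega[0][0].copy())


def _percolate(network: NetworkModel, Y: np.ndarray, mu: np.ndarray,
               omega_edges: np.ndarray, edge_src: np.ndarray,
               edge_dst: np.ndarray) -> np.ndarray:
    """Vectorized first-passage times over replicates.

    omega_edges[(rep, e)] is the contact delay along directed edge e
    (src -> dst); transmission requires omega < mu of the source.  Repeated
    edge relaxation (Bellman-Ford over at most node_count rounds) suffices
    on the small graphs this package targets.
    """
    reps, n = Y.shape
    delay = np.where(omega_edges < mu[:, edge_src], omega_edges, np.inf)
    T = np.where(Y == 1, 0.0, np.inf)
    infectable = Y == 2
    for _ in range(max(n - 1, 1)):
        cand = T[:, edge_src] + delay
        changed = False
        for e in range(edge_src.size):
            j = edge_dst[e]
            better = infectable[:, j] & (cand[:, e] < T[:, j])
            if np.any(better):
                T[better, j] = cand[better, e]
                changed = True
        if not changed:
            break
    return T


def _edge_arrays(network: NetworkModel):
    """Directed edge list grouped by source, plus per-node out-degrees."""
    src, dst = [], []
    for i, nbrs in enumerate(network.neighbours):
        for j in nbrs:
            src.append(i)
            dst.append(j)
    src = np.asarray(src, dtype=int)
    dst = np.asarray(dst, dtype=int)
    out_deg = np.bincount(src, minlength=network.node_count)
    return src, dst, out_deg


def _run_replicates(network: NetworkModel, model: AssociationModel,
                    init: NodeInit, reps: int, rng: np.random.Generator):
    n = network.node_count
    src, dst, out_deg = _edge_arrays(network)
    u = rng.random((reps, n))
    Y = np.where(u < init.z, 2, np.where(u < init.z + init.y, 3, 1))
    mu, omega = _shock_draws(model, reps, n, out_deg, rng)
    # flatten per-node omega blocks into directed-edge order
    omega_edges = np.empty((reps, src.size))
    pos = 0
    for i in range(n):
        d = int(out_deg[i])
        omega_edges[:, pos:pos + d] = omega[i]
        pos += d
    T_inf = _percolate(network, Y, mu, omega_edges, src, dst)
    with np.errstate(invalid="ignore"):
        T_rec = T_inf + mu
    return Y, T_inf, T_rec


def simulate_epidemic(network: NetworkModel, model: AssociationModel,
                      init: NodeInit,
                      rng: np.random.Generator) -> EpidemicRealization:
    """One realization of the stochastic epidemic via percolation."""
    Y, T_inf, T_rec = _run_replicates(network, model, init, 1, rng)
    Y, T_inf, T_rec = Y[0], T_inf[0], T_rec[0]
    T_rec = np.where(np.isfinite(T_inf), T_rec, np.inf)
    size = int(np.sum((Y == 2) & np.isfinite(T_inf)))
    return EpidemicRealization(infection_time=T_inf, recovery_time=T_rec,
                               final_size=size)


def estimate_marginals(network: NetworkModel, model: AssociationModel,
                       init: NodeInit, grid: TimeGrid, replicates: int,
                       seed: int) -> MarginalEstimate:
    """Empirical per-node P_S/P_I/P_R on the grid from seeded replicates.

    Sorting each node's infection and recovery times turns the grid
    evaluation into two searchsorted passes, so memory stays
    O(replicates + grid).
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    Y, T_inf, T_rec = _run_replicates(network, model, init, replicates, rng)
    times = grid.times
    n = network.node_count
    P_S = np.empty((n, times.size))
    P_R = np.empty((n, times.size))
    for i in range(n):
        susceptible = Y[:, i] == 2
        inf_times = np.sort(T_inf[susceptible, i])
        # susceptible at t: initially susceptible and not yet infected
        P_S[i] = (susceptible.sum()
                  - np.searchsorted(inf_times, times, side="right")
                  ) / replicates
        ever_infected = np.isfinite(T_inf[:, i])
        rec_times = np.sort(T_rec[ever_infected, i])
        n_vacc = int(np.sum(Y[:, i] == 3))
        P_R[i] = (n_vacc + np.searchsorted(rec_times, times, side="right")
                  ) / replicates
    P_I = 1.0 - P_S - P_R
    return MarginalEstimate(grid=grid, P_S=P_S, P_I=P_I, P_R=P_R,
                            replicates=replicates)


def forward_equations_markov(network: NetworkModel, beta: float, gamma: float,
                             init: NodeInit, grid: TimeGrid) -> Trajectory:
    """Exact marginals from the 3^N Kolmogorov forward equations.

    State space {S, I, R}^N encoded base-3 (digit 0/1/2 = S/I/R); the
    initial law is the product of per-node (z, 1-z-y, y); the generator has
    per-node recovery at rate gamma and infection at rate
    beta * (number of infected neighbours).  The linear master equation is
    propagated by Krylov matrix-exponential action on the whole grid.
    """
    n = network.node_count
    if n > 10:
        raise ValueError("master-equation oracle limited to 10 nodes (3^N states)")
    if n * math.log(3) > 700:  # pragma: no cover - unreachable given cap
        raise ValueError("state space too large")
    if init.node_count != n:
        raise ValueError("initial conditions and network disagree on node count")
    dim = 3 ** n
    states = np.arange(dim)
    digits = np.empty((n, dim), dtype=np.int8)
    for i in range(n):
        digits[i] = (states // 3 ** i) % 3

    rows, cols, vals = [], [], []
    diag = np.zeros(dim)
    nbrs = network.neighbours
    for i in range(n):
        place = 3 ** i
        # recovery I -> R
        mask = digits[i] == 1
        frm = states[mask]
        rows.append(frm + place)   # digit 1 -> 2
        cols.append(frm)
        vals.append(np.full(frm.size, gamma))
        diag[frm] -= gamma
        # infection S -> I at rate beta * (# infected neighbours)
        mask = digits[i] == 0
        if nbrs[i]:
            n_inf = np.zeros(dim)
            for j in nbrs[i]:
                n_inf += digits[j] == 1
            rate = beta * n_inf[states[mask]]
            frm = states[mask][rate > 0]
            rate = rate[rate > 0]
            rows.append(frm + place)   # digit 0 -> 1
            cols.append(frm)
            vals.append(rate)
            diag[frm] -= rate
    rows.append(states)
    cols.append(states)
    vals.append(diag)
    Q = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(dim, dim))

    p0 = np.ones(dim)
    for i in range(n):
        node_probs = np.array([init.z[i], 1.0 - init.z[i] - init.y[i],
                               init.y[i]])
        p0 *= node_probs[digits[i]]

    P = expm_multiply(Q, p0, start=0.0, stop=grid.t_max,
                      num=grid.times.size, endpoint=True)

    S = np.empty((n, grid.times.size))
    I = np.empty_like(S)
    R = np.empty_like(S)
    for i in range(n):
        for c, out in ((0, S), (1, I), (2, R)):
            mask = digits[i] == c
            out[i] = P[:, mask].sum(axis=1)
    return Trajectory(grid, S, I, R)
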
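"""Graphs, initial conditions, time grids and trajectory I/O.

The contact structure is a finite simple undirected graph.  Initial
conditions are per-node probabilities ``z`` (initially susceptible) and ``y``
(initially recovered/vaccinated); the remaining mass ``1 - z - y`` is the
probability of being an initial infective.  All solvers operate on one
uniform time grid so that convolution quadrature and cross-model comparisons
are exactly grid-aligned.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "NetworkModel",
    "NodeInit",
    "TimeGrid",
    "Trajectory",
    "load_edge_list",
    "make_symmetric_graph",
    "is_tree",
    "write_trajectory",
    "read_trajectory",
]

#: graph families whose bundled generators are genuinely arc-transitive
#: (every ordered neighbour pair is equivalent under an automorphism), so the
#: homogeneous solvers apply.  ``star`` and ``balanced_tree`` are provided for
#: tree-exactness tests only and are NOT symmetric.
SYMMETRIC_FAMILIES = ("complete", "cycle", "ring_lattice")


@dataclass(frozen=True)
class NetworkModel:
    """Finite simple undirected graph with 0-based contiguous node ids."""

    node_count: int
    edges: frozenset  # frozenset of frozenset({u, v}) pairs
    node_labels: tuple = None  # original ids, position = internal index

    @property
    def neighbours(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.node_count)]
        for e in self.edges:
            u, v = sorted(e)
            adj[u].append(v)
            adj[v].append(u)
        return [sorted(a) for a in adj]

    @property
    def directed_edges(self) -> list[tuple[int, int]]:
        """All ordered pairs (i, j) with {i, j} an edge."""
        out = []
        for e in self.edges:
            u, v = sorted(e)
            out.append((u, v))
            out.append((v, u))
        return sorted(out)

    @property
    def edge_count(self) -> int:
        return len(self.edges)

    def degree(self, i: int) -> int:
        return len(self.neighbours[i])

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.node_count))
        g.add_edges_from(tuple(sorted(e)) for e in self.edges)
        return g

    def __post_init__(self):
        if self.node_count < 0:
            raise ValueError("node_count must be non-negative")
        for e in self.edges:
            u, v = sorted(e)
            if u == v:
                raise ValueError(f"self-loop at node {u}")
            if not (0 <= u < self.node_count and 0 <= v < self.node_count):
                raise ValueError(f"edge ({u},{v}) outside node range")


def _build(edges: Sequence[tuple[int, int]], node_count: int | None = None,
           labels: Sequence | None = None) -> NetworkModel:
    eset = set()
    for u, v in edges:
        if u == v:
            raise ValueError(f"self-loop at node {u}")
        key = frozenset((u, v))
        if key in eset:
            raise ValueError(f"duplicate edge ({u},{v})")
        eset.add(key)
    if node_count is None:
        node_count = (max((max(e) for e in eset), default=-1) + 1) if eset else 0
    return NetworkModel(node_count=node_count, edges=frozenset(eset),
                        node_labels=tuple(labels) if labels is not None else None)


def load_edge_list(path, node_count: int | None = None) -> NetworkModel:
    """Load a graph from a CSV edge list with header ``u,v``.

    Arbitrary integer node ids are remapped to 0-based contiguous indices
    (sorted by original id); the original ids are recorded in
    ``node_labels``.  ``node_count`` overrides the inferred count so that
    isolated trailing nodes can be represented.
    """
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [c.strip().lower() for c in header[:2]] != ["u", "v"]:
            raise ValueError(f"{path}: expected CSV header 'u,v'")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            try:
                u, v = int(row[0]), int(row[1])
            except (ValueError, IndexError):
                raise ValueError(f"{path}: non-integer node id on row {lineno}")
            if u == v:
                raise ValueError(f"{path}: self-loop on row {lineno}")
            rows.append((u, v))
    ids = sorted({u for u, _ in rows} | {v for _, v in rows})
    remap = {orig: k for k, orig in enumerate(ids)}
    edges = [(remap[u], remap[v]) for u, v in rows]
    n = len(ids)
    if node_count is not None:
        if node_count < n:
            raise ValueError("node_count override smaller than ids present")
        ids = ids + [None] * (node_count - n)
        n = node_count
    return _build(edges, node_count=n, labels=ids)


def make_symmetric_graph(family: str, **params) -> NetworkModel:
    """Construct a named graph family.

    ``complete`` (m), ``cycle`` (length), ``ring_lattice`` (length, k
    neighbours each side), ``star`` (leaves) and ``balanced_tree``
    (branching, height).  The first three are arc-transitive, matching the
    homogeneous model's symmetry assumption; the trees are for exactness
    tests.
    """
    if family == "complete":
        m = int(params["m"])
        if m < 2:
            raise ValueError("complete graph needs m >= 2")
        g = nx.complete_graph(m)
    elif family == "cycle":
        length = int(params["length"])
        if length < 3:
            raise ValueError("cycle needs length >= 3")
        g = nx.cycle_graph(length)
    elif family == "ring_lattice":
        length = int(params["length"])
        k = int(params.get("k", 1))
        if length < 3 or k < 1 or 2 * k >= length:
            raise ValueError("ring lattice needs length >= 3 and 1 <= k < length/2")
        g = nx.circulant_graph(length, list(range(1, k + 1)))
    elif family in ("star", "star_for_tree_tests"):
        leaves = int(params["leaves"])
        if leaves < 1:
            raise ValueError("star needs >= 1 leaf")
        g = nx.star_graph(leaves)
    elif family == "balanced_tree":
        branching = int(params["branching"])
        height = int(params["height"])
        if branching < 1 or height < 0:
            raise ValueError("invalid balanced tree parameters")
        g = nx.balanced_tree(branching, height)
    elif family == "path":
        length = int(params["length"])
        if length < 1:
            raise ValueError("path needs >= 1 node")
        g = nx.path_graph(length)
    else:
        raise ValueError(f"unknown graph family {family!r}")
    return _build(list(g.edges()), node_count=g.number_of_nodes())


def is_tree(network: NetworkModel) -> bool:
    """True iff the graph is acyclic (a forest counts)."""
    return nx.is_forest(network.to_networkx())


@dataclass(frozen=True)
class NodeInit:
    """Per-node initial-condition probabilities.

    ``z[i] = P(node i initially susceptible)``, ``y[i] = P(initially
    recovered/vaccinated)``; ``1 - z[i] - y[i]`` is the probability of being
    an initial infective.  Independent across nodes.
    """

    z: np.ndarray
    y: np.ndarray

    @classmethod
    def homogeneous(cls, node_count: int, z: float, y: float = 0.0) -> "NodeInit":
        return cls(np.full(node_count, float(z)), np.full(node_count, float(y)))

    def __post_init__(self):
        z = np.atleast_1d(np.asarray(self.z, dtype=float))
        y = np.atleast_1d(np.asarray(self.y, dtype=float))
        if z.shape != y.shape:
            raise ValueError("z and y must have the same length")
        if np.any(z < 0) or np.any(y < 0) or np.any(z + y > 1 + 1e-12):
            raise ValueError("need 0 <= z_i, 0 <= y_i and z_i + y_i <= 1")
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "y", y)

    @property
    def node_count(self) -> int:
        return self.z.size


@dataclass(frozen=True)
class TimeGrid:
    """Uniform grid 0, dt, ..., t_max; t_max must be a multiple of dt."""

    t_max: float
    dt: float
    times: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if self.dt <= 0 or self.t_max <= 0:
            raise ValueError("t_max and dt must be positive")
        steps = self.t_max / self.dt
        n = round(steps)
        if abs(steps - n) > 1e-9 * max(1.0, abs(steps)):
            raise ValueError("t_max must be an integer multiple of dt")
        object.__setattr__(self, "times", np.linspace(0.0, self.t_max, n + 1))

    @property
    def n_steps(self) -> int:
        return self.times.size - 1

    def index_of(self, t: float) -> int:
        """Grid index of time t; t must lie on the grid."""
        k = round(t / self.dt)
        if abs(t - k * self.dt) > 1e-9 * max(1.0, abs(t)):
            raise ValueError(f"t={t} is not on the grid (dt={self.dt})")
        return int(k)


@dataclass
class Trajectory:
    """S/I/R time courses on a grid; per-node arrays have shape (nodes, T)."""

    grid: TimeGrid
    S: np.ndarray
    I: np.ndarray
    R: np.ndarray

    @property
    def per_node(self) -> bool:
        return np.asarray(self.S).ndim == 2

    def mean(self) -> "Trajectory":
        """Average over nodes (identity for population-level trajectories)."""
        if not self.per_node:
            return self
        return Trajectory(self.grid, self.S.mean(axis=0),
                          self.I.mean(axis=0), self.R.mean(axis=0))

    def validate(self, conservation_tol: float = 1e-9,
                 monotone_tol: float = 1e-6) -> None:
        S, I, R = (np.atleast_2d(a) for a in (self.S, self.I, self.R))
        if np.max(np.abs(S + I + R - 1.0)) > conservation_tol:
            raise ValueError("S + I + R deviates from 1 beyond tolerance")
        if np.max(np.diff(S, axis=1)) > monotone_tol:
            raise ValueError("S is increasing beyond tolerance")
        if np.min(np.diff(R, axis=1)) < -monotone_tol:
            raise ValueError("R is decreasing beyond tolerance")


def write_trajectory(trajectory: Trajectory, path) -> None:
    """Write a trajectory as CSV ``t,S,I,R`` (per-node adds a ``node`` column)."""
    t = trajectory.grid.times
    if trajectory.per_node:
        n = trajectory.S.shape[0]
        frames = []
        for i in range(n):
            frames.append(pd.DataFrame({
                "node": i, "t": t,
                "S": trajectory.S[i], "I": trajectory.I[i], "R": trajectory.R[i],
            }))
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame({"t": t, "S": trajectory.S,
                           "I": trajectory.I, "R": trajectory.R})
    df.to_csv(path, index=False, float_format="%.12g")


def read_trajectory(path) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory`."""
    df = pd.read_csv(path)
    if "node" in df.columns:
        nodes = sorted(df["node"].unique())
        t = df[df["node"] == nodes[0]]["t"].to_numpy()
        grid = TimeGrid(t_max=float(t[-1]), dt=float(t[1] - t[0]))
        S = np.vstack([df[df["node"] == i]["S"].to_numpy() for i in nodes])
        I = np.vstack([df[df["node"] == i]["I"].to_numpy() for i in nodes])
        R = np.vstack([df[df["node"] == i]["R"].to_numpy() for i in nodes])
    else:
        t = df["t"].to_numpy()
        grid = TimeGrid(t_max=float(t[-1]), dt=float(t[1] - t[0]))
        S, I, R = (df[c].to_numpy() for c in ("S", "I", "R"))
    return Trajectory(grid, S, I, R)
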
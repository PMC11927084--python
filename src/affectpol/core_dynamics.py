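"""Primitive types and the node-level choice-update rule.

The model describes a population split into two antagonistic groups
(blue = 0, red = 1) in which every individual holds a binary choice
``H(v)`` (mask / don't mask, adopt / don't adopt).  A node revising its
choice looks at the fractions of its neighbors, split by group match and
current choice, and feels a signed social drive

    drive = alpha * (in1 - in0) - beta * (out1 - out0)

where ``alpha`` weighs conformity with the in-group and ``beta`` weighs
opposition to the out-group.  The node switches to choice 1 when the
drive exceeds the inertia threshold ``delta``, to choice 0 when it falls
below ``-delta``, and otherwise keeps its current choice.

Graphs are stored in CSR (compressed sparse row) adjacency form so the
same arrays feed the pure-Python API, the vectorized bookkeeping and the
compiled agent-based inner loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

import numpy as np
import networkx as nx
import scipy.sparse as sp

BLUE = 0
RED = 1


class IsolatedNodeError(ValueError):
    """Raised when the update rule is applied to a degree-0 node.

    The neighbor fractions divide by the degree, so the rule is
    undefined for isolated nodes; callers must either remove them or
    run the scheduler with ``tolerate_isolates``.
    """


@dataclass(frozen=True)
class ModelParams:
    """Behavioral constants of the choice-adoption model.

    Parameters
    ----------
    alpha : float
        In-group-love weight (conformity with same-group neighbors),
        in [0, 1].
    beta : float
        Out-group-hate weight (opposition to other-group neighbors),
        in [0, 1].
    delta : float
        Inertia threshold: the net drive must exceed ``delta`` in
        magnitude for a node to change its choice. In [0, 1].
    rho : float
        Homophily level in (0, 1); 0.5 is neutral mixing. Only used by
        the block-model mean field and the block-model graph generator.
    """

    alpha: float
    beta: float
    delta: float = 0.0
    rho: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError(f"beta must be in [0, 1], got {self.beta}")
        if not (0.0 <= self.delta <= 1.0):
            raise ValueError(f"delta must be in [0, 1], got {self.delta}")
        if not (0.0 < self.rho < 1.0):
            raise ValueError(f"rho must be in (0, 1), got {self.rho}")


@dataclass(frozen=True)
class NeighborStats:
    """Fractions of a node's neighbors by (group match, choice).

    ``in0 + in1 + out0 + out1 == 1`` for any node of degree >= 1.
    """

    in0: float
    in1: float
    out0: float
    out1: float


@dataclass(frozen=True)
class StateVector:
    """Group-level adoption fractions, always ordered (blue, red)."""

    thetaB: float
    thetaR: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.thetaB <= 1.0 and 0.0 <= self.thetaR <= 1.0):
            raise ValueError(f"state components must lie in [0, 1]: {self}")

    def as_array(self) -> np.ndarray:
        return np.array([self.thetaB, self.thetaR], dtype=float)


@dataclass
class LabeledGraph:
    """Undirected simple graph with optional binary group labels.

    Nodes are 0-based contiguous integers.  Adjacency is held in CSR
    form (``indptr``/``indices``); each undirected edge appears in both
    rows.  ``labels[v]`` is 0 (blue) or 1 (red); ``labels`` may be
    ``None`` for an unlabeled topology.
    """

    n: int
    indptr: np.ndarray
    indices: np.ndarray
    labels: Optional[np.ndarray] = None
    id_map: Optional[dict] = field(default=None, repr=False)  # original -> internal

    # ---- constructors -------------------------------------------------

    @classmethod
    def from_edges(
        cls, n: int, edges: np.ndarray, labels: Optional[np.ndarray] = None
    ) -> "LabeledGraph":
        """Build from an (m, 2) integer array; dedups and drops self-loops."""
        edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
        if edges.size and (edges.min() < 0 or edges.max() >= n):
            raise ValueError("edge endpoint out of range")
        keep = edges[:, 0] != edges[:, 1]
        edges = edges[keep]
        lo = np.minimum(edges[:, 0], edges[:, 1])
        hi = np.maximum(edges[:, 0], edges[:, 1])
        if lo.size:
            uniq = np.unique(lo * np.int64(n) + hi)
            lo, hi = uniq // n, uniq % n
        src = np.concatenate([lo, hi])
        dst = np.concatenate([hi, lo])
        order = np.argsort(src, kind="stable")
        src, dst = src[order], dst[order]
        indptr = np.zeros(n + 1, dtype=np.int64)
        np.add.at(indptr, src + 1, 1)
        np.cumsum(indptr, out=indptr)
        return cls(n=n, indptr=indptr, indices=dst.astype(np.int32),
                   labels=_check_labels(labels, n))

    @classmethod
    def complete(cls, n: int, labels: Optional[np.ndarray] = None) -> "LabeledGraph":
        """Complete graph on ``n`` nodes (every pair connected)."""
        if n < 2:
            raise ValueError("complete graph needs at least 2 nodes")
        base = np.arange(n, dtype=np.int32)
        # row v lists all nodes except v
        indices = np.empty(n * (n - 1), dtype=np.int32)
        for v in range(n):
            row = indices[v * (n - 1):(v + 1) * (n - 1)]
            row[:v] = base[:v]
            row[v:] = base[v + 1:]
        indptr = np.arange(0, n * (n - 1) + 1, n - 1, dtype=np.int64)
        return cls(n=n, indptr=indptr, indices=indices,
                   labels=_check_labels(labels, n))

    @classmethod
    def from_networkx(cls, g: nx.Graph, labels: Optional[np.ndarray] = None) -> "LabeledGraph":
        nodes = sorted(g.nodes())
        if nodes != list(range(g.number_of_nodes())):
            raise ValueError("networkx graph must have contiguous 0-based int nodes")
        edges = np.array(list(g.edges()), dtype=np.int64).reshape(-1, 2)
        return cls.from_edges(g.number_of_nodes(), edges, labels)

    # ---- views --------------------------------------------------------

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(map(tuple, self.edge_array()))
        if self.labels is not None:
            nx.set_node_attributes(
                g, {v: int(self.labels[v]) for v in range(self.n)}, "group"
            )
        return g

    def edge_array(self) -> np.ndarray:
        """(m, 2) array with each undirected edge listed once, u < v."""
        src = np.repeat(np.arange(self.n), np.diff(self.indptr))
        dst = self.indices
        mask = src < dst
        return np.column_stack([src[mask], dst[mask]]).astype(np.int64)

    def to_sparse(self) -> sp.csr_array:
        data = np.ones(len(self.indices), dtype=np.int64)
        return sp.csr_array((data, self.indices, self.indptr), shape=(self.n, self.n))

    def neighbors(self, node: int) -> np.ndarray:
        return self.indices[self.indptr[node]:self.indptr[node + 1]]

    def degree(self, node: int) -> int:
        return int(self.indptr[node + 1] - self.indptr[node])

    @property
    def degrees(self) -> np.ndarray:
        return np.diff(self.indptr)

    @property
    def n_edges(self) -> int:
        return len(self.indices) // 2

    @property
    def n_red(self) -> int:
        self._require_labels()
        return int(self.labels.sum())

    @property
    def red_fraction(self) -> float:
        return self.n_red / self.n

    def with_labels(self, labels: np.ndarray) -> "LabeledGraph":
        return replace(self, labels=_check_labels(labels, self.n))

    def _require_labels(self) -> None:
        if self.labels is None:
            raise ValueError("graph has no group labels")

    def iter_edges(self) -> Iterator[tuple[int, int]]:
        yield from map(tuple, self.edge_array())


def _check_labels(labels: Optional[np.ndarray], n: int) -> Optional[np.ndarray]:
    if labels is None:
        return None
    labels = np.asarray(labels, dtype=np.int8)
    if labels.shape != (n,):
        raise ValueError(f"labels must have shape ({n},)")
    if labels.size and not np.isin(labels, [BLUE, RED]).all():
        raise ValueError("labels must be 0 (blue) or 1 (red)")
    return labels


# ---- node-level rule --------------------------------------------------


def neighbor_stats(graph: LabeledGraph, choices: np.ndarray, node: int) -> NeighborStats:
    """Normalized neighbor counts by (group match, choice) for ``node``.

    Returns the four fractions (in0, in1, out0, out1); they sum to 1.
    Raises :class:`IsolatedNodeError` for a degree-0 node.
    """
    graph._require_labels()
    nbrs = graph.neighbors(node)
    d = len(nbrs)
    if d == 0:
        raise IsolatedNodeError(f"node {node} is isolated; update rule undefined")
    same = graph.labels[nbrs] == graph.labels[node]
    h = choices[nbrs].astype(bool)
    in1 = int(np.count_nonzero(same & h))
    in0 = int(np.count_nonzero(same & ~h))
    out1 = int(np.count_nonzero(~same & h))
    out0 = d - in1 - in0 - out1
    return NeighborStats(in0 / d, in1 / d, out0 / d, out1 / d)


def drive(stats: NeighborStats, params: ModelParams) -> float:
    """Signed social drive alpha*(in1-in0) - beta*(out1-out0), in [-1, 1]."""
    return params.alpha * (stats.in1 - stats.in0) - params.beta * (stats.out1 - stats.out0)


def update_choice(
    graph: LabeledGraph, choices: np.ndarray, node: int, params: ModelParams
) -> int:
    """New choice for ``node``: 1 if drive > delta, 0 if drive < -delta,
    else the current choice.  Boundary drives (== +/-delta) keep the
    current choice — the inequalities are strict, compared exactly."""
    g = drive(neighbor_stats(graph, choices, node), params)
    if g > params.delta:
        return 1
    if g < -params.delta:
        return 0
    return int(choices[node])


def group_state(graph: LabeledGraph, choices: np.ndarray) -> StateVector:
    """Per-group fraction of nodes currently at choice 1, as (blue, red)."""
    graph._require_labels()
    labels = graph.labels
    choices = np.asarray(choices)
    n_red = int(labels.sum())
    n_blue = graph.n - n_red
    if n_red == 0 or n_blue == 0:
        raise ValueError("both groups must be nonempty to define the group state")
    ones_red = int(choices[labels == RED].sum())
    ones_blue = int(choices[labels == BLUE].sum())
    return StateVector(ones_blue / n_blue, ones_red / n_red)
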
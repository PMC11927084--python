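"""Graph generation, label assignment and edge-list I/O.

Provides the graph families the dynamics run on: complete graphs,
binomial (Erdos–Renyi-like) graphs, and two-block stochastic block
models parameterized by the homophily level rho (within-group edge
probability c*rho, cross-group c*(1-rho), with a global density
multiplier c).  Label machinery covers uniformly random red/blue
assignment, assortativity-targeted assignment via simulated annealing on
label swaps, and the standard categorical (Newman) assortativity
coefficient.  Edge lists use the plain-text SNAP dialect: two
whitespace-separated integer ids per line, '#' comments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .core_dynamics import BLUE, RED, LabeledGraph

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


@dataclass(frozen=True)
class SBMSpec:
    """Two-block stochastic block model specification.

    Within-group pairs connect with probability ``density * rho``,
    cross-group pairs with ``density * (1 - rho)``.  The default
    density keeps desk-scale graphs sparse; with no inertia the
    dynamics depend on neighbor composition ratios, not density.
    """

    n: int
    r: float
    rho: float
    density: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least 2 nodes")
        if not (0.0 < self.r < 1.0):
            raise ValueError(f"r must be in (0, 1), got {self.r}")
        if not (0.0 < self.rho < 1.0):
            raise ValueError(f"rho must be in (0, 1), got {self.rho}")
        if not (0.0 < self.density <= 1.0):
            raise ValueError(f"density must be in (0, 1], got {self.density}")
        for p in (self.p_within, self.p_cross):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"edge probability {p} outside [0, 1]")

    @property
    def p_within(self) -> float:
        return self.density * self.rho

    @property
    def p_cross(self) -> float:
        return self.density * (1.0 - self.rho)


@dataclass(frozen=True)
class AssignmentSpec:
    """Assortativity-targeted red/blue assignment request."""

    r: float
    target_assortativity: Optional[float] = None
    seed: int = 0
    tol: float = 0.02
    max_iter: int = 200_000

    def __post_init__(self) -> None:
        if not (0.0 < self.r < 1.0):
            raise ValueError(f"r must be in (0, 1), got {self.r}")
        t = self.target_assortativity
        if t is not None and not (-1.0 < t < 1.0):
            raise ValueError(f"target assortativity must be in (-1, 1), got {t}")


def complete_graph(n: int) -> LabeledGraph:
    """Complete (fully connected) simple graph on ``n`` nodes."""
    return LabeledGraph.complete(n)


def binomial_graph(n: int, p: float, seed: Optional[int] = None) -> LabeledGraph:
    """Erdos–Renyi-like graph: each pair linked independently with prob p."""
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    mask = rng.random(len(iu[0])) < p
    edges = np.column_stack([iu[0][mask], iu[1][mask]])
    return LabeledGraph.from_edges(n, edges)


def sbm_graph(spec: SBMSpec, labels: np.ndarray, seed: Optional[int] = None) -> LabeledGraph:
    """Sample a two-block SBM respecting the given red/blue labels.

    Every within-group pair is linked independently with probability
    ``density*rho`` and every cross-group pair with ``density*(1-rho)``;
    at rho=0.5 this reduces to a binomial random graph.
    """
    labels = np.asarray(labels, dtype=np.int8)
    if labels.shape != (spec.n,):
        raise ValueError(f"labels must have shape ({spec.n},)")
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(spec.n, k=1)
    same = labels[iu] == labels[ju]
    p = np.where(same, spec.p_within, spec.p_cross)
    mask = rng.random(len(iu)) < p
    edges = np.column_stack([iu[mask], ju[mask]])
    return LabeledGraph.from_edges(spec.n, edges, labels=labels)


def random_labels(n: int, r: float, seed: Optional[int] = None) -> np.ndarray:
    """Uniformly random labels with exactly round(r*n) red nodes."""
    if not (0.0 < r < 1.0):
        raise ValueError(f"r must be in (0, 1), got {r}")
    n_red = int(math.floor(r * n + 0.5))
    rng = np.random.default_rng(seed)
    labels = np.zeros(n, dtype=np.int8)
    labels[rng.choice(n, size=n_red, replace=False)] = RED
    return labels


def assign_random(graph: LabeledGraph, r: float, seed: Optional[int] = None) -> np.ndarray:
    """Uniformly random red/blue assignment on a graph's node set."""
    return random_labels(graph.n, r, seed=seed)


def party_assortativity(graph: LabeledGraph, labels: Optional[np.ndarray] = None) -> float:
    """Newman categorical assortativity of the red/blue labels over edges.

    Computed from the 2x2 edge mixing matrix e (fractions of directed
    edge ends by endpoint labels): (tr e - sum(e @ e)) / (1 - sum(e @ e)).
    +1 means perfectly homophilic mixing, negative values heterophilic.
    """
    if labels is None:
        graph._require_labels()
        labels = graph.labels
    labels = np.asarray(labels, dtype=np.int8)
    edges = graph.edge_array()
    if len(edges) == 0:
        raise ValueError("graph has no edges; assortativity undefined")
    lu = labels[edges[:, 0]].astype(np.int64)
    lv = labels[edges[:, 1]].astype(np.int64)
    e = np.zeros((2, 2), dtype=float)
    np.add.at(e, (lu, lv), 1.0)
    np.add.at(e, (lv, lu), 1.0)
    e /= e.sum()
    s = (e @ e).sum()
    if s == 1.0:
        # all edge ends carry a single label: mixing is degenerate
        raise ValueError("both label values must appear among edge endpoints")
    return float((np.trace(e) - s) / (1.0 - s))


class AssortativityTargetError(RuntimeError):
    """Annealing could not reach the requested assortativity."""

    def __init__(self, target: float, best: float):
        super().__init__(
            f"could not reach target assortativity {target:+.3f}; "
            f"best achieved {best:+.3f}"
        )
        self.target = target
        self.best = best


def assign_assortative(graph: LabeledGraph, spec: AssignmentSpec) -> np.ndarray:
    """Labels with exact red count and assortativity near a target.

    Starts from a uniformly random assignment with round(r*N) red nodes
    and anneals pairwise red/blue label swaps (which preserve the group
    sizes exactly) toward |assortativity - target| = 0 with geometric
    cooling.  ``target_assortativity=None`` returns the random
    assignment unchanged.
    """
    labels = assign_random(graph, spec.r, seed=spec.seed)
    if spec.target_assortativity is None:
        return labels
    target = spec.target_assortativity
    rng = np.random.default_rng(spec.seed)

    edges = graph.edge_array()
    lu = labels[edges[:, 0]]
    lv = labels[edges[:, 1]]
    # directed edge-end mixing counts; updated incrementally under swaps
    counts = np.zeros((2, 2), dtype=np.int64)
    np.add.at(counts, (lu.astype(np.int64), lv.astype(np.int64)), 1)
    np.add.at(counts, (lv.astype(np.int64), lu.astype(np.int64)), 1)
    total = counts.sum()

    adj_indptr, adj_indices = graph.indptr, graph.indices

    def score(c: np.ndarray) -> float:
        e = c / total
        s = (e @ e).sum()
        if s == 1.0:
            return -2.0  # degenerate; never better than any real value
        return float((np.trace(e) - s) / (1.0 - s))

    def apply_swap(c: np.ndarray, u: int, v: int, lab: np.ndarray) -> np.ndarray:
        """Mixing counts after swapping the labels of u (red) and v (blue)."""
        c = c.copy()
        adjacent = False
        for node, other in ((u, v), (v, u)):
            old = lab[node]
            new = 1 - old
            for w in adj_indices[adj_indptr[node]:adj_indptr[node + 1]]:
                if w == other:
                    adjacent = True  # handled once below
                    continue
                lw = lab[w]
                c[old, lw] -= 1
                c[lw, old] -= 1
                c[new, lw] += 1
                c[lw, new] += 1
        if adjacent:
            ou, ov = lab[u], lab[v]
            c[ou, ov] -= 1
            c[ov, ou] -= 1
            c[1 - ou, 1 - ov] += 1
            c[1 - ov, 1 - ou] += 1
        return c

    current = score(counts)
    best = current
    best_labels = labels.copy()
    n_steps = spec.max_iter
    # temperature on the scale of a single swap's assortativity change
    temp0, temp1 = 0.002, 1e-6
    cool = (temp1 / temp0) ** (1.0 / max(n_steps - 1, 1))
    temp = temp0
    reds = np.flatnonzero(labels == RED)
    blues = np.flatnonzero(labels == BLUE)
    red_pos = {int(v): i for i, v in enumerate(reds)}
    blue_pos = {int(v): i for i, v in enumerate(blues)}

    for _ in range(n_steps):
        u = int(reds[rng.integers(len(reds))])
        v = int(blues[rng.integers(len(blues))])
        new_counts = apply_swap(counts, u, v, labels)
        cand = score(new_counts)
        gain = abs(current - target) - abs(cand - target)
        if gain >= 0 or rng.random() < math.exp(gain / temp):
            counts = new_counts
            current = cand
            labels[u], labels[v] = BLUE, RED
            iu_, iv_ = red_pos.pop(u), blue_pos.pop(v)
            reds[iu_], blues[iv_] = v, u
            red_pos[v], blue_pos[u] = iu_, iv_
            if abs(current - target) < abs(best - target):
                best = current
                best_labels = labels.copy()
            if abs(current - target) <= spec.tol * 0.5:
                return labels
        temp *= cool

    if abs(best - target) <= spec.tol:
        return best_labels
    raise AssortativityTargetError(target, best)


# ---- edge-list I/O ----------------------------------------------------


def read_edgelist(path: PathLike, mapping_path: Optional[PathLike] = None) -> LabeledGraph:
    """Read a SNAP-dialect edge list into an unlabeled graph.

    Arbitrary integer ids are remapped to contiguous 0..N-1 (sorted by
    original id); the mapping is kept on the returned graph's
    ``id_map`` and, when ``mapping_path`` is given, persisted as CSV
    "original_id,internal_id".  Duplicate and reversed pairs are
    merged; self-loops are dropped with a warning.
    """
    pairs: list[tuple[int, int]] = []
    n_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two ids, got {stripped!r}")
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer id in {stripped!r}") from exc
            if u == v:
                n_loops += 1
                continue
            pairs.append((u, v))
    if n_loops:
        logger.warning("%s: dropped %d self-loop(s)", path, n_loops)
    if not pairs:
        raise ValueError(f"{path}: no edges found")
    arr = np.asarray(pairs, dtype=np.int64)
    original_ids = np.unique(arr)
    remap = {int(orig): i for i, orig in enumerate(original_ids)}
    internal = np.searchsorted(original_ids, arr)
    graph = LabeledGraph.from_edges(len(original_ids), internal)
    graph.id_map = remap
    if mapping_path is not None:
        pd.DataFrame(
            {"original_id": original_ids, "internal_id": np.arange(len(original_ids))}
        ).to_csv(mapping_path, index=False)
    return graph


def write_edgelist(graph: LabeledGraph, path: PathLike) -> None:
    """Write each undirected edge once as 'u v' per line."""
    with open(path, "w") as fh:
        fh.write(f"# nodes {graph.n} edges {graph.n_edges}\n")
        for u, v in graph.edge_array():
            fh.write(f"{u} {v}\n")


def read_labels(path: PathLike, n: Optional[int] = None) -> np.ndarray:
    """Read a label CSV with header 'node,group' into a dense array."""
    df = pd.read_csv(path)
    if not {"node", "group"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns 'node,group'")
    size = n if n is not None else int(df["node"].max()) + 1
    labels = np.zeros(size, dtype=np.int8)
    labels[df["node"].to_numpy()] = df["group"].to_numpy()
    return labels


def write_labels(labels: np.ndarray, path: PathLike) -> None:
    pd.DataFrame({"node": np.arange(len(labels)), "group": labels}).to_csv(
        path, index=False
    )


def read_choices(path: PathLike, n: Optional[int] = None) -> np.ndarray:
    """Read a choice-state CSV with header 'node,choice'."""
    df = pd.read_csv(path)
    if not {"node", "choice"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns 'node,choice'")
    size = n if n is not None else int(df["node"].max()) + 1
    choices = np.zeros(size, dtype=np.int8)
    choices[df["node"].to_numpy()] = df["choice"].to_numpy()
    return choices


def write_choices(choices: np.ndarray, path: PathLike) -> None:
    pd.DataFrame({"node": np.arange(len(choices)), "choice": choices}).to_csv(
        path, index=False
    )
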
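"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive results from first principles
(literal rule transcription, dense mixing-matrix formulas, fixed-step
Euler integration) so they share no code with the implementation paths
they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from affectpol import LabeledGraph, ModelParams
from affectpol.meanfield import MeanFieldConfig


# ---- literal single-node update oracle --------------------------------


def brute_force_update(graph: LabeledGraph, choices: np.ndarray, node: int,
                       params: ModelParams) -> int:
    """Literal transcription of the threshold update rule.

    Counts each neighbor category with an explicit loop and applies the
    strict-inequality rule directly.
    """
    nbrs = list(graph.neighbors(node))
    d = len(nbrs)
    assert d > 0
    in0 = in1 = out0 = out1 = 0
    for w in nbrs:
        same = graph.labels[w] == graph.labels[node]
        if same and choices[w] == 0:
            in0 += 1
        elif same and choices[w] == 1:
            in1 += 1
        elif not same and choices[w] == 0:
            out0 += 1
        else:
            out1 += 1
    g = params.alpha * (in1 / d - in0 / d) - params.beta * (out1 / d - out0 / d)
    if g < -params.delta:
        return 0
    if g > params.delta:
        return 1
    return int(choices[node])


# ---- fixed-step Euler oracle for the mean-field ODE -------------------


def euler_integrate(theta0, cfg: MeanFieldConfig, horizon: float, dt: float = 1e-4,
                    t_eval=None) -> np.ndarray:
    """Naive forward-Euler integration of the mean-field ODE.

    Evaluates the drive indicators afresh at every step; returns the
    states sampled at ``t_eval`` (nearest grid point at or before t).
    """
    a, b, c, d = cfg.coefficients()
    delta = cfg.delta
    n_steps = int(round(horizon / dt))
    if t_eval is None:
        t_eval = np.linspace(0.0, horizon, 51)
    snap_steps = np.minimum(np.round(np.asarray(t_eval) / dt).astype(int), n_steps)
    out = np.empty((len(t_eval), 2))
    tb, tr = float(theta0[0]), float(theta0[1])
    snap_idx = 0
    for k in range(n_steps + 1):
        while snap_idx < len(snap_steps) and snap_steps[snap_idx] == k:
            out[snap_idx] = (tb, tr)
            snap_idx += 1
        x, y = 2.0 * tb - 1.0, 2.0 * tr - 1.0
        gb = a * x - b * y
        gr = c * y - d * x
        rb = (1.0 - tb) if gb > delta else (-tb if gb < -delta else 0.0)
        rr = (1.0 - tr) if gr > delta else (-tr if gr < -delta else 0.0)
        tb = min(max(tb + dt * rb, 0.0), 1.0)
        tr = min(max(tr + dt * rr, 0.0), 1.0)
    while snap_idx < len(snap_steps):
        out[snap_idx] = (tb, tr)
        snap_idx += 1
    return out


# ---- dense mixing-matrix assortativity oracle -------------------------


def mixing_matrix_assortativity(graph: LabeledGraph, labels: np.ndarray) -> float:
    """Categorical assortativity from an explicitly accumulated 2x2
    mixing matrix over directed edge ends."""
    e = np.zeros((2, 2))
    for u, v in graph.iter_edges():
        e[labels[u], labels[v]] += 1
        e[labels[v], labels[u]] += 1
    e /= e.sum()
    ai = e.sum(axis=1)
    bi = e.sum(axis=0)
    num = np.trace(e) - float(ai @ bi)
    den = 1.0 - float(ai @ bi)
    return num / den


# ---- random labeled graph factory -------------------------------------


def random_labeled_graph(rng: np.random.Generator, n_min: int = 6, n_max: int = 20,
                         ensure_no_isolates: bool = True) -> LabeledGraph:
    """Small random labeled graph with both groups nonempty."""
    while True:
        n = int(rng.integers(n_min, n_max + 1))
        p = float(rng.uniform(0.2, 0.7))
        iu = np.triu_indices(n, k=1)
        mask = rng.random(len(iu[0])) < p
        edges = np.column_stack([iu[0][mask], iu[1][mask]])
        if len(edges) == 0:
            continue
        labels = (rng.random(n) < rng.uniform(0.2, 0.8)).astype(np.int8)
        if labels.sum() == 0 or labels.sum() == n:
            continue
        g = LabeledGraph.from_edges(n, edges, labels)
        if ensure_no_isolates and (g.degrees == 0).any():
            continue
        return g


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


def random_case1_config(rng: np.random.Generator, margin: float = 1e-3) -> MeanFieldConfig:
    """Random consensus-regime (case-1) configuration with delta=0,
    kept away from the phase boundaries by ``margin``."""
    while True:
        alpha = float(rng.uniform(0.05, 1.0))
        beta = float(rng.uniform(0.0, 1.0))
        r = float(rng.uniform(0.1, 0.9))
        p = alpha * (1 - r) - beta * r
        q = alpha * r - beta * (1 - r)
        if p > margin and q > margin:
            return MeanFieldConfig(ModelParams(alpha, beta, 0.0), r)
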
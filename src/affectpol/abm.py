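"""Stochastic agent-based dynamics on labeled graphs.

One update step picks a node uniformly at random (with replacement) and
applies the threshold rule to it; all other nodes keep their choice.
Group-level adoption fractions are recorded on a step grid rescaled to
ODE time t = k/N: the expected per-step change of a group fraction is
O(1/N), so N update steps correspond to one unit of mean-field time.

The inner loop is compiled with numba so that desk-scale runs (complete
graphs with thousands of nodes, tens of replicate seeds) stay fast;
absorption is detected by a full stability sweep (no node's update
could change its choice), never by merely observing no recent flips.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from numba import njit

from .core_dynamics import (
    BLUE,
    RED,
    IsolatedNodeError,
    LabeledGraph,
    ModelParams,
    StateVector,
)
from .meanfield import Trajectory

logger = logging.getLogger(__name__)

StateLike = Union[StateVector, Sequence[float]]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a single agent-based run.

    ``theta0`` gives the per-group initial adoption fractions; exactly
    round(theta0 * group size) nodes per group start at choice 1.
    ``max_steps`` defaults to 30*N single-node updates (30 units of
    rescaled time); ``record_every`` defaults to N//20 steps, i.e. 20
    samples per time unit.
    """

    params: ModelParams
    theta0: tuple[float, float] = (0.5, 0.5)
    max_steps: Optional[int] = None
    record_every: Optional[int] = None
    seed: int = 0
    stop_on_absorption: bool = True
    tolerate_isolates: bool = False

    def resolve(self, n: int) -> tuple[int, int]:
        max_steps = self.max_steps if self.max_steps is not None else 30 * n
        record_every = (
            self.record_every if self.record_every is not None else max(1, n // 20)
        )
        if max_steps < 1 or record_every < 1:
            raise ValueError("max_steps and record_every must be >= 1")
        return max_steps, record_every


@dataclass
class EnsembleSummary:
    """Pointwise mean and empirical 95% band over replicate runs."""

    times: np.ndarray
    mean: np.ndarray  # (K, 2) columns (blue, red)
    lower: np.ndarray
    upper: np.ndarray
    n_runs: int
    meta: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.times,
                "mean_B": self.mean[:, 0],
                "lo_B": self.lower[:, 0],
                "hi_B": self.upper[:, 0],
                "mean_R": self.mean[:, 1],
                "lo_R": self.lower[:, 1],
                "hi_R": self.upper[:, 1],
            }
        )


def init_choices(
    labels: np.ndarray,
    theta0: StateLike,
    seed: Union[int, np.random.Generator, None] = None,
) -> np.ndarray:
    """Initial choices with exactly round(theta * group size) ones per group."""
    labels = np.asarray(labels, dtype=np.int8)
    if isinstance(theta0, StateVector):
        tb, tr = theta0.thetaB, theta0.thetaR
    else:
        tb, tr = float(theta0[0]), float(theta0[1])
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    choices = np.zeros(len(labels), dtype=np.int8)
    for group, frac in ((BLUE, tb), (RED, tr)):
        members = np.flatnonzero(labels == group)
        if len(members) == 0:
            raise ValueError("both groups must be nonempty")
        k = int(math.floor(frac * len(members) + 0.5))
        if k:
            choices[rng.choice(members, size=k, replace=False)] = 1
    return choices


@njit(cache=False)
def _run_steps(
    indptr, indices, labels, choices, order, k0, k1,
    alpha, beta, delta, ones, rec_every, rec_B, rec_R, n_blue, n_red,
):  # pragma: no cover - exercised through run()
    for k in range(k0, k1):
        v = order[k]
        s, e = indptr[v], indptr[v + 1]
        d = e - s
        if d > 0:
            lv = labels[v]
            in1 = 0
            out1 = 0
            n_in = 0
            for idx in range(s, e):
                w = indices[idx]
                if labels[w] == lv:
                    n_in += 1
                    in1 += choices[w]
                else:
                    out1 += choices[w]
            n_out = d - n_in
            g = (alpha * (2 * in1 - n_in) - beta * (2 * out1 - n_out)) / d
            old = choices[v]
            new = old
            if g > delta:
                new = 1
            elif g < -delta:
                new = 0
            if new != old:
                choices[v] = new
                if lv == 1:
                    ones[1] += new - old
                else:
                    ones[0] += new - old
        if (k + 1) % rec_every == 0:
            ri = (k + 1) // rec_every
            rec_B[ri] = ones[0] / n_blue
            rec_R[ri] = ones[1] / n_red


@njit(cache=False)
def _all_stable(indptr, indices, labels, choices, alpha, beta, delta):  # pragma: no cover
    n = len(indptr) - 1
    for v in range(n):
        s, e = indptr[v], indptr[v + 1]
        d = e - s
        if d == 0:
            continue
        lv = labels[v]
        in1 = 0
        out1 = 0
        n_in = 0
        for idx in range(s, e):
            w = indices[idx]
            if labels[w] == lv:
                n_in += 1
                in1 += choices[w]
            else:
                out1 += choices[w]
        n_out = d - n_in
        g = (alpha * (2 * in1 - n_in) - beta * (2 * out1 - n_out)) / d
        if g > delta:
            if choices[v] == 0:
                return False
        elif g < -delta:
            if choices[v] == 1:
                return False
    return True


def run(
    graph: LabeledGraph,
    labels: Optional[np.ndarray] = None,
    config: RunConfig = None,
    choices0: Optional[np.ndarray] = None,
) -> Trajectory:
    """Run sequential random single-node updates and record group states.

    Returns a :class:`~affectpol.meanfield.Trajectory` on the rescaled
    time axis t = k/N.  With ``stop_on_absorption`` a full stability
    sweep runs every N steps and the run halts once no node's update
    could change its choice; the remaining record grid is filled with
    the absorbed state so replicate runs share a common grid.
    """
    if config is None:
        raise ValueError("config is required")
    if labels is None:
        graph._require_labels()
        labels = graph.labels
    labels = np.asarray(labels, dtype=np.int8)
    n = graph.n
    degrees = graph.degrees
    if (degrees == 0).any():
        if not config.tolerate_isolates:
            raise IsolatedNodeError(
                f"{int((degrees == 0).sum())} isolated node(s); the update rule "
                "is undefined for them (set tolerate_isolates to skip them)"
            )
        logger.warning(
            "%d isolated node(s) will be skipped by the scheduler",
            int((degrees == 0).sum()),
        )
    max_steps, record_every = config.resolve(n)
    rng = np.random.default_rng(config.seed)
    if choices0 is None:
        choices = init_choices(labels, config.theta0, rng)
    else:
        choices = np.array(choices0, dtype=np.int8)
    n_red = int(labels.sum())
    n_blue = n - n_red
    if n_red == 0 or n_blue == 0:
        raise ValueError("both groups must be nonempty")

    order = rng.integers(0, n, size=max_steps, dtype=np.int64)
    ones = np.array(
        [int(choices[labels == BLUE].sum()), int(choices[labels == RED].sum())],
        dtype=np.int64,
    )
    n_rec = max_steps // record_every + 1
    rec_B = np.empty(n_rec)
    rec_R = np.empty(n_rec)
    rec_B[0] = ones[0] / n_blue
    rec_R[0] = ones[1] / n_red

    alpha, beta, delta = config.params.alpha, config.params.beta, config.params.delta
    absorbed_at: Optional[int] = None
    chunk = n  # stability sweep cadence
    k = 0
    while k < max_steps:
        k1 = min(k + chunk, max_steps)
        _run_steps(
            graph.indptr, graph.indices, labels, choices, order, k, k1,
            alpha, beta, delta, ones, record_every, rec_B, rec_R, n_blue, n_red,
        )
        k = k1
        if config.stop_on_absorption and _all_stable(
            graph.indptr, graph.indices, labels, choices, alpha, beta, delta
        ):
            absorbed_at = k
            # freeze the remaining record grid at the absorbed state
            ri = k // record_every
            rec_B[ri + 1:] = ones[0] / n_blue
            rec_R[ri + 1:] = ones[1] / n_red
            break

    steps = np.arange(n_rec) * record_every
    times = steps / n
    thetas = np.column_stack([rec_B, rec_R])
    return Trajectory(
        times=times,
        thetas=thetas,
        events=[],
        regions=None,
        meta={
            "kind": "abm",
            "seed": config.seed,
            "n": n,
            "steps": steps,
            "max_steps": max_steps,
            "record_every": record_every,
            "absorbed_at_step": absorbed_at,
            "final_choices": choices,
        },
    )


def ensemble(
    graph: LabeledGraph,
    labels: Optional[np.ndarray] = None,
    config: RunConfig = None,
    n_runs: int = 50,
) -> EnsembleSummary:
    """Replicate ``run`` over independent seed substreams and band the paths.

    The 95% band is the pointwise 2.5/97.5 empirical percentile across
    runs (robust at the typical 50-replicate design).  Per-run seeds
    are spawned from the master seed and recorded in the metadata.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(config.seed).spawn(n_runs)
    ]
    trajs = []
    for s in seeds:
        cfg_i = RunConfig(
            params=config.params,
            theta0=config.theta0,
            max_steps=config.max_steps,
            record_every=config.record_every,
            seed=s,
            stop_on_absorption=config.stop_on_absorption,
            tolerate_isolates=config.tolerate_isolates,
        )
        trajs.append(run(graph, labels, cfg_i))
    stack = np.stack([t.thetas for t in trajs])  # (n_runs, K, 2)
    return EnsembleSummary(
        times=trajs[0].times,
        mean=stack.mean(axis=0),
        lower=np.percentile(stack, 2.5, axis=0),
        upper=np.percentile(stack, 97.5, axis=0),
        n_runs=n_runs,
        meta={"master_seed": config.seed, "run_seeds": seeds},
    )


def detect_reversal(
    trajectory: Trajectory, window: int = 5, min_amp: float = 1e-4
) -> list[tuple[float, str]]:
    """Times at which a group's trend flips direction.

    Mean-field trajectories carry exact region-switch events, which are
    used directly (a reversal is a transition whose region sign flips,
    possibly through a frozen interval).  Sampled agent-based
    trajectories are analyzed via the sign changes of a moving-average
    smoothed increment sequence; ``min_amp`` suppresses flips whose
    smoothed increments never exceed noise scale.
    """
    if trajectory.events:
        out = []
        # per-group sequence of signed regions, starting from the first sample
        last_sign = {"B": 0, "R": 0}
        if trajectory.regions is not None:
            last_sign = {
                "B": int(np.sign(trajectory.regions[0, 0])),
                "R": int(np.sign(trajectory.regions[0, 1])),
            }
        for ev in trajectory.events:
            new = int(np.sign(ev.new_region))
            if new != 0:
                if last_sign[ev.group] != 0 and new != last_sign[ev.group]:
                    out.append((ev.time, ev.group))
                last_sign[ev.group] = new
        return out

    if len(trajectory.times) < 3:
        raise ValueError("need at least 3 samples to detect reversals")
    out = []
    inc = np.diff(trajectory.thetas, axis=0)
    w = max(1, min(window, len(inc)))
    kernel = np.ones(w) / w
    for col, grp in ((0, "B"), (1, "R")):
        smooth = np.convolve(inc[:, col], kernel, mode="same")
        sign = np.where(smooth > min_amp, 1, np.where(smooth < -min_amp, -1, 0))
        nz = np.flatnonzero(sign)
        for i, j in zip(nz[:-1], nz[1:]):
            if sign[i] != sign[j]:
                out.append((float(trajectory.times[j + 1]), grp))
    return sorted(out)
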
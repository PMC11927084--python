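"""Mean-field limit of the choice dynamics and its phase analysis.

For a large fully connected (or unbiased) population the group-level
adoption fractions theta = (thetaB, thetaR) follow a piecewise-smooth
ODE: each component grows at rate (1 - theta) while its group's drive
exceeds the inertia delta, decays at rate -theta while the drive is
below -delta, and is frozen in between.  The drives are affine in the
state:

    driveB = a*(2 thetaB - 1) - b*(2 thetaR - 1),  a = alpha_e (1-r), b = beta_e r
    driveR = c*(2 thetaR - 1) - d*(2 thetaB - 1),  c = alpha_e r,     d = beta_e (1-r)

with r the red-group fraction and (alpha_e, beta_e) the effective
conformity/opposition weights: equal to (alpha, beta) on a fully
connected graph and to (alpha*rho, beta*(1-rho)) on a two-block
homophilic graph, where rho is the homophily level.

Within a region of constant drive signs each component relaxes
exponentially toward 0, 1 or stays put, so the trajectory is integrated
exactly region by region: closed-form segments joined at drive-threshold
crossing events located by solving A + B*exp(-tau) = s.

The long-run outcome from a party-independent start is decided by the
signs of the two corner drives

    p = alpha_e*(1-r) - beta_e*r      (blue drive at the (1,1) corner)
    q = alpha_e*r - beta_e*(1-r)      (red drive at the (1,1) corner)

p>0, q>0: consensus (case 1); p<0, q>0: partisan split with the red
majority keeping the popular choice (case 2); p>0, q<0: the mirror blue
case (case 3); p<0, q<0: an unstable half-half split (case 4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core_dynamics import ModelParams, StateVector

FULLY_CONNECTED = "fully_connected"
SBM = "sbm"

#: strict-inequality comparisons treat drives this close to a threshold
#: as sitting exactly on it (resolved by the local vector field)
BOUNDARY_TOL = 1e-12
#: minimum admissible event spacing in time
MIN_EVENT_DT = 1e-12

StateLike = Union[StateVector, Sequence[float], np.ndarray]


def _as_pair(state: StateLike) -> tuple[float, float]:
    if isinstance(state, StateVector):
        return state.thetaB, state.thetaR
    tb, tr = float(state[0]), float(state[1])
    if not (0.0 <= tb <= 1.0 and 0.0 <= tr <= 1.0):
        raise ValueError(f"state must lie in the unit square, got {(tb, tr)}")
    return tb, tr


@dataclass(frozen=True)
class MeanFieldConfig:
    """Mean-field problem description.

    ``mode`` selects the graph family the ODE approximates: on a
    ``fully_connected`` graph homophily plays no role; in ``sbm`` mode
    the in-group weight is amplified by rho and the out-group weight by
    (1 - rho).  ``red_drive`` selects the red group's drive convention:
    ``"symmetric"`` carries the red in-group size factor r (the form
    consistent with the fully connected derivation and the phase
    boundaries); ``"printed"`` omits it and is kept only for
    comparison.
    """

    params: ModelParams
    r: float
    mode: str = FULLY_CONNECTED
    red_drive: str = "symmetric"

    def __post_init__(self) -> None:
        if not (0.0 < self.r < 1.0):
            raise ValueError(f"red fraction r must be in (0, 1), got {self.r}")
        if self.mode not in (FULLY_CONNECTED, SBM):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.red_drive not in ("symmetric", "printed"):
            raise ValueError(f"unknown red_drive {self.red_drive!r}")

    @property
    def delta(self) -> float:
        return self.params.delta

    def coefficients(self) -> tuple[float, float, float, float]:
        """(a, b, c, d): driveB = a*x - b*y, driveR = c*y - d*x
        with x = 2 thetaB - 1, y = 2 thetaR - 1."""
        ae, be = effective_params(self.params, self.mode)
        a = ae * (1.0 - self.r)
        b = be * self.r
        c = ae * self.r if self.red_drive == "symmetric" else ae
        d = be * (1.0 - self.r)
        return a, b, c, d


def effective_params(params: ModelParams, mode: str) -> tuple[float, float]:
    """Effective (alpha, beta) after homophily rescaling.

    In ``sbm`` mode homophily amplifies in-group love and dampens
    out-group hate: (alpha*rho, beta*(1-rho)).  Fully connected mode
    returns (alpha, beta) unchanged.
    """
    if mode == SBM:
        return params.alpha * params.rho, params.beta * (1.0 - params.rho)
    if mode == FULLY_CONNECTED:
        return params.alpha, params.beta
    raise ValueError(f"unknown mode {mode!r}")


def drives(state: StateLike, cfg: MeanFieldConfig) -> tuple[float, float]:
    """Group-level social drives (driveB, driveR) at ``state``."""
    tb, tr = _as_pair(state)
    a, b, c, d = cfg.coefficients()
    x, y = 2.0 * tb - 1.0, 2.0 * tr - 1.0
    return a * x - b * y, c * y - d * x


def rhs(state: StateLike, cfg: MeanFieldConfig) -> tuple[float, float]:
    """Right-hand side of the mean-field ODE at ``state``.

    Per group: rate (1 - theta) if the drive exceeds delta, -theta if it
    is below -delta, 0 otherwise (strict inequalities)."""
    tb, tr = _as_pair(state)
    gb, gr = drives(state, cfg)
    delta = cfg.delta

    def rate(g: float, theta: float) -> float:
        if g > delta:
            return 1.0 - theta
        if g < -delta:
            return -theta
        return 0.0

    return rate(gb, tb), rate(gr, tr)


# ---- regimes ----------------------------------------------------------

_CASE_DESCRIPTIONS = {
    1: "consensus",
    2: "partisan (red majority side)",
    3: "partisan (blue majority side)",
    4: "nonpartisan",
    "boundary": "non-generic boundary",
}


@dataclass(frozen=True)
class Regime:
    """Asymptotic regime from a party-independent off-center start."""

    case_id: Union[int, str]
    description: str
    p: float  # blue corner drive alpha_e*(1-r) - beta_e*r
    q: float  # red corner drive alpha_e*r - beta_e*(1-r)


def classify_regime(cfg: MeanFieldConfig) -> Regime:
    """Classify the phase-diagram case from the effective parameters.

    The four strict-inequality cases correspond to the sign pattern of
    the corner drives p and q; a vanishing corner drive is the
    non-generic boundary between cases.
    """
    ae, be = effective_params(cfg.params, cfg.mode)
    if ae == 0.0 and be == 0.0:
        raise ValueError("alpha_eff and beta_eff are both zero: no dynamics")
    r = cfg.r
    p = ae * (1.0 - r) - be * r
    q = ae * r - be * (1.0 - r)
    scale = max(ae, be)
    if abs(p) <= BOUNDARY_TOL * scale or abs(q) <= BOUNDARY_TOL * scale:
        case: Union[int, str] = "boundary"
    elif p > 0 and q > 0:
        case = 1
    elif p < 0 and q > 0:
        case = 2
    elif p > 0 and q < 0:
        case = 3
    else:
        case = 4
    return Regime(case, _CASE_DESCRIPTIONS[case], p, q)


# ---- trajectories -----------------------------------------------------


@dataclass(frozen=True)
class SwitchEvent:
    """A change of a group's dynamic region along a trajectory."""

    time: float
    group: str  # "B" or "R"
    old_region: int  # -1 decaying, 0 frozen, +1 growing
    new_region: int
    kind: str  # "cross" | "slide" | "freeze"


@dataclass
class _Segment:
    t0: float
    t1: float
    theta0: tuple[float, float]
    modes: tuple[int, int]

    def eval(self, t: float) -> tuple[float, float]:
        e = math.exp(-(t - self.t0))
        out = []
        for i in range(2):
            target = _target(self.modes[i], self.theta0[i])
            out.append(target + (self.theta0[i] - target) * e)
        return out[0], out[1]


def _target(mode: int, theta: float) -> float:
    if mode > 0:
        return 1.0
    if mode < 0:
        return 0.0
    return theta


@dataclass
class Trajectory:
    """Time-indexed group states with region bookkeeping.

    ``regions`` holds, per sample and group, the active dynamic region
    (-1 decaying, 0 frozen, +1 growing); ``events`` the region switches.
    """

    times: np.ndarray
    thetas: np.ndarray  # (K, 2) columns (blue, red)
    events: list[SwitchEvent] = field(default_factory=list)
    regions: Optional[np.ndarray] = None  # (K, 2) ints
    meta: dict = field(default_factory=dict)

    @property
    def final(self) -> StateVector:
        tb, tr = self.thetas[-1]
        return StateVector(float(min(max(tb, 0.0), 1.0)), float(min(max(tr, 0.0), 1.0)))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"t": self.times, "theta_B": self.thetas[:, 0], "theta_R": self.thetas[:, 1]}
        )
        if self.regions is not None:
            df["region_B"] = self.regions[:, 0]
            df["region_R"] = self.regions[:, 1]
        return df

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"t": e.time, "group": e.group, "from_region": e.old_region,
                 "to_region": e.new_region, "kind": e.kind}
                for e in self.events
            ],
            columns=["t", "group", "from_region", "to_region", "kind"],
        )


class EventLoopError(RuntimeError):
    """Event-driven integration exceeded max_events (possible sliding mode)."""


def _resolve_modes(
    theta: tuple[float, float], cfg: MeanFieldConfig
) -> tuple[tuple[int, int], list[str]]:
    """Dynamic region of each component, resolving exact-threshold states.

    A drive sitting exactly on +/-delta yields zero rate under the
    strict inequalities; whether the component stays frozen or
    immediately re-enters an active region is decided by the drive's
    time derivative with the component held frozen (the other component
    moving at its own rate).  Freezes are reported so the caller can
    record them.
    """
    delta = cfg.delta
    a, b, c, d = cfg.coefficients()
    gb, gr = drives(theta, cfg)
    notes: list[str] = []

    def strict(g: float) -> Optional[int]:
        if g > delta + BOUNDARY_TOL:
            return 1
        if g < -delta - BOUNDARY_TOL:
            return -1
        if delta > BOUNDARY_TOL and abs(g) < delta - BOUNDARY_TOL:
            return 0
        return None  # on a threshold

    mb, mr = strict(gb), strict(gr)

    # frozen-hypothesis drive derivatives: only the other component moves
    def rate(mode: Optional[int], th: float) -> float:
        if mode == 1:
            return 1.0 - th
        if mode == -1:
            return -th
        return 0.0

    def resolve(g: float, other_rate: float, cross_coef: float, which: str) -> int:
        # d(drive)/dt with this component frozen
        gdot = cross_coef * 2.0 * other_rate
        if abs(g - delta) <= BOUNDARY_TOL + abs(delta) * 1e-15:  # upper threshold
            if gdot > BOUNDARY_TOL:
                return 1
            if gdot < -BOUNDARY_TOL:
                return 0 if delta > BOUNDARY_TOL else -1
        else:  # lower threshold
            if gdot < -BOUNDARY_TOL:
                return -1
            if gdot > BOUNDARY_TOL:
                return 0 if delta > BOUNDARY_TOL else 1
        notes.append(which)
        return 0

    if mb is None:
        mb = resolve(gb, rate(mr, theta[1]), -b, "B")
    if mr is None:
        mr = resolve(gr, rate(mb, theta[0]), -d, "R")
    return (mb, mr), notes


def _drive_exp_coefs(
    theta: tuple[float, float], modes: tuple[int, int], cfg: MeanFieldConfig
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Coefficients (A, B) of drive(tau) = A + B exp(-tau) per group."""
    a, b, c, d = cfg.coefficients()
    tB = _target(modes[0], theta[0])
    tR = _target(modes[1], theta[1])
    cB = theta[0] - tB
    cR = theta[1] - tR
    AB = a * (2.0 * tB - 1.0) - b * (2.0 * tR - 1.0)
    BB = 2.0 * a * cB - 2.0 * b * cR
    AR = c * (2.0 * tR - 1.0) - d * (2.0 * tB - 1.0)
    BR = 2.0 * c * cR - 2.0 * d * cB
    return (AB, BB), (AR, BR)


def _next_crossing(coefs, delta: float, horizon_tau: float) -> Optional[float]:
    """Smallest tau in (0, horizon_tau) at which either drive hits +/-delta."""
    thresholds = (delta,) if delta == 0.0 else (delta, -delta)
    best: Optional[float] = None
    for A, B in coefs:
        if B == 0.0:
            continue
        for s in thresholds:
            u = (s - A) / B  # exp(-tau)
            if 0.0 < u < 1.0:
                tau = -math.log(u)
                if MIN_EVENT_DT < tau < horizon_tau and (best is None or tau < best):
                    best = tau
    return best


def integrate(
    theta0: StateLike,
    cfg: MeanFieldConfig,
    horizon: float = 40.0,
    t_eval: Optional[np.ndarray] = None,
    n_samples: int = 401,
    max_events: int = 1000,
) -> Trajectory:
    """Exact event-driven integration of the mean-field ODE.

    Within each region the components relax exponentially in closed
    form; region exits are located by solving the affine-in-exp(-tau)
    drive equations, so the only error sources are floating-point
    round-off.  The trajectory is sampled on ``t_eval`` (default: a
    uniform grid of ``n_samples`` points on [0, horizon]) plus all
    event times.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    theta = _as_pair(theta0)
    t = 0.0
    segments: list[_Segment] = []
    events: list[SwitchEvent] = []
    prev_modes: Optional[tuple[int, int]] = None

    while True:
        modes, frozen_notes = _resolve_modes(theta, cfg)
        if prev_modes is not None and modes != prev_modes:
            for i, grp in enumerate("BR"):
                if modes[i] != prev_modes[i]:
                    kind = "freeze" if grp in frozen_notes or modes[i] == 0 else "cross"
                    events.append(SwitchEvent(t, grp, prev_modes[i], modes[i], kind))
        prev_modes = modes

        if modes == (0, 0):
            segments.append(_Segment(t, horizon, theta, modes))
            break
        coefs = _drive_exp_coefs(theta, modes, cfg)
        tau = _next_crossing(coefs, cfg.delta, horizon - t)
        if tau is None:
            segments.append(_Segment(t, horizon, theta, modes))
            break
        seg = _Segment(t, t + tau, theta, modes)
        segments.append(seg)
        theta = seg.eval(t + tau)
        theta = (min(max(theta[0], 0.0), 1.0), min(max(theta[1], 0.0), 1.0))
        t += tau
        if len(events) + 1 > max_events:
            raise EventLoopError(
                f"exceeded max_events={max_events} at t={t:.6g}; "
                "the trajectory may be chattering on a switching manifold"
            )

    if t_eval is None:
        t_eval = np.linspace(0.0, horizon, n_samples)
    else:
        t_eval = np.asarray(t_eval, dtype=float)
        if t_eval.size and (t_eval[0] < 0 or t_eval[-1] > horizon + 1e-12):
            raise ValueError("t_eval must lie within [0, horizon]")
    times = np.unique(np.concatenate([t_eval, [e.time for e in events]]))
    thetas = np.empty((len(times), 2))
    regions = np.empty((len(times), 2), dtype=np.int8)
    si = 0
    for k, tk in enumerate(times):
        while si + 1 < len(segments) and tk > segments[si].t1:
            si += 1
        seg = segments[si]
        thetas[k] = seg.eval(min(tk, seg.t1))
        regions[k] = seg.modes
    np.clip(thetas, 0.0, 1.0, out=thetas)
    return Trajectory(times=times, thetas=thetas, events=events, regions=regions,
                      meta={"horizon": horizon, "n_segments": len(segments)})


# ---- limiting states and consensus -----------------------------------

_DIAGONAL_LIMITS_HIGH = {1: (1.0, 1.0), 2: (0.0, 1.0), 3: (1.0, 0.0), 4: (0.5, 0.5)}
_DIAGONAL_LIMITS_LOW = {1: (0.0, 0.0), 2: (1.0, 0.0), 3: (0.0, 1.0), 4: (0.5, 0.5)}


def limiting_state(
    theta0: StateLike,
    cfg: MeanFieldConfig,
    horizon: float = 40.0,
    tol: float = 1e-9,
) -> StateVector:
    """Asymptotic state of the mean-field trajectory from ``theta0``.

    For delta=0 and a party-independent off-center start the limit is
    given in closed form by the regime classification (the partisan
    cases follow majority-keeps-the-popular-choice semantics);
    otherwise the ODE is integrated until both rates vanish or the
    state is within ``tol`` of an invariant point.
    """
    tb, tr = _as_pair(theta0)
    if cfg.delta == 0.0 and tb == tr and tb != 0.5:
        regime = classify_regime(cfg)
        if regime.case_id in (1, 2, 3, 4):
            table = _DIAGONAL_LIMITS_HIGH if tb > 0.5 else _DIAGONAL_LIMITS_LOW
            return StateVector(*table[regime.case_id])
    traj = integrate((tb, tr), cfg, horizon=horizon, n_samples=2)
    final = traj.final
    rates = rhs(final, cfg)
    if max(abs(rates[0]), abs(rates[1])) > tol:
        # not yet absorbed: snap components that are numerically saturated
        snap = []
        for v in (final.thetaB, final.thetaR):
            if v < tol:
                snap.append(0.0)
            elif v > 1.0 - tol:
                snap.append(1.0)
            else:
                snap.append(v)
        return StateVector(*snap)
    return final


@dataclass(frozen=True)
class ConsensusResult:
    """Outcome of the consensus-reachability check with its certificate."""

    reachable: bool
    corner: Optional[StateVector]
    reason: str

    def __bool__(self) -> bool:
        return self.reachable


def consensus_reachable(theta0: StateLike, cfg: MeanFieldConfig) -> ConsensusResult:
    """Whether the trajectory from ``theta0`` reaches full consensus.

    Requires delta=0.  Consensus needs (i) a consensus-stable regime
    (case 1) and (ii) an initial state whose two group drives share a
    strict sign; the sign then persists along the flow (the shared-sign
    cone is invariant in case 1), so the state converges to the (1,1)
    or (0,0) corner accordingly.
    """
    if cfg.delta != 0.0:
        raise ValueError("consensus analysis requires delta=0")
    tb, tr = _as_pair(theta0)
    regime = classify_regime(cfg)
    if regime.case_id != 1:
        return ConsensusResult(False, None, f"regime is {regime.case_id}, not case 1")
    gb, gr = drives((tb, tr), cfg)
    if gb == 0.0 and gr == 0.0:
        return ConsensusResult(False, None, "fixed point: both drives vanish")
    if gb > 0.0 and gr > 0.0:
        return ConsensusResult(True, StateVector(1.0, 1.0), "both drives positive")
    if gb < 0.0 and gr < 0.0:
        return ConsensusResult(True, StateVector(0.0, 0.0), "both drives negative")
    return ConsensusResult(False, None, "group drives disagree in sign")


# ---- switching manifolds ----------------------------------------------


@dataclass(frozen=True)
class ManifoldLine:
    """Affine locus coef_B*thetaB + coef_R*thetaR = const in state space."""

    group: str  # "B" or "R"
    side: int  # +1 for drive = +delta, -1 for drive = -delta
    coef_B: float
    coef_R: float
    const: float

    def residual(self, state: StateLike) -> float:
        tb, tr = _as_pair(state)
        return self.coef_B * tb + self.coef_R * tr - self.const

    def theta_R_at(self, theta_B: float) -> float:
        """Solve the line for thetaR at a given thetaB."""
        if self.coef_R == 0.0:
            raise ZeroDivisionError("manifold is vertical in thetaB")
        return (self.const - self.coef_B * theta_B) / self.coef_R


@dataclass(frozen=True)
class SwitchingManifolds:
    """The four tipping-point lines driveB = +/-delta, driveR = +/-delta."""

    lines: tuple[ManifoldLine, ManifoldLine, ManifoldLine, ManifoldLine]

    def line(self, group: str, side: int) -> ManifoldLine:
        for ln in self.lines:
            if ln.group == group and ln.side == side:
                return ln
        raise KeyError((group, side))


def switching_manifolds(cfg: MeanFieldConfig) -> SwitchingManifolds:
    """Tipping-point loci where a group's drive equals +/-delta.

    On these lines the group's trend can reverse; at delta=0 the two
    lines of each group coincide and pass through (0.5, 0.5).
    """
    a, b, c, d = cfg.coefficients()
    delta = cfg.delta
    lines = []
    for side in (1, -1):
        # a(2tB-1) - b(2tR-1) = side*delta
        lines.append(ManifoldLine("B", side, 2.0 * a, -2.0 * b, side * delta + a - b))
        # c(2tR-1) - d(2tB-1) = side*delta
        lines.append(ManifoldLine("R", side, -2.0 * d, 2.0 * c, side * delta + c - d))
    return SwitchingManifolds(tuple(lines))
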
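"""Bifurcation diagrams, phase diagrams and signal-driven transitions.

One- and two-parameter sweeps locate, at every grid point, the full fixed
point set of the effective model; the coexisting stable labels form the
"phase" at that point, and stable/unstable branches are assembled by
nearest-neighbour continuation.  Fold (saddle-node) points are bracketed
at grid resolution.  ``temporal_transition`` integrates the detailed
model under time-dependent microRNA schedules to follow phenotype
switches such as the collective-to-amoeboid transition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .circuit_model import (
    CircuitParameters,
    SignalInput,
    detailed_rhs,
    lift_to_detailed,
)
from .steady_state import SteadyStateSet, classify_phenotype, find_fixed_points

__all__ = [
    "BifurcationBranch",
    "PhaseDiagram",
    "SweepResult",
    "sweep_1d",
    "sweep_2d",
    "temporal_transition",
    "SWEEPABLE",
]

logger = logging.getLogger(__name__)

#: parameter names accepted by the sweeps; ``mu`` locks mu1 = mu2
SWEEPABLE = ("mu", "mu1", "mu2", "grb2", "gab1")


def _signals_with(signals: SignalInput, name: str, value: float) -> SignalInput:
    if name == "mu":
        return replace(signals, mu1=value, mu2=value)
    if name in ("mu1", "mu2", "grb2", "gab1"):
        return replace(signals, **{name: value})
    raise ValueError(f"unknown sweep parameter {name!r}; expected one of {SWEEPABLE}")


# ---------------------------------------------------------------------------
# one-parameter sweep
# ---------------------------------------------------------------------------

@dataclass
class BifurcationBranch:
    """One continued branch of fixed points along a control parameter."""

    branch_id: int
    parameter: str
    values: list[float] = field(default_factory=list)       # parameter values
    rac1_gtp: list[float] = field(default_factory=list)
    rhoa_gtp: list[float] = field(default_factory=list)
    stable: list[bool] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class SweepResult:
    """Branches, per-point steady-state sets and phase intervals of a
    one-parameter sweep."""

    parameter: str
    grid: np.ndarray
    steady_states: list[SteadyStateSet]
    branches: list[BifurcationBranch]
    #: (start_value, end_value, phase_string) for maximal constant-phase runs
    phase_intervals: list[tuple[float, float, str]]
    #: parameter values bracketing a change in stable-state count (folds)
    fold_brackets: list[tuple[float, float]]

    @property
    def phases(self) -> set[str]:
        return {ph for _, _, ph in self.phase_intervals}


def _assemble_branches(grid, sets: list[SteadyStateSet], parameter: str,
                       jump_rtol: float = 0.15) -> list[BifurcationBranch]:
    """Nearest-neighbour continuation of fixed points across the grid.

    A point continues the branch whose previous state is nearest (relative
    distance); candidates farther than ``jump_rtol`` (relative to the
    state scale) start a new branch.  Ties break deterministically toward
    the smaller distance, logged when two candidates are within tolerance.
    """
    branches: list[BifurcationBranch] = []
    active: dict[int, tuple[float, float]] = {}  # branch id -> last state

    for value, ss in zip(grid, sets):
        scale = max([max(p.rac1_gtp, p.rhoa_gtp) for p in ss.points], default=1.0)
        assignment: dict[int, int] = {}          # point index -> branch id
        if active:
            bids = list(active)
            prev = np.array([active[b] for b in bids])
            cur = np.array([[p.rac1_gtp, p.rhoa_gtp] for p in ss.points])
            dist = np.linalg.norm(cur[:, None, :] - prev[None, :, :], axis=-1)
            # pair points to branches globally, smallest distance first
            order = np.dstack(np.unravel_index(np.argsort(dist, axis=None),
                                               dist.shape))[0]
            used_pts, used_bids = set(), set()
            for pi, bj in order:
                if pi in used_pts or bj in used_bids:
                    continue
                if dist[pi, bj] > jump_rtol * scale:
                    break
                if np.sum(np.abs(dist[pi] - dist[pi, bj]) < 1e-6 * scale) > 1:
                    logger.info("branch tie at %s=%g broken toward nearer state",
                                parameter, value)
                assignment[int(pi)] = bids[int(bj)]
                used_pts.add(pi)
                used_bids.add(bj)
        active = {}
        for i, p in enumerate(ss.points):
            bid = assignment.get(i)
            if bid is None:
                bid = len(branches)
                branches.append(BifurcationBranch(branch_id=bid, parameter=parameter))
            br = branches[bid]
            br.values.append(float(value))
            br.rac1_gtp.append(p.rac1_gtp)
            br.rhoa_gtp.append(p.rhoa_gtp)
            br.stable.append(p.stable)
            active[bid] = (p.rac1_gtp, p.rhoa_gtp)
    return branches


def sweep_1d(params: CircuitParameters, varying: str,
             value_range: tuple[float, float], n_points: int = 200,
             signals: SignalInput | None = None, grid: int = 160,
             ) -> SweepResult:
    """One-parameter bifurcation sweep.

    ``varying`` is one of ``mu`` (mu1 = mu2 locked), ``mu1``, ``mu2``,
    ``grb2`` or ``gab1``; the other signals stay at their values in
    ``signals``.  A zero-length range yields a single-point diagram
    identical to :func:`find_fixed_points`.
    """
    if varying not in SWEEPABLE:
        raise ValueError(f"unknown sweep parameter {varying!r}; expected one of {SWEEPABLE}")
    signals = signals or SignalInput()
    lo, hi = value_range
    values = np.array([lo]) if hi == lo else np.linspace(lo, hi, n_points)

    sets = [find_fixed_points(params, _signals_with(signals, varying, v), grid=grid)
            for v in values]
    branches = _assemble_branches(values, sets, varying)

    intervals: list[tuple[float, float, str]] = []
    folds: list[tuple[float, float]] = []
    start = values[0]
    prev_phase = sets[0].phase_string()
    prev_n = len(sets[0].stable)
    for idx in range(1, len(values)):
        v, ss = values[idx], sets[idx]
        ph = ss.phase_string()
        if ph != prev_phase:
            intervals.append((float(start), float(v), prev_phase))
            start = v
            prev_phase = ph
        if len(ss.stable) != prev_n:
            folds.append((float(values[idx - 1]), float(v)))
            prev_n = len(ss.stable)
    intervals.append((float(start), float(values[-1]), prev_phase))
    return SweepResult(parameter=varying, grid=values, steady_states=sets,
                       branches=branches, phase_intervals=intervals,
                       fold_brackets=folds)


# ---------------------------------------------------------------------------
# two-parameter phase diagram
# ---------------------------------------------------------------------------

@dataclass
class PhaseDiagram:
    """Grid of coexisting-stable-state phases over two control parameters."""

    x_parameter: str
    y_parameter: str
    x_values: np.ndarray
    y_values: np.ndarray
    #: phase string per (y, x) grid point; missing root-finds are ""
    phase: np.ndarray
    steady_states: list[list[SteadyStateSet | None]]

    @property
    def distinct_phases(self) -> set[str]:
        return {ph for ph in self.phase.ravel() if ph}

    def contains_phase(self, labels: set[str] | frozenset[str]) -> bool:
        target = "+".join(sorted(labels))
        return bool(np.any(self.phase == target))


def sweep_2d(params: CircuitParameters, varying: tuple[str, str],
             ranges: tuple[tuple[float, float], tuple[float, float]],
             resolution: int | tuple[int, int] = 100,
             signals: SignalInput | None = None, grid: int = 160,
             ) -> PhaseDiagram:
    """Two-parameter phase diagram.

    ``varying = (x_name, y_name)`` must be two distinct parameter names;
    degenerate ranges collapse that axis to a single point.  A grid point
    where root-finding fails entirely is recorded with an empty phase.
    """
    x_name, y_name = varying
    if x_name == y_name:
        raise ValueError("two-parameter sweep needs two distinct parameter names")
    for name in varying:
        if name not in SWEEPABLE:
            raise ValueError(f"unknown sweep parameter {name!r}")
    signals = signals or SignalInput()
    if isinstance(resolution, int):
        resolution = (resolution, resolution)
    (x_lo, x_hi), (y_lo, y_hi) = ranges
    xs = np.array([x_lo]) if x_hi == x_lo else np.linspace(x_lo, x_hi, resolution[0])
    ys = np.array([y_lo]) if y_hi == y_lo else np.linspace(y_lo, y_hi, resolution[1])

    phase = np.empty((len(ys), len(xs)), dtype=object)
    sets: list[list[SteadyStateSet | None]] = []
    for i, y in enumerate(ys):
        row: list[SteadyStateSet | None] = []
        for j, x in enumerate(xs):
            sig = _signals_with(_signals_with(signals, x_name, x), y_name, y)
            try:
                ss = find_fixed_points(params, sig, grid=grid)
            except RuntimeError:
                logger.warning("root finding failed at %s=%g, %s=%g; marked missing",
                               x_name, x, y_name, y)
                row.append(None)
                phase[i, j] = ""
                continue
            row.append(ss)
            phase[i, j] = ss.phase_string()
        sets.append(row)
    return PhaseDiagram(x_parameter=x_name, y_parameter=y_name,
                        x_values=xs, y_values=ys, phase=phase.astype(str),
                        steady_states=sets)


# ---------------------------------------------------------------------------
# temporal dynamics under signal schedules
# ---------------------------------------------------------------------------

@dataclass
class TransitionResult:
    """Trajectory of the detailed model under a time-varying signal."""

    times: np.ndarray
    states: np.ndarray                  # (n, 6) detailed-model states
    labels: list[str]                   # High/Low label per time point
    phenotypes: list[str]

    @property
    def final_label(self) -> str:
        return self.labels[-1]

    @property
    def final_phenotype(self) -> str:
        return self.phenotypes[-1]


def temporal_transition(params: CircuitParameters, schedule: SignalInput,
                        t_end: float, initial_state: np.ndarray | None = None,
                        n_eval: int = 400) -> TransitionResult:
    """Integrate the detailed model under a signal schedule (stiff solver).

    The initial condition defaults to the LL attractor (or, failing that,
    the first stable state) at the schedule's t = 0 signal levels, lifted
    to the 6-variable state.  The phenotype label is emitted along the
    trajectory; integration failure raises with the last valid time.
    """
    sig0 = schedule.at(0.0)
    if initial_state is None:
        ss = find_fixed_points(params, sig0)
        if not ss.stable:
            raise RuntimeError("no stable state at the schedule's initial signals")
        start = next((p for p in ss.stable if p.label == "LL"), ss.stable[0])
        initial_state = lift_to_detailed(start.state, params, sig0)

    def rhs(t, y):
        return detailed_rhs(np.maximum(y, 0.0), params, schedule, t=t)

    times = np.linspace(0.0, t_end, n_eval)
    sol = solve_ivp(rhs, (0.0, t_end), np.asarray(initial_state, float),
                    method="LSODA", t_eval=times, rtol=1e-8, atol=1e-6)
    if not sol.success:
        raise RuntimeError(
            f"stiff integration failed at t={sol.t[-1] if len(sol.t) else 0.0:g}: "
            f"{sol.message}")

    states = sol.y.T
    labels, phenotypes = [], []
    for row in states:
        label, phen, _ = classify_phenotype((row[0], row[3]), params)
        labels.append(label)
        phenotypes.append(phen)
    return TransitionResult(times=sol.t, states=states, labels=labels,
                            phenotypes=phenotypes)
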
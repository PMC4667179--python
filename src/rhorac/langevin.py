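"""Stochastic dynamics and effective landscapes of the GTPase circuit.

The reduced 4-variable model (GTP and GDP pools of both GTPases, GDI
sequestration at fast equilibrium) is driven by additive Gaussian white
noise of amplitude ``noise_level`` (molecules/sqrt(hour)) and integrated
with the Euler-Maruyama scheme, reflecting at zero so molecule counts
stay non-negative.  A long trajectory yields the stationary occupancy
``P(x)`` over the (RhoA-GTP, Rac1-GTP) plane and the effective landscape
``E = -ln P``; basins correspond to the High/Low quadrants of the
phase plane, so noise-induced states without a deterministic fixed point
(the LL basin of the standalone circuit) are detected as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .circuit_model import (
    CircuitParameters,
    LoadingSpec,
    SignalInput,
    lift_to_reduced,
    mirna_inhibition,
    reduced_rhs,
    shifted_hill,
)
from .steady_state import SteadyStateSet, find_fixed_points

__all__ = [
    "LangevinTrajectory",
    "LandscapeResult",
    "simulate_langevin",
    "build_landscape",
    "BASIN_LABELS",
]

BASIN_LABELS = ("LL", "LH", "HL", "HH")

#: consecutive thinned samples required in a new basin to count a transition
DWELL_THRESHOLD = 10


# ---------------------------------------------------------------------------
# parameter packing for the compiled kernel
# ---------------------------------------------------------------------------

_SPECIES_INDEX = {"rac1_gtp": 0, "rhoa_gtp": 2}  # indices in the 4-var state


def _pack_loading(spec: LoadingSpec, signals: SignalInput) -> tuple[float, np.ndarray]:
    """Fold constant signal regulators into the intrinsic rate and return
    (folded_rate, regs) with regs rows (state_index, threshold, n, lam)."""
    rate = spec.intrinsic_rate
    rows = []
    for name, hill in spec.regulators:
        if name in _SPECIES_INDEX:
            rows.append((float(_SPECIES_INDEX[name]), hill.threshold,
                         float(hill.coefficient), hill.fold_change))
        else:
            rate *= shifted_hill(getattr(signals, name), hill)
    regs = np.array(rows, dtype=np.float64).reshape(-1, 4)
    return float(rate), regs


def _pack(params: CircuitParameters, signals: SignalInput):
    sig = signals.at(0.0)
    p_rac = mirna_inhibition(sig.mu2, params.mirna_rac1)
    p_rho = mirna_inhibition(sig.mu1, params.mirna_rhoa)
    scal = np.array([
        params.g_rac1 * p_rac,                      # 0 folded Rac1 production
        params.g_rhoa_basal * p_rho,                # 1 folded basal RhoA production
        params.g_rhoa_exc * p_rho,                  # 2 folded excitatory RhoA production
        params.rhoa_selfact.threshold,              # 3
        float(params.rhoa_selfact.coefficient),     # 4
        params.rhoa_selfact.fold_change,            # 5
        params.k_rac1,                              # 6
        params.k_rhoa,                              # 7
        params.gdi_partition_rac1,                  # 8
        params.gdi_partition_rhoa,                  # 9
    ])
    b_rac, regs_b_rac = _pack_loading(params.loading_rac1, sig)
    b_rho, regs_b_rho = _pack_loading(params.loading_rhoa, sig)
    j_rac, regs_j_rac = _pack_loading(params.hydrolysis_rac1, sig)
    j_rho, regs_j_rho = _pack_loading(params.hydrolysis_rhoa, sig)
    rates = np.array([b_rac, b_rho, j_rac, j_rho])
    return scal, rates, regs_b_rac, regs_b_rho, regs_j_rac, regs_j_rho


@njit(cache=False)
def _eval_loading(rate, regs, x):
    out = rate
    for i in range(regs.shape[0]):
        idx = int(regs[i, 0])
        x0 = regs[i, 1]
        n = regs[i, 2]
        lam = regs[i, 3]
        out *= lam + (1.0 - lam) / (1.0 + (x[idx] / x0) ** n)
    return out


@njit(cache=False)
def _drift(x, scal, rates, rb1, rb2, rj1, rj2, out):
    b_rac = _eval_loading(rates[0], rb1, x)
    b_rho = _eval_loading(rates[1], rb2, x)
    j_rac = _eval_loading(rates[2], rj1, x)
    j_rho = _eval_loading(rates[3], rj2, x)
    prod_rac = scal[0]
    hill = scal[5] + (1.0 - scal[5]) / (1.0 + (x[2] / scal[3]) ** scal[4])
    prod_rho = scal[1] + scal[2] * hill
    k_rac, k_rho = scal[6], scal[7]
    c_rac, c_rho = scal[8], scal[9]
    out[0] = b_rac * x[1] - (j_rac + k_rac) * x[0]
    out[1] = prod_rac - b_rac * x[1] + j_rac * x[0] - k_rac * (1.0 + c_rac) * x[1]
    out[2] = b_rho * x[3] - (j_rho + k_rho) * x[2]
    out[3] = prod_rho - b_rho * x[3] + j_rho * x[2] - k_rho * (1.0 + c_rho) * x[3]


@njit(cache=False)
def _em_run(x0, n_steps, dt, gamma, thin, seed, scal, rates, rb1, rb2, rj1, rj2):
    np.random.seed(seed)
    x = x0.copy()
    f = np.empty(4)
    n_keep = n_steps // thin
    out = np.empty((n_keep, 4))
    sq = gamma * np.sqrt(dt)
    kept = 0
    for step in range(n_steps):
        _drift(x, scal, rates, rb1, rb2, rj1, rj2, f)
        for i in range(4):
            x[i] = x[i] + f[i] * dt + sq * np.random.normal()
            if x[i] < 0.0:       # reflecting boundary: counts stay non-negative
                x[i] = -x[i]
        if (step + 1) % thin == 0:
            out[kept] = x
            kept += 1
    return out


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

@dataclass
class LangevinTrajectory:
    """Thinned Euler-Maruyama trajectory of the reduced 4-variable model."""

    samples: np.ndarray          # (n, 4): rac1_gtp, rac1_gdp, rhoa_gtp, rhoa_gdp
    dt: float
    thin: int
    t_total: float
    seed: int
    noise_level: float

    @property
    def sample_interval(self) -> float:
        return self.dt * self.thin

    @property
    def active(self) -> np.ndarray:
        """(n, 2) array of (rac1_gtp, rhoa_gtp) samples."""
        return self.samples[:, [0, 2]]


def drift_reduced(state4, params: CircuitParameters, signals: SignalInput) -> np.ndarray:
    """Compiled-kernel drift; equals :func:`rhorac.circuit_model.reduced_rhs`."""
    packed = _pack(params, signals)
    out = np.empty(4)
    _drift(np.asarray(state4, dtype=float), *packed, out)
    return out


def simulate_langevin(params: CircuitParameters, signals: SignalInput,
                      t_total: float = 1e5, dt: float = 0.01,
                      seed: int = 0, thin: int = 10,
                      x0: np.ndarray | None = None,
                      noise_level: float | None = None) -> LangevinTrajectory:
    """Euler-Maruyama simulation of the reduced model under white noise.

    Each step updates ``x += f(x) dt + noise_level * sqrt(dt) * N(0,1)``
    per component, reflecting at zero.  The trajectory is thinned to every
    ``thin``-th step.  Identical (seed, parameters) give identical output.

    Before integrating, the deterministic step size is checked at every
    stable attractor: if a single step changes any component by more than
    5% of the state scale, a ``ValueError`` asks for a smaller ``dt``.
    """
    signals = signals.at(0.0)
    gamma = params.noise_level if noise_level is None else float(noise_level)
    if gamma < 0:
        raise ValueError("noise level must be non-negative")

    ss = find_fixed_points(params, signals)
    attractors = [lift_to_reduced(p.state, params, signals) for p in ss.stable]
    for a in attractors:
        # a 10% displacement must relax by less than 5% of the state per
        # step, otherwise explicit Euler is too coarse for the local rates
        step = np.abs(reduced_rhs(a * 1.1 + 1.0, params, signals)) * dt
        scale = np.maximum(np.abs(a), 10.0)
        if np.any(step / scale > 0.05):
            raise ValueError(
                f"dt={dt} too coarse: deterministic step exceeds 5% of the "
                "state at an attractor; reduce dt")

    if x0 is None:
        x0 = attractors[0] if attractors else np.full(4, 10.0)
    n_steps = int(round(t_total / dt))
    packed = _pack(params, signals)
    samples = _em_run(np.asarray(x0, dtype=float), n_steps, dt, gamma,
                      int(thin), int(seed) & 0x7FFFFFFF, *packed)
    return LangevinTrajectory(samples=samples, dt=dt, thin=int(thin),
                              t_total=t_total, seed=int(seed),
                              noise_level=gamma)


@dataclass
class LandscapeResult:
    """Occupancy histogram, effective potential and basin statistics.

    The histogram is over the (RhoA-GTP, Rac1-GTP) plane (RhoA on the
    first axis).  ``potential`` is ``-ln P`` with unvisited bins set to
    NaN; ``occupancy`` maps basin labels to fractions of samples (summing
    to 1); ``transitions[i, j]`` counts dwell-filtered moves from basin
    ``BASIN_LABELS[i]`` to ``BASIN_LABELS[j]`` (diagonal zero).
    """

    hist: np.ndarray
    rhoa_edges: np.ndarray
    rac1_edges: np.ndarray
    potential: np.ndarray
    occupancy: dict[str, float]
    #: minimum of E over each basin's bins (NaN if the basin was never
    #: visited); the depth of the basin on the effective landscape
    basin_potentials: dict[str, float]
    transitions: np.ndarray
    basin_rule: str
    total_time: float
    seed: int
    basin_sequence: np.ndarray = field(repr=False, default=None)

    #: row/column order of the transition count matrix
    transitions_labels: tuple[str, ...] = BASIN_LABELS

    @property
    def basins_visited(self) -> list[str]:
        return [l for l in BASIN_LABELS if self.occupancy.get(l, 0.0) > 0.0]

    def transition_count(self, a: str, b: str) -> int:
        return int(self.transitions[BASIN_LABELS.index(a), BASIN_LABELS.index(b)])


def _quadrant_labels(active: np.ndarray, params: CircuitParameters) -> np.ndarray:
    """0=LL, 1=LH, 2=HL, 3=HH from per-axis thresholds (RhoA major bit)."""
    rac_high = active[:, 0] > params.thresh_rac1_high
    rho_high = active[:, 1] > params.thresh_rhoa_high
    return (2 * rho_high + rac_high).astype(np.int64)


def _nearest_labels(active: np.ndarray, steady_states: SteadyStateSet) -> np.ndarray:
    stable = steady_states.stable
    if not stable:
        raise ValueError("nearest-state basin rule needs at least one stable state")
    centers = np.array([p.state for p in stable])
    d = np.linalg.norm(active[:, None, :] - centers[None, :, :], axis=-1)
    nearest = np.argmin(d, axis=1)
    codes = np.array([BASIN_LABELS.index(p.label) for p in stable])
    return codes[nearest]


def _dwell_filter(raw: np.ndarray, dwell: int) -> np.ndarray:
    """Suppress basin excursions shorter than ``dwell`` samples.

    The assignment switches only once the new basin persists for at least
    ``dwell`` consecutive samples; shorter visits stay with the previous
    basin (prevents boundary chatter inflating transition rates).
    """
    # run-length encode
    change = np.nonzero(np.diff(raw))[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(raw)]])
    out = raw.copy()
    current = raw[starts[0]]
    for s, e in zip(starts, ends):
        if raw[s] != current and (e - s) >= dwell:
            current = raw[s]
        out[s:e] = current
    return out


def build_landscape(trajectory: LangevinTrajectory,
                    steady_states: SteadyStateSet,
                    params: CircuitParameters,
                    bins: int = 60,
                    burn_in: float = 100.0,
                    dwell: int = DWELL_THRESHOLD,
                    basin_rule: str = "threshold") -> LandscapeResult:
    """Histogram a trajectory into an effective landscape ``E = -ln P``.

    ``burn_in`` hours are discarded before histogramming.  Basins are the
    High/Low quadrants of the (RhoA-GTP, Rac1-GTP) plane by default
    (``basin_rule='threshold'``), which detects noise-induced basins that
    lack a deterministic fixed point; ``basin_rule='nearest'`` assigns to
    the nearest deterministic stable state instead.  Transitions are
    counted only when the new basin persists for ``dwell`` consecutive
    thinned samples.
    """
    n_burn = int(burn_in / trajectory.sample_interval)
    if n_burn >= len(trajectory.samples):
        raise ValueError("burn-in exceeds trajectory length")
    active = trajectory.active[n_burn:]

    hist, rho_edges, rac_edges = np.histogram2d(
        active[:, 1], active[:, 0], bins=bins)
    prob = hist / hist.sum()
    with np.errstate(divide="ignore"):
        potential = np.where(prob > 0, -np.log(prob), np.nan)

    if basin_rule == "threshold":
        raw = _quadrant_labels(active, params)
    elif basin_rule == "nearest":
        raw = _nearest_labels(active, steady_states)
    else:
        raise ValueError(f"unknown basin_rule {basin_rule!r}")
    assigned = _dwell_filter(raw, dwell)

    occupancy = {label: float(np.mean(assigned == i))
                 for i, label in enumerate(BASIN_LABELS)}

    # basin depth on the landscape: min E over the bins of each quadrant
    rho_mid = 0.5 * (rho_edges[:-1] + rho_edges[1:])
    rac_mid = 0.5 * (rac_edges[:-1] + rac_edges[1:])
    rho_grid, rac_grid = np.meshgrid(rho_mid, rac_mid, indexing="ij")
    quad = (2 * (rho_grid > params.thresh_rhoa_high)
            + (rac_grid > params.thresh_rac1_high))
    basin_potentials = {}
    for i, label in enumerate(BASIN_LABELS):
        mask = (quad == i) & np.isfinite(potential)
        basin_potentials[label] = (float(np.min(potential[mask]))
                                   if mask.any() else float("nan"))
    transitions = np.zeros((4, 4), dtype=np.int64)
    seq = assigned[np.concatenate([[True], np.diff(assigned) != 0])]
    for a, b in zip(seq[:-1], seq[1:]):
        transitions[a, b] += 1

    return LandscapeResult(
        hist=hist, rhoa_edges=rho_edges, rac1_edges=rac_edges,
        potential=potential, occupancy=occupancy,
        basin_potentials=basin_potentials, transitions=transitions,
        basin_rule=basin_rule,
        total_time=trajectory.t_total - burn_in, seed=trajectory.seed,
        basin_sequence=seq)
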
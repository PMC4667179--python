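"""Fixed points of the effective Rac1/RhoA model and phenotype labels.

Fixed points are located as intersections of the two nullclines
(dRac1-GTP/dt = 0 and dRhoA-GTP/dt = 0), polished by a Newton-type root
finder, and classified by linearisation: a state is stable when both
eigenvalues of the Jacobian have negative real part.  Stable states map
to migration phenotypes through per-axis High/Low thresholds:

    (RhoA, Rac1) = (L, L) -> hybrid epithelial/mesenchymal (E/M)
    (L, H) -> mesenchymal (M);  (H, L) -> amoeboid (A);  (H, H) -> A/M

``brute_force_attractors`` provides an independent oracle: many forward
integrations of the same vector field, clustered at their endpoints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from contourpy import contour_generator
from scipy import optimize

from .circuit_model import (
    CircuitParameters,
    SignalInput,
    effective_rhs,
    state_bounds,
)

__all__ = [
    "FixedPoint",
    "SteadyStateSet",
    "compute_nullclines",
    "find_fixed_points",
    "classify_phenotype",
    "brute_force_attractors",
    "LABEL_TO_PHENOTYPE",
]

logger = logging.getLogger(__name__)

#: association of High/Low state labels (RhoA first) with migration phenotypes
LABEL_TO_PHENOTYPE = {"LL": "E/M", "LH": "M", "HL": "A", "HH": "A/M"}

#: relative merge tolerance for duplicate roots
MERGE_RTOL = 1e-4
#: default nullcline grid resolution
NULLCLINE_GRID = 256


@dataclass(frozen=True)
class FixedPoint:
    """A polished fixed point of the effective model."""

    rac1_gtp: float
    rhoa_gtp: float
    stable: bool
    eigenvalues: tuple[complex, complex]
    label: str
    phenotype: str
    ambiguous: bool = False

    @property
    def state(self) -> np.ndarray:
        return np.array([self.rac1_gtp, self.rhoa_gtp])


@dataclass
class SteadyStateSet:
    """All located fixed points for one parameter/signal combination."""

    points: list[FixedPoint] = field(default_factory=list)

    @property
    def stable(self) -> list[FixedPoint]:
        return [p for p in self.points if p.stable]

    @property
    def unstable(self) -> list[FixedPoint]:
        return [p for p in self.points if not p.stable]

    @property
    def phase(self) -> frozenset[str]:
        """The set of coexisting stable labels (the 'phase')."""
        return frozenset(p.label for p in self.stable)

    def phase_string(self) -> str:
        """Canonical sorted '+'-joined phase, e.g. ``'HH+HL+LH'``."""
        return "+".join(sorted(self.phase))

    def __len__(self) -> int:
        return len(self.points)


# ---------------------------------------------------------------------------
# nullclines
# ---------------------------------------------------------------------------

def compute_nullclines(params: CircuitParameters, signals: SignalInput,
                       grid: int = NULLCLINE_GRID,
                       bounds: tuple[float, float] | None = None,
                       ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Zero-level contours of the two effective rate components.

    Returns ``(rac1_nullclines, rhoa_nullclines)``, each a list of
    polylines with columns (rac1_gtp, rhoa_gtp).  The bounding box
    defaults to the invariant region derived from production/degradation
    balance, which provably contains every fixed point, so no adaptive
    expansion is required; a custom ``bounds`` that yields no contour for
    a component raises ``RuntimeError``.
    """
    rac_max, rho_max = bounds if bounds is not None else state_bounds(params, signals)
    rac = np.linspace(0.0, rac_max, grid)
    rho = np.linspace(0.0, rho_max, grid)
    rr, hh = np.meshgrid(rac, rho)  # hh: rhoa values
    state = np.stack([rr, hh], axis=-1)
    rates = effective_rhs(state, params, signals)

    out: list[list[np.ndarray]] = []
    for comp in range(2):
        gen = contour_generator(x=rr, y=hh, z=rates[..., comp])
        lines = [np.asarray(l) for l in gen.lines(0.0) if len(l) >= 2]
        if not lines:
            raise RuntimeError(
                f"no nullcline for component {comp} inside the bounding box "
                f"[0,{rac_max:.3g}]x[0,{rho_max:.3g}]"
            )
        out.append(lines)
    return out[0], out[1]


def _segment_intersections(lines_a: list[np.ndarray],
                           lines_b: list[np.ndarray]) -> np.ndarray:
    """All pairwise crossing points between two polyline families."""
    pts = []
    for la in lines_a:
        a0, a1 = la[:-1], la[1:]
        for lb in lines_b:
            b0, b1 = lb[:-1], lb[1:]
            # vectorized segment-segment intersection
            d1 = a1 - a0                                    # (n,2)
            d2 = b1 - b0                                    # (m,2)
            diff = b0[None, :, :] - a0[:, None, :]          # (n,m,2)
            denom = d1[:, None, 0] * d2[None, :, 1] - d1[:, None, 1] * d2[None, :, 0]
            with np.errstate(divide="ignore", invalid="ignore"):
                t = (diff[..., 0] * d2[None, :, 1] - diff[..., 1] * d2[None, :, 0]) / denom
                s = (diff[..., 0] * d1[:, None, 1] - diff[..., 1] * d1[:, None, 0]) / denom
            hit = (np.abs(denom) > 0) & (t >= 0) & (t <= 1) & (s >= 0) & (s <= 1)
            ii, jj = np.nonzero(hit)
            if len(ii):
                pts.append(a0[ii] + t[ii, jj, None] * d1[ii])
    if not pts:
        return np.empty((0, 2))
    return np.vstack(pts)


# ---------------------------------------------------------------------------
# fixed points
# ---------------------------------------------------------------------------

def jacobian(state, params: CircuitParameters, signals: SignalInput,
             rel_step: float = 1e-6) -> np.ndarray:
    """Central-difference Jacobian of the effective RHS at ``state``."""
    state = np.asarray(state, dtype=float)
    J = np.empty((2, 2))
    for j in range(2):
        h = rel_step * max(abs(state[j]), 1.0)
        ep = state.copy(); ep[j] += h
        em = state.copy(); em[j] = max(em[j] - h, 0.0)
        J[:, j] = (effective_rhs(ep, params, signals)
                   - effective_rhs(em, params, signals)) / (ep[j] - em[j])
    return J


def _polish_root(x0, params, signals, scale) -> np.ndarray | None:
    def fun(x):
        return effective_rhs(np.maximum(x, 0.0), params, signals)

    sol = optimize.root(fun, np.asarray(x0, float), method="hybr",
                        options={"xtol": 1e-12})
    if not sol.success:
        return None
    x = np.maximum(sol.x, 0.0)
    if np.max(np.abs(effective_rhs(x, params, signals))) > 1e-8 * scale:
        return None
    return x


def classify_phenotype(state, params: CircuitParameters,
                       band: float = 1e-3) -> tuple[str, str, bool]:
    """Label a state High/Low per axis and map it to a migration phenotype.

    Returns ``(label, phenotype, ambiguous)`` with the label ordered
    (RhoA, Rac1) as in the field's (1,0)-style shorthand.  A coordinate
    within a relative ``band`` of its threshold flags the call ambiguous.
    """
    rac, rho = float(state[0]), float(state[1])
    ambiguous = (abs(rac - params.thresh_rac1_high) <= band * params.thresh_rac1_high
                 or abs(rho - params.thresh_rhoa_high) <= band * params.thresh_rhoa_high)
    label = ("H" if rho > params.thresh_rhoa_high else "L") + \
            ("H" if rac > params.thresh_rac1_high else "L")
    if ambiguous:
        logger.warning("state (%.3g, %.3g) lies within the threshold band; "
                       "label %s is ambiguous", rac, rho, label)
    return label, LABEL_TO_PHENOTYPE[label], ambiguous


def _dedupe(points: np.ndarray, params, signals, scale) -> list[np.ndarray]:
    """Merge roots closer than MERGE_RTOL (relative to scale) keeping the
    one with the smaller residual."""
    kept: list[np.ndarray] = []
    residual = lambda x: float(np.max(np.abs(effective_rhs(x, params, signals))))
    for x in points:
        merged = False
        for i, y in enumerate(kept):
            if np.all(np.abs(x - y) <= MERGE_RTOL * scale):
                if residual(x) < residual(y):
                    kept[i] = x
                merged = True
                break
        if not merged:
            kept.append(x)
    return kept


def _locate_roots(params, signals, grid) -> list[np.ndarray]:
    nc_rac, nc_rho = compute_nullclines(params, signals, grid=grid)
    seeds = _segment_intersections(nc_rac, nc_rho)
    scale = max(state_bounds(params, signals))
    # near-tangent intersections hide twin roots inside one grid cell, so
    # each seed is polished together with four slightly displaced copies
    rac_max, rho_max = state_bounds(params, signals)
    cell = np.array([rac_max, rho_max]) / grid
    offsets = np.array([[0.0, 0.0], [1.5, 0.0], [-1.5, 0.0], [0.0, 1.5], [0.0, -1.5]])
    polished = []
    for seed in seeds:
        found_any = False
        for off in offsets:
            x = _polish_root(np.maximum(seed + off * cell, 0.0),
                             params, signals, scale)
            if x is not None:
                polished.append(x)
                found_any = True
        if not found_any:
            logger.warning("root polish failed for seed %s; point dropped", seed)
    return _dedupe(np.array(polished) if polished else np.empty((0, 2)),
                   params, signals, scale)


def find_fixed_points(params: CircuitParameters, signals: SignalInput,
                      grid: int = NULLCLINE_GRID) -> SteadyStateSet:
    """Locate, polish and classify all fixed points of the effective model.

    Nullcline intersections seed a Newton-type polish to
    ``|RHS| < 1e-8`` (relative to the production scale); duplicates
    within the merge tolerance collapse to the smaller-residual root, and
    stability comes from the eigenvalues of the linearisation.  For this
    planar system the fixed-point count is odd away from bifurcations, so
    an even count triggers one automatic retry on a 2x finer grid.
    """
    roots = _locate_roots(params, signals, grid)
    if len(roots) % 2 == 0:
        refined = _locate_roots(params, signals, 2 * grid)
        if len(refined) > len(roots):
            roots = refined
        else:
            logger.warning(
                "even fixed-point count (%d) persists after grid refinement; "
                "possible tangency at these parameters", len(roots))

    out = SteadyStateSet()
    for x in sorted(roots, key=lambda r: (r[0], r[1])):
        eig = np.linalg.eigvals(jacobian(x, params, signals))
        stable = bool(np.all(eig.real < 0))
        label, phenotype, ambiguous = classify_phenotype(x, params)
        out.points.append(FixedPoint(
            rac1_gtp=float(x[0]), rhoa_gtp=float(x[1]), stable=stable,
            eigenvalues=(complex(eig[0]), complex(eig[1])),
            label=label, phenotype=phenotype, ambiguous=ambiguous))
    return out


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def _rk4_flow(starts: np.ndarray, params, signals, t_end: float,
              dt: float) -> np.ndarray:
    """Vectorised fixed-step RK4 flow of the effective model, clamped at 0."""
    x = starts.astype(float).copy()
    n_steps = int(np.ceil(t_end / dt))
    f = lambda s: effective_rhs(s, params, signals)
    for _ in range(n_steps):
        k1 = f(x)
        k2 = f(np.maximum(x + 0.5 * dt * k1, 0.0))
        k3 = f(np.maximum(x + 0.5 * dt * k2, 0.0))
        k4 = f(np.maximum(x + dt * k3, 0.0))
        x = np.maximum(x + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4), 0.0)
    return x


def brute_force_attractors(params: CircuitParameters, signals: SignalInput,
                           n_starts: int = 144, t_end: float = 400.0,
                           dt: float = 0.02, seed: int | None = None,
                           ) -> tuple[SteadyStateSet, list[np.ndarray]]:
    """Attractors by multi-start forward integration (verification oracle).

    Initial conditions tile the invariant box on a regular grid (plus
    jitter when ``seed`` is given); every endpoint with a near-zero rate
    is polished and clustered.  Endpoints still moving at ``t_end`` are
    returned separately as non-convergent (possible limit cycles), never
    merged into the attractor set.
    """
    rac_max, rho_max = state_bounds(params, signals)
    side = max(int(np.floor(np.sqrt(n_starts))), 2)
    g1 = np.linspace(0.0, rac_max, side)
    g2 = np.linspace(0.0, rho_max, side)
    starts = np.stack(np.meshgrid(g1, g2), axis=-1).reshape(-1, 2)
    extra = n_starts - len(starts)
    rng = np.random.default_rng(seed)
    if extra > 0:
        starts = np.vstack([starts, rng.uniform([0, 0], [rac_max, rho_max],
                                                size=(extra, 2))])
    if seed is not None:
        starts = starts + rng.uniform(0, 1e-3, starts.shape) * [rac_max, rho_max]

    ends = _rk4_flow(starts, params, signals, t_end, dt)
    scale = max(rac_max, rho_max)
    rates = effective_rhs(ends, params, signals)
    converged = np.max(np.abs(rates), axis=-1) < 1e-6 * scale
    nonconverged = [e for e in ends[~converged]]
    if nonconverged:
        logger.warning("%d of %d starts had not converged by t=%g",
                       len(nonconverged), n_starts, t_end)

    polished = []
    for e in ends[converged]:
        x = _polish_root(e, params, signals, scale)
        if x is not None:
            polished.append(x)
    roots = _dedupe(np.array(polished) if polished else np.empty((0, 2)),
                    params, signals, scale)

    out = SteadyStateSet()
    for x in sorted(roots, key=lambda r: (r[0], r[1])):
        eig = np.linalg.eigvals(jacobian(x, params, signals))
        label, phenotype, ambiguous = classify_phenotype(x, params)
        out.points.append(FixedPoint(
            rac1_gtp=float(x[0]), rhoa_gtp=float(x[1]),
            stable=bool(np.all(eig.real < 0)),
            eigenvalues=(complex(eig[0]), complex(eig[1])),
            label=label, phenotype=phenotype, ambiguous=ambiguous))
    return out, nonconverged
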
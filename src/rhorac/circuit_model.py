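"""Regulatory functions and right-hand sides of the Rac1/RhoA migration circuit.

The circuit couples the mutually inhibitory Rac1/RhoA GTPase toggle switch
(the core regulator of amoeboid/mesenchymal transitions) to the EMT
machinery through two microRNA signals: ``mu1`` inhibits RhoA translation
and ``mu2`` inhibits Rac1 translation.  Each GTPase cycles between an
active GTP-loaded form, an inactive GDP-loaded form and a GDI-sequestered
pool.  Three model granularities are provided:

* **detailed** (6 variables): GTP/GDP/GDI pools for both GTPases, with
  mass-action GDI binding, GTP loading (the ``B`` functions) and GTP
  hydrolysis (the ``J`` functions) interconverting the pools.
* **reduced** (4 variables): the GDI pools at fast equilibrium (GDI
  binding/unbinding is much faster than protein turnover); used by the
  stochastic simulator.
* **effective** (2 variables, Rac1-GTP and RhoA-GTP): additionally places
  the GDP pools at quasi-steady state.  Production is then partitioned
  into the active form by the loading/hydrolysis balance
  ``B / (B + J_eff)`` with ``J_eff = (J + k) * (1 + c)`` with
  the species' GDI partition ``c = gdi_on / (gdi_off + k)``, so the effective model's fixed points
  coincide exactly with those of the detailed model.  All bifurcation and
  stability analysis runs on this model.

Units: molecules for all concentrations, hours for time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from importlib import resources
from typing import Mapping

import numpy as np

__all__ = [
    "HillSpec",
    "MirnaSpec",
    "LoadingSpec",
    "CircuitParameters",
    "SignalInput",
    "Schedule",
    "shifted_hill",
    "mirna_inhibition",
    "loading_rate",
    "effective_hydrolysis",
    "effective_rhs",
    "reduced_rhs",
    "detailed_rhs",
    "signal_response",
    "lift_to_detailed",
    "lift_to_reduced",
    "load_parameters",
    "default_parameters",
    "parameters_to_dict",
    "parameters_from_dict",
]

#: names accepted as regulator species in loading/hydrolysis functions
REGULATOR_SPECIES = ("rac1_gtp", "rhoa_gtp", "grb2", "gab1")

PARAMS_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# regulatory primitives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HillSpec:
    """Shifted Hill function ``H(x) = lam + (1 - lam) / (1 + (x/x0)**n)``.

    ``H(0) = 1`` and ``H(inf) = lam``; a fold change ``lam > 1`` is an
    activation, ``lam < 1`` a repression.  ``threshold`` is in molecules.
    """

    threshold: float
    coefficient: int
    fold_change: float

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError(f"Hill threshold must be positive, got {self.threshold}")
        if int(self.coefficient) != self.coefficient or self.coefficient < 1:
            raise ValueError(f"Hill coefficient must be a positive integer, got {self.coefficient}")
        if self.fold_change < 0:
            raise ValueError(f"fold change must be non-negative, got {self.fold_change}")


@dataclass(frozen=True)
class MirnaSpec:
    """MicroRNA translational-inhibition function ``P(mu)``.

    ``P(mu) = 1 / (1 + (mu/mu0)**n)`` maps a microRNA level to the fraction
    of production that escapes silencing: 1 means no effect, 0 complete
    silencing.  ``half_effect`` (mu0) is the level giving ``P = 1/2``.
    """

    half_effect: float
    coefficient: int

    def __post_init__(self) -> None:
        if self.half_effect <= 0:
            raise ValueError(f"half_effect must be positive, got {self.half_effect}")
        if int(self.coefficient) != self.coefficient or self.coefficient < 1:
            raise ValueError(f"coefficient must be a positive integer, got {self.coefficient}")


@dataclass(frozen=True)
class LoadingSpec:
    """Total GTP loading (or hydrolysis) rate of one GTPase.

    The rate is ``intrinsic_rate`` (1/hour) multiplied by one shifted-Hill
    factor per regulator, capturing GEF/GAP-mediated activation or
    repression by the active GTPases and by the Grb2/Gab1 effectors of the
    c-Met pathway.  Evaluated rates are strictly positive whenever all
    fold changes are positive.
    """

    intrinsic_rate: float
    regulators: tuple[tuple[str, HillSpec], ...] = ()

    def __post_init__(self) -> None:
        if self.intrinsic_rate <= 0:
            raise ValueError(f"intrinsic_rate must be positive, got {self.intrinsic_rate}")
        for name, _ in self.regulators:
            if name not in REGULATOR_SPECIES:
                raise ValueError(f"unknown regulator species {name!r}")


def shifted_hill(x, spec: HillSpec):
    """Evaluate the shifted Hill function at ``x`` (molecules, >= 0).

    Accepts scalars or arrays; negative input raises ``ValueError``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("shifted_hill requires non-negative input")
    lam = spec.fold_change
    h = lam + (1.0 - lam) / (1.0 + (x / spec.threshold) ** spec.coefficient)
    return float(h) if h.ndim == 0 else h


def mirna_inhibition(mu, spec: MirnaSpec):
    """Fraction of production escaping microRNA silencing, in [0, 1]."""
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < 0):
        raise ValueError("mirna_inhibition requires non-negative input")
    p = 1.0 / (1.0 + (mu / spec.half_effect) ** spec.coefficient)
    return float(p) if p.ndim == 0 else p


def loading_rate(spec: LoadingSpec, env: Mapping[str, object]):
    """Evaluate a B or J function in an environment of regulator levels.

    ``env`` maps species names (``rac1_gtp``, ``rhoa_gtp``, ``grb2``,
    ``gab1``) to scalar or array levels; regulators absent from ``env``
    raise ``KeyError``.
    """
    rate = spec.intrinsic_rate
    for name, hill in spec.regulators:
        rate = rate * shifted_hill(env[name], hill)
    return rate


# ---------------------------------------------------------------------------
# parameter container
# ---------------------------------------------------------------------------

@dataclass
class CircuitParameters:
    """All rate constants and regulatory specifications of the circuit.

    The single source of model truth: the same object parameterises the
    effective, reduced and detailed models as well as the stochastic
    simulator.  Rates are per hour, concentrations in molecules.
    """

    g_rac1: float
    g_rhoa_basal: float
    g_rhoa_exc: float
    k_rac1: float
    k_rhoa: float
    rhoa_selfact: HillSpec
    loading_rac1: LoadingSpec
    loading_rhoa: LoadingSpec
    hydrolysis_rac1: LoadingSpec
    hydrolysis_rhoa: LoadingSpec
    mirna_rhoa: MirnaSpec
    mirna_rac1: MirnaSpec
    gdi_on: float
    gdi_off: float
    noise_level: float = 0.0
    #: per-axis High/Low classification thresholds (molecules), frozen at
    #: calibration time as the geometric mean of the extreme stable-state
    #: coordinates of the standalone circuit
    thresh_rac1_high: float = 1.0
    thresh_rhoa_high: float = 1.0

    def __post_init__(self) -> None:
        for name in ("g_rac1", "g_rhoa_basal", "g_rhoa_exc", "k_rac1", "k_rhoa",
                     "gdi_on", "gdi_off", "thresh_rac1_high", "thresh_rhoa_high"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.noise_level < 0:
            raise ValueError("noise_level must be non-negative")

    # -- Grb2/Gab1 half-activation thresholds live on the loading regulators;
    #    exposed as attributes so parameter files can override them wholesale.

    def _signal_regulator(self, which: str) -> HillSpec:
        spec = self.loading_rac1 if which == "grb2" else self.loading_rhoa
        for name, hill in spec.regulators:
            if name == which:
                return hill
        raise KeyError(f"no {which} regulator present in loading spec")

    @property
    def grb2_thresh(self) -> float:
        """Half-activation threshold of the Grb2 signal on Rac1 loading."""
        return self._signal_regulator("grb2").threshold

    @property
    def gab1_thresh(self) -> float:
        """Half-activation threshold of the Gab1 signal on RhoA loading."""
        return self._signal_regulator("gab1").threshold

    def with_signal_thresholds(self, grb2: float, gab1: float) -> "CircuitParameters":
        """Return a copy with new Grb2/Gab1 half-activation thresholds."""
        def _retune(spec: LoadingSpec, which: str, value: float) -> LoadingSpec:
            regs = tuple(
                (name, replace(h, threshold=value) if name == which else h)
                for name, h in spec.regulators
            )
            return replace(spec, regulators=regs)

        return replace(
            self,
            loading_rac1=_retune(self.loading_rac1, "grb2", grb2),
            loading_rhoa=_retune(self.loading_rhoa, "gab1", gab1),
        )

    def gdi_timescale_ratio(self) -> float:
        """Ratio of GDI binding to the slowest degradation rate.

        The fast-equilibrium reduction assumes this is large (>= 100).
        """
        return self.gdi_on / max(self.k_rac1, self.k_rhoa)

    def validate(self) -> None:
        """Check the fast-GDI assumption underlying the reduced models."""
        if self.gdi_timescale_ratio() < 100.0:
            raise ValueError(
                "gdi_on must exceed the degradation rates by >= 100x for the "
                f"fast-equilibrium reduction (ratio {self.gdi_timescale_ratio():.1f})"
            )

    @property
    def gdi_partition_rac1(self) -> float:
        """Equilibrium GDI-bound : GDP-bound ratio for Rac1, ``on/(off+k)``.

        Degradation of the bound form makes the effective unbinding rate
        ``gdi_off + k``.
        """
        return self.gdi_on / (self.gdi_off + self.k_rac1)

    @property
    def gdi_partition_rhoa(self) -> float:
        """Equilibrium GDI-bound : GDP-bound ratio for RhoA."""
        return self.gdi_on / (self.gdi_off + self.k_rhoa)


# ---------------------------------------------------------------------------
# signals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Schedule:
    """Piecewise-linear time course of a signal, e.g. a decaying microRNA.

    ``points`` is a sequence of (time, level) breakpoints; evaluation
    outside the breakpoint range clamps to the end values, so a schedule
    is defined on any simulated interval.
    """

    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.points) < 1:
            raise ValueError("schedule needs at least one breakpoint")
        times = [t for t, _ in self.points]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("schedule breakpoints must be strictly increasing in time")
        if any(v < 0 for _, v in self.points):
            raise ValueError("schedule levels must be non-negative")

    def __call__(self, t: float) -> float:
        times = np.array([p[0] for p in self.points])
        values = np.array([p[1] for p in self.points])
        return float(np.interp(t, times, values))


@dataclass(frozen=True)
class SignalInput:
    """External inputs: microRNA levels mu1 (on RhoA), mu2 (on Rac1) and
    the c-Met effectors Grb2 (activating Rac1) and Gab1 (activating RhoA).

    Each field is a non-negative level in molecules, or a :class:`Schedule`
    for time-dependent protocols.
    """

    mu1: float | Schedule = 0.0
    mu2: float | Schedule = 0.0
    grb2: float | Schedule = 0.0
    gab1: float | Schedule = 0.0

    def __post_init__(self) -> None:
        for name in ("mu1", "mu2", "grb2", "gab1"):
            v = getattr(self, name)
            if not isinstance(v, Schedule) and v < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def is_static(self) -> bool:
        return not any(isinstance(getattr(self, n), Schedule)
                       for n in ("mu1", "mu2", "grb2", "gab1"))

    def at(self, t: float) -> "SignalInput":
        """Resolve any schedules to instantaneous levels at time ``t``."""
        if self.is_static:
            return self
        vals = {}
        for name in ("mu1", "mu2", "grb2", "gab1"):
            v = getattr(self, name)
            vals[name] = v(t) if isinstance(v, Schedule) else v
        return SignalInput(**vals)


def locked_mu(mu: float, grb2: float = 0.0, gab1: float = 0.0) -> SignalInput:
    """Signals with mu1 = mu2 = mu (the single-signal protocol)."""
    return SignalInput(mu1=mu, mu2=mu, grb2=grb2, gab1=gab1)


# ---------------------------------------------------------------------------
# right-hand sides
# ---------------------------------------------------------------------------

def _env(rac1_gtp, rhoa_gtp, signals: SignalInput) -> dict:
    return {
        "rac1_gtp": rac1_gtp,
        "rhoa_gtp": rhoa_gtp,
        "grb2": signals.grb2,
        "gab1": signals.gab1,
    }


def _productions(rhoa_gtp, params: CircuitParameters, signals: SignalInput):
    """MicroRNA-inhibited production rates (g_Rac1*P(mu2), g_RhoA(rho)*P(mu1))."""
    p_rac = mirna_inhibition(signals.mu2, params.mirna_rac1)
    p_rho = mirna_inhibition(signals.mu1, params.mirna_rhoa)
    prod_rac = params.g_rac1 * p_rac
    prod_rho = (params.g_rhoa_basal
                + params.g_rhoa_exc * shifted_hill(rhoa_gtp, params.rhoa_selfact)) * p_rho
    return prod_rac, prod_rho


def effective_hydrolysis(j_rate, k: float, c: float):
    """Map the detailed hydrolysis rate to the effective-model balance rate.

    With GDP and GDI pools at quasi-steady state the loading/hydrolysis
    partition of production uses ``J_eff = (J + k) * (1 + c)`` in place of
    the bare hydrolysis rate J.
    """
    return (j_rate + k) * (1.0 + c)


def effective_rhs(state, params: CircuitParameters, signals: SignalInput):
    """Rate vector of the effective 2-variable model.

    ``state`` is ``(rac1_gtp, rhoa_gtp)`` or an array broadcastable to
    shape (..., 2); returns d(state)/dt in molecules/hour with the same
    shape.  Production is partitioned into the active form by the
    B/(B + J_eff) loading-hydrolysis balance and each species decays at
    its first-order degradation rate.
    """
    state = np.asarray(state, dtype=float)
    rac, rho = state[..., 0], state[..., 1]
    signals = signals.at(0.0) if not signals.is_static else signals
    env = _env(rac, rho, signals)
    prod_rac, prod_rho = _productions(rho, params, signals)
    b_rac = loading_rate(params.loading_rac1, env)
    b_rho = loading_rate(params.loading_rhoa, env)
    j_rac = effective_hydrolysis(loading_rate(params.hydrolysis_rac1, env),
                                 params.k_rac1, params.gdi_partition_rac1)
    j_rho = effective_hydrolysis(loading_rate(params.hydrolysis_rhoa, env),
                                 params.k_rhoa, params.gdi_partition_rhoa)
    drac = prod_rac * b_rac / (b_rac + j_rac) - params.k_rac1 * rac
    drho = prod_rho * b_rho / (b_rho + j_rho) - params.k_rhoa * rho
    return np.stack([drac, drho], axis=-1)


def reduced_rhs(state, params: CircuitParameters, signals: SignalInput, t: float = 0.0):
    """Rate vector of the 4-variable model (GDI pools at fast equilibrium).

    ``state`` is ``(rac1_gtp, rac1_gdp, rhoa_gtp, rhoa_gdp)``; the
    GDI-sequestered pools track ``c * GDP``.  This is the drift used by
    the Langevin simulator.
    """
    state = np.asarray(state, dtype=float)
    rac_t, rac_d = state[..., 0], state[..., 1]
    rho_t, rho_d = state[..., 2], state[..., 3]
    sig = signals.at(t)
    env = _env(rac_t, rho_t, sig)
    prod_rac, prod_rho = _productions(rho_t, params, sig)
    c_rac = params.gdi_partition_rac1
    c_rho = params.gdi_partition_rhoa
    b_rac = loading_rate(params.loading_rac1, env)
    b_rho = loading_rate(params.loading_rhoa, env)
    j_rac = loading_rate(params.hydrolysis_rac1, env)
    j_rho = loading_rate(params.hydrolysis_rhoa, env)
    d_rac_t = b_rac * rac_d - (j_rac + params.k_rac1) * rac_t
    d_rac_d = prod_rac - b_rac * rac_d + j_rac * rac_t - params.k_rac1 * (1.0 + c_rac) * rac_d
    d_rho_t = b_rho * rho_d - (j_rho + params.k_rhoa) * rho_t
    d_rho_d = prod_rho - b_rho * rho_d + j_rho * rho_t - params.k_rhoa * (1.0 + c_rho) * rho_d
    return np.stack([d_rac_t, d_rac_d, d_rho_t, d_rho_d], axis=-1)


def detailed_rhs(state, params: CircuitParameters, signals: SignalInput, t: float = 0.0):
    """Rate vector of the detailed 6-variable model.

    ``state`` is ``(rac1_gtp, rac1_gdp, rac1_gdi, rhoa_gtp, rhoa_gdp,
    rhoa_gdi)``.  Production (microRNA-inhibited) enters the GDP pool,
    loading (B) and hydrolysis (J) interconvert GDP and GTP forms, GDI
    binds the GDP form mass-action style, and every form degrades at the
    species' first-order rate.
    """
    state = np.asarray(state, dtype=float)
    rac_t, rac_d, rac_i = state[..., 0], state[..., 1], state[..., 2]
    rho_t, rho_d, rho_i = state[..., 3], state[..., 4], state[..., 5]
    sig = signals.at(t)
    env = _env(rac_t, rho_t, sig)
    prod_rac, prod_rho = _productions(rho_t, params, sig)
    on, off = params.gdi_on, params.gdi_off
    b_rac = loading_rate(params.loading_rac1, env)
    b_rho = loading_rate(params.loading_rhoa, env)
    j_rac = loading_rate(params.hydrolysis_rac1, env)
    j_rho = loading_rate(params.hydrolysis_rhoa, env)
    d_rac_t = b_rac * rac_d - (j_rac + params.k_rac1) * rac_t
    d_rac_d = (prod_rac - b_rac * rac_d + j_rac * rac_t
               - on * rac_d + off * rac_i - params.k_rac1 * rac_d)
    d_rac_i = on * rac_d - off * rac_i - params.k_rac1 * rac_i
    d_rho_t = b_rho * rho_d - (j_rho + params.k_rhoa) * rho_t
    d_rho_d = (prod_rho - b_rho * rho_d + j_rho * rho_t
               - on * rho_d + off * rho_i - params.k_rhoa * rho_d)
    d_rho_i = on * rho_d - off * rho_i - params.k_rhoa * rho_i
    return np.stack([d_rac_t, d_rac_d, d_rac_i, d_rho_t, d_rho_d, d_rho_i], axis=-1)


def lift_to_reduced(state2, params: CircuitParameters, signals: SignalInput):
    """Lift an effective-model fixed point to the 4-variable state.

    At quasi-steady state ``GDP = (J + k) * GTP / B``; exact at fixed
    points, a good initial condition elsewhere.
    """
    rac, rho = float(state2[0]), float(state2[1])
    sig = signals.at(0.0)
    env = _env(rac, rho, sig)
    b_rac = loading_rate(params.loading_rac1, env)
    b_rho = loading_rate(params.loading_rhoa, env)
    j_rac = loading_rate(params.hydrolysis_rac1, env)
    j_rho = loading_rate(params.hydrolysis_rhoa, env)
    rac_d = (j_rac + params.k_rac1) * rac / b_rac
    rho_d = (j_rho + params.k_rhoa) * rho / b_rho
    return np.array([rac, rac_d, rho, rho_d])


def lift_to_detailed(state2, params: CircuitParameters, signals: SignalInput):
    """Lift an effective-model fixed point to the 6-variable state."""
    rac, rac_d, rho, rho_d = lift_to_reduced(state2, params, signals)
    return np.array([rac, rac_d, params.gdi_partition_rac1 * rac_d,
                     rho, rho_d, params.gdi_partition_rhoa * rho_d])


def signal_response(hgf_level: float, which: str, params: CircuitParameters) -> float:
    """Grb2 or Gab1 level produced downstream of an HGF stimulus.

    A saturating Hill response with half-maximum at the effector's own
    activation threshold: zero basal output, amplitude twice the
    threshold so that a saturating HGF stimulus drives the effector well
    past its half-activation point on the circuit.
    """
    if hgf_level < 0:
        raise ValueError("hgf_level must be non-negative")
    if which == "grb2":
        hill = params._signal_regulator("grb2")
    elif which == "gab1":
        hill = params._signal_regulator("gab1")
    else:
        raise ValueError(f"unknown signal {which!r}; expected 'grb2' or 'gab1'")
    theta, n = hill.threshold, hill.coefficient
    x = (hgf_level / theta) ** n
    return 2.0 * theta * x / (1.0 + x)


# ---------------------------------------------------------------------------
# (de)serialization
# ---------------------------------------------------------------------------

def _hill_to_dict(h: HillSpec) -> dict:
    return {"threshold": h.threshold, "coefficient": h.coefficient,
            "fold_change": h.fold_change}


def _hill_from_dict(d: Mapping) -> HillSpec:
    return HillSpec(d["threshold"], int(d["coefficient"]), d["fold_change"])


def _loading_to_dict(s: LoadingSpec) -> dict:
    return {"intrinsic_rate": s.intrinsic_rate,
            "regulators": [{"species": n, **_hill_to_dict(h)} for n, h in s.regulators]}


def _loading_from_dict(d: Mapping) -> LoadingSpec:
    regs = tuple((r["species"], _hill_from_dict(r)) for r in d.get("regulators", []))
    return LoadingSpec(d["intrinsic_rate"], regs)


def parameters_to_dict(p: CircuitParameters) -> dict:
    """Serialize to a plain dict (JSON-ready, versioned schema)."""
    return {
        "schema_version": PARAMS_SCHEMA_VERSION,
        "units": {"concentration": "molecules", "time": "hour"},
        "g_rac1": p.g_rac1,
        "g_rhoa_basal": p.g_rhoa_basal,
        "g_rhoa_exc": p.g_rhoa_exc,
        "k_rac1": p.k_rac1,
        "k_rhoa": p.k_rhoa,
        "rhoa_selfact": _hill_to_dict(p.rhoa_selfact),
        "loading_rac1": _loading_to_dict(p.loading_rac1),
        "loading_rhoa": _loading_to_dict(p.loading_rhoa),
        "hydrolysis_rac1": _loading_to_dict(p.hydrolysis_rac1),
        "hydrolysis_rhoa": _loading_to_dict(p.hydrolysis_rhoa),
        "mirna_rhoa": {"half_effect": p.mirna_rhoa.half_effect,
                       "coefficient": p.mirna_rhoa.coefficient},
        "mirna_rac1": {"half_effect": p.mirna_rac1.half_effect,
                       "coefficient": p.mirna_rac1.coefficient},
        "gdi_on": p.gdi_on,
        "gdi_off": p.gdi_off,
        "noise_level": p.noise_level,
        "thresh_rac1_high": p.thresh_rac1_high,
        "thresh_rhoa_high": p.thresh_rhoa_high,
    }


def parameters_from_dict(d: Mapping) -> CircuitParameters:
    version = d.get("schema_version", PARAMS_SCHEMA_VERSION)
    if version != PARAMS_SCHEMA_VERSION:
        raise ValueError(f"unsupported parameter schema version {version}")
    return CircuitParameters(
        g_rac1=d["g_rac1"],
        g_rhoa_basal=d["g_rhoa_basal"],
        g_rhoa_exc=d["g_rhoa_exc"],
        k_rac1=d["k_rac1"],
        k_rhoa=d["k_rhoa"],
        rhoa_selfact=_hill_from_dict(d["rhoa_selfact"]),
        loading_rac1=_loading_from_dict(d["loading_rac1"]),
        loading_rhoa=_loading_from_dict(d["loading_rhoa"]),
        hydrolysis_rac1=_loading_from_dict(d["hydrolysis_rac1"]),
        hydrolysis_rhoa=_loading_from_dict(d["hydrolysis_rhoa"]),
        mirna_rhoa=MirnaSpec(d["mirna_rhoa"]["half_effect"],
                             int(d["mirna_rhoa"]["coefficient"])),
        mirna_rac1=MirnaSpec(d["mirna_rac1"]["half_effect"],
                             int(d["mirna_rac1"]["coefficient"])),
        gdi_on=d["gdi_on"],
        gdi_off=d["gdi_off"],
        noise_level=d.get("noise_level", 0.0),
        thresh_rac1_high=d.get("thresh_rac1_high", 1.0),
        thresh_rhoa_high=d.get("thresh_rhoa_high", 1.0),
    )


def load_parameters(path_or_name) -> CircuitParameters:
    """Load parameters from a JSON file path or a packaged data file name."""
    import os

    p = os.fspath(path_or_name)
    if os.path.exists(p):
        with open(p) as fh:
            d = json.load(fh)
    else:
        name = p if p.endswith(".json") else f"{p}.json"
        d = json.loads(resources.files("rhorac.data").joinpath(name).read_text())
    return parameters_from_dict(d)


def default_parameters() -> CircuitParameters:
    """The calibrated default parameter set shipped with the package."""
    ref = resources.files("rhorac.data").joinpath("default_params.json")
    return parameters_from_dict(json.loads(ref.read_text()))


def state_bounds(params: CircuitParameters, signals: SignalInput,
                 margin: float = 1.10) -> tuple[float, float]:
    """Upper bounds on (Rac1-GTP, RhoA-GTP) in the positive invariant region.

    Since the loading partition B/(B+J_eff) < 1 and P <= 1, steady active
    levels cannot exceed production/degradation; a multiplicative margin
    gives a box guaranteed to contain every fixed point.
    """
    lam = max(params.rhoa_selfact.fold_change, 1.0)
    rac_max = params.g_rac1 / params.k_rac1
    rho_max = (params.g_rhoa_basal + params.g_rhoa_exc * lam) / params.k_rhoa
    return margin * rac_max, margin * rho_max
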
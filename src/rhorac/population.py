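"""Phenotype distributions over heterogeneous cell populations.

Non-genetic cell-to-cell variability is modelled by perturbing every
continuous circuit parameter independently and uniformly within a
relative window (default +/-5%) and every Hill coefficient by a discrete
uniform draw from [n-1, n+1] (floored at 1).  Each synthetic cell's
stable states are found deterministically and each state's phenotype
receives weight 1/(number of stable states), so a tri-stable cell
contributes a third of a cell to each of its three phenotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .circuit_model import (
    CircuitParameters,
    HillSpec,
    LoadingSpec,
    MirnaSpec,
    SignalInput,
)
from .steady_state import LABEL_TO_PHENOTYPE, find_fixed_points

__all__ = ["PopulationSpec", "sample_population", "phenotype_distribution",
           "PhenotypeDistribution"]

logger = logging.getLogger(__name__)

PHENOTYPE_ORDER = ("E/M", "M", "A", "A/M")


@dataclass(frozen=True)
class PopulationSpec:
    """How to draw a heterogeneous population around a base parameter set."""

    n_cells: int = 500
    relative_perturbation: float = 0.05
    hill_coefficient_jitter: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be at least 1")
        if not 0.0 <= self.relative_perturbation < 1.0:
            raise ValueError("relative_perturbation must be in [0, 1)")
        if self.hill_coefficient_jitter < 0:
            raise ValueError("hill_coefficient_jitter must be non-negative")


def _jitter_hill(h: HillSpec, rng, delta: float, jit: int) -> HillSpec:
    n = int(rng.integers(h.coefficient - jit, h.coefficient + jit + 1))
    if n < 1:
        logger.warning("jittered Hill coefficient %d clamped to 1", n)
        n = 1
    return HillSpec(
        threshold=h.threshold * rng.uniform(1 - delta, 1 + delta),
        coefficient=n,
        fold_change=h.fold_change * rng.uniform(1 - delta, 1 + delta),
    )


def _jitter_loading(s: LoadingSpec, rng, delta: float, jit: int) -> LoadingSpec:
    return LoadingSpec(
        intrinsic_rate=s.intrinsic_rate * rng.uniform(1 - delta, 1 + delta),
        regulators=tuple((name, _jitter_hill(h, rng, delta, jit))
                         for name, h in s.regulators),
    )


def perturb_parameters(base: CircuitParameters, rng,
                       delta: float, jit: int) -> CircuitParameters:
    """One synthetic cell: every continuous rate/threshold scaled by an
    independent U[1-delta, 1+delta] draw, Hill coefficients jittered.

    The controlled signals (mu1, mu2, Grb2, Gab1) are external inputs, not
    circuit parameters, and the frozen High/Low classification thresholds
    are the phenotype definition, so neither is perturbed.
    """
    u = lambda: rng.uniform(1 - delta, 1 + delta)
    return replace(
        base,
        g_rac1=base.g_rac1 * u(),
        g_rhoa_basal=base.g_rhoa_basal * u(),
        g_rhoa_exc=base.g_rhoa_exc * u(),
        k_rac1=base.k_rac1 * u(),
        k_rhoa=base.k_rhoa * u(),
        rhoa_selfact=_jitter_hill(base.rhoa_selfact, rng, delta, jit),
        loading_rac1=_jitter_loading(base.loading_rac1, rng, delta, jit),
        loading_rhoa=_jitter_loading(base.loading_rhoa, rng, delta, jit),
        hydrolysis_rac1=_jitter_loading(base.hydrolysis_rac1, rng, delta, jit),
        hydrolysis_rhoa=_jitter_loading(base.hydrolysis_rhoa, rng, delta, jit),
        mirna_rhoa=MirnaSpec(base.mirna_rhoa.half_effect * u(),
                             base.mirna_rhoa.coefficient),
        mirna_rac1=MirnaSpec(base.mirna_rac1.half_effect * u(),
                             base.mirna_rac1.coefficient),
        gdi_on=base.gdi_on * u(),
        gdi_off=base.gdi_off * u(),
    )


def sample_population(base_params: CircuitParameters,
                      spec: PopulationSpec) -> list[CircuitParameters]:
    """Draw ``spec.n_cells`` perturbed parameter sets, reproducible by seed."""
    rng = np.random.default_rng(spec.seed)
    return [perturb_parameters(base_params, rng, spec.relative_perturbation,
                               spec.hill_coefficient_jitter)
            for _ in range(spec.n_cells)]


@dataclass
class PhenotypeDistribution:
    """Population fractions per phenotype at one signal condition."""

    fractions: dict[str, float]
    n_cells: int
    n_excluded: int

    @property
    def dominant(self) -> str:
        return max(self.fractions, key=self.fractions.get)


def phenotype_distribution(population: list[CircuitParameters],
                           signals: SignalInput,
                           grid: int = 128) -> PhenotypeDistribution:
    """Weighted phenotype fractions over a population of cells.

    Every stable state of a cell contributes ``1/n_stable`` of that cell
    to its phenotype; fractions are normalised over included cells.
    Cells whose stability analysis fails (no stable state found, or
    root-finding errors) are excluded and counted.
    """
    if not population:
        raise ValueError("population is empty")
    weights = {ph: 0.0 for ph in PHENOTYPE_ORDER}
    excluded = 0
    for cell in population:
        try:
            ss = find_fixed_points(cell, signals, grid=grid)
            stable = ss.stable
            if not stable:
                raise RuntimeError("no stable state located")
        except Exception as exc:                      # noqa: BLE001
            logger.warning("cell excluded from distribution: %s", exc)
            excluded += 1
            continue
        w = 1.0 / len(stable)
        for p in stable:
            weights[LABEL_TO_PHENOTYPE[p.label]] += w
    n_inc = len(population) - excluded
    if n_inc == 0:
        raise RuntimeError("all cells excluded; distribution undefined")
    fractions = {ph: w / n_inc for ph, w in weights.items()}
    return PhenotypeDistribution(fractions=fractions, n_cells=n_inc,
                                 n_excluded=excluded)
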
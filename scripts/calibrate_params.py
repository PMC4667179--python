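"""Construct and freeze the shipped default parameter set.

The circuit's algebraic structure (shifted-Hill regulation, loading/
hydrolysis partition, microRNA silencing) admits a family of parameter
sets; the defaults are chosen so the circuit realises the qualitative
phase structure of the coupled microRNA-Rac1/RhoA switch:

* standalone circuit (mu1 = mu2 = 0): three stable states HL, LH, HH;
* mu1 = mu2 = 100 molecules: tri-stability HL, LL, LH;
* an intermediate window where all four states coexist;
* mono-stable {LL} at high microRNA levels;
* a Grb2/Gab1 response at high mu restricted to the {LL} and {LH} phases.

Each GTPase arm is poised near two saddle-node events tuned through the
silencing factor P(mu): the "ignition" of its low state (which controls
where LL appears) and the extinction of its cross-inhibited high state
(which controls where HH dies).  The numbers below place ignition around
mu ~ 40 and extinction around mu ~ 70 so the four-state window spans
roughly mu in [45, 65].

Run from the repository root:  python scripts/calibrate_params.py
Rewrites src/rhorac/data/*.json and prints the verification scan.
"""

import json
import pathlib
import sys

import numpy as np

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from rhorac.circuit_model import (CircuitParameters, HillSpec, LoadingSpec,
                                  MirnaSpec, locked_mu, parameters_to_dict)
from rhorac.steady_state import find_fixed_points

DATA = pathlib.Path(__file__).resolve().parents[1] / "src" / "rhorac" / "data"

#: noise amplitude (molecules/sqrt(hour)) chosen so a Langevin run of 1e5
#: hours at mu = 0 visits all four phase-plane basins while the three
#: deterministic attractors remain well separated from the thresholds
NOISE_LEVEL = 240.0


def build_defaults() -> CircuitParameters:
    return CircuitParameters(
        # production/degradation (molecules/hour, 1/hour)
        g_rac1=6000.0,
        g_rhoa_basal=60.0,
        g_rhoa_exc=386.0,
        k_rac1=1.0,
        k_rhoa=1.0,
        # transcriptional self-activation of RhoA
        rhoa_selfact=HillSpec(threshold=390.0, coefficient=6, fold_change=5.0),
        # GTP loading of Rac1: GEF self-activation, repression by RhoA-GTP,
        # activation by the Grb2 branch of c-Met signalling
        loading_rac1=LoadingSpec(1.349, (
            ("rac1_gtp", HillSpec(560.0, 8, 12.0)),
            ("rhoa_gtp", HillSpec(300.0, 4, 0.21)),
            ("grb2", HillSpec(500000.0, 2, 30.0)),
        )),
        # GTP loading of RhoA: repression by Rac1-GTP, activation by Gab1
        loading_rhoa=LoadingSpec(6.0, (
            ("rac1_gtp", HillSpec(300.0, 4, 0.45)),
            ("gab1", HillSpec(500000.0, 2, 4.0)),
        )),
        # intrinsic GTP hydrolysis (GAP background); Rac1 cycles faster
        hydrolysis_rac1=LoadingSpec(8.0),
        hydrolysis_rhoa=LoadingSpec(1.0),
        # microRNA silencing: gentle (n = 1) so that levels of order 1e2
        # molecules tip the marginal states while full silencing needs 1e4
        mirna_rhoa=MirnaSpec(half_effect=300.0, coefficient=1),
        mirna_rac1=MirnaSpec(half_effect=300.0, coefficient=1),
        # fast GDI cycling (>= 100x degradation)
        gdi_on=200.0,
        gdi_off=100.0,
        noise_level=NOISE_LEVEL,
        # placeholder High/Low thresholds, frozen below from the mu=0 states
        thresh_rac1_high=1.0,
        thresh_rhoa_high=1.0,
    )


def freeze_thresholds(params: CircuitParameters) -> CircuitParameters:
    """Per-axis threshold = geometric mean of the extreme stable-state
    coordinates of the standalone (mu = 0) circuit."""
    ss = find_fixed_points(params, locked_mu(0.0))
    racs = [p.rac1_gtp for p in ss.stable]
    rhos = [p.rhoa_gtp for p in ss.stable]
    params.thresh_rac1_high = round(float(np.sqrt(min(racs) * max(racs))), 2)
    params.thresh_rhoa_high = round(float(np.sqrt(min(rhos) * max(rhos))), 2)
    return params


def main() -> None:
    params = freeze_thresholds(build_defaults())
    params.validate()

    DATA.mkdir(exist_ok=True)
    with open(DATA / "default_params.json", "w") as fh:
        json.dump(parameters_to_dict(params), fh, indent=1)
        fh.write("\n")

    # variant with more responsive c-Met coupling (half signal thresholds)
    variant = params.with_signal_thresholds(250000.0, 250000.0)
    with open(DATA / "lowthresh_params.json", "w") as fh:
        json.dump(parameters_to_dict(variant), fh, indent=1)
        fh.write("\n")

    print(f"thresholds: Rac1 {params.thresh_rac1_high}, RhoA {params.thresh_rhoa_high}")
    for mu in (0, 5, 10, 15, 20, 25, 45, 100, 300, 1000, 2000, 20000):
        ss = find_fixed_points(params, locked_mu(mu))
        print(f"mu={mu:>6}: {{{ss.phase_string()}}}  "
              f"stable={len(ss.stable)} total={len(ss)}")


if __name__ == "__main__":
    main()
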
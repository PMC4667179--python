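import numpy as np
import pytest

from rhorac import default_parameters
from rhorac.circuit_model import (
    CircuitParameters,
    HillSpec,
    LoadingSpec,
    MirnaSpec,
)


@pytest.fixture(scope="session")
def params() -> CircuitParameters:
    """The calibrated default parameter set (read once per session)."""
    return default_parameters()


@pytest.fixture(scope="session")
def symmetric_params() -> CircuitParameters:
    """A fully symmetric circuit: identical kinetics for both GTPase arms,
    no transcriptional self-activation, mirrored mutual inhibition."""
    inhibition = HillSpec(threshold=300.0, coefficient=4, fold_change=0.2)
    return CircuitParameters(
        g_rac1=1000.0,
        g_rhoa_basal=1000.0,
        g_rhoa_exc=1e-12,
        k_rac1=1.0,
        k_rhoa=1.0,
        rhoa_selfact=HillSpec(threshold=300.0, coefficient=2, fold_change=1.0),
        loading_rac1=LoadingSpec(2.0, (("rhoa_gtp", inhibition),)),
        loading_rhoa=LoadingSpec(2.0, (("rac1_gtp", inhibition),)),
        hydrolysis_rac1=LoadingSpec(1.0),
        hydrolysis_rhoa=LoadingSpec(1.0),
        mirna_rhoa=MirnaSpec(half_effect=300.0, coefficient=1),
        mirna_rac1=MirnaSpec(half_effect=300.0, coefficient=1),
        gdi_on=200.0,
        gdi_off=100.0,
        thresh_rac1_high=300.0,
        thresh_rhoa_high=300.0,
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240)
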
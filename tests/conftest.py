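import numpy as np
import pytest

from redoxfilm import (
    BoundaryConditions,
    FilmParameters,
    PotentialValue,
    default_parameter_set,
    solve_steady_state,
)


@pytest.fixture(scope="session")
def dv2_params() -> FilmParameters:
    return default_parameter_set("DV2_pH7")


@pytest.fixture(scope="session")
def dv1_params() -> FilmParameters:
    return default_parameter_set("DV1_pH7")


@pytest.fixture(scope="session")
def anaerobic_bc() -> BoundaryConditions:
    """H2-saturated, O2-free bulk with an oxidizing electrode (+0.2 V SHE)."""
    return BoundaryConditions(
        PotentialValue(0.2, "SHE"), bulk_h2=0.78, bulk_o2=0.0
    )


@pytest.fixture(scope="session")
def dv2_steady(dv2_params, anaerobic_bc):
    """Anaerobic steady state of the DV2 pH 7 film at +0.2 V (200 nodes)."""
    return solve_steady_state(dv2_params, anaerobic_bc, n_nodes=200)


@pytest.fixture(scope="session")
def dv1_steady(dv1_params, anaerobic_bc):
    return solve_steady_state(dv1_params, anaerobic_bc, n_nodes=200)
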
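import dataclasses

import pytest

from sednit.column_model import solve_steady_state
from sednit.io import northpond_like
from sednit.synthetic_data import default_zones


@pytest.fixture(scope="session")
def spec():
    """The shipped two-sided-oxygenation example scenario."""
    return northpond_like()


@pytest.fixture(scope="session")
def solved(spec):
    """Steady state of the example column at its native 200-node grid."""
    sol = solve_steady_state(spec.column, spec.kinetics)
    assert sol.converged
    return sol


@pytest.fixture(scope="session")
def zones(solved):
    from sednit.fluxes import DepthProfile, detect_transition_zones

    o2 = DepthProfile(solved.z, solved.concentrations["O2"], species="O2")
    return detect_transition_zones(o2)


@pytest.fixture(scope="session")
def small_spec(spec):
    """Same scenario on a coarser grid for repeated-solve tests."""
    return dataclasses.replace(spec, column=dataclasses.replace(spec.column, n_nodes=100))
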
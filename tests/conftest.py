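import pytest

from oncoeco import DEFAULT_PARAMETERS, equilibrate


@pytest.fixture(scope="session")
def params():
    return DEFAULT_PARAMETERS


@pytest.fixture(scope="session")
def baseline_equilibrium(params):
    """Burned-in equilibrium at the published baseline parameters."""
    state, converged, years = equilibrate(params)
    assert converged, f"baseline burn-in did not converge within {years} years"
    return state
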
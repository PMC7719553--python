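import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gmse import MutationParams, SelectionParams

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def base_mutation() -> MutationParams:
    """Gaussian-regime mutation kernel used throughout: frequent small mutations."""
    return MutationParams(v_alpha=0.0025, rho_m=-0.7, phi_m=1.0, mu=0.01, n_loci=20)


@pytest.fixture(scope="session")
def base_selection() -> SelectionParams:
    """Strong-selection fitness peak (narrow, tilted toward positive correlation)."""
    return SelectionParams(v_s=5.0, rho_s=0.8, phi_s=2.0)


@pytest.fixture(scope="session")
def base_M(base_mutation) -> np.ndarray:
    return base_mutation.matrix()


@pytest.fixture(scope="session")
def base_V(base_selection) -> np.ndarray:
    return base_selection.matrix()
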
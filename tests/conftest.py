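import numpy as np
import pytest
from hypothesis import settings

from warfcea import default_base_case

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def base_config():
    return default_base_case()


@pytest.fixture(scope="session")
def base_outcomes(base_config):
    """Both arms of the model evaluated once at the frozen base case."""
    from warfcea import evaluate_arm

    return {
        which: evaluate_arm(base_config, which)
        for which in ("intervention", "control")
    }


def random_transition_matrix(rng: np.random.Generator) -> np.ndarray:
    """A random valid 9-state matrix: stochastic rows, absorbing death."""
    m = rng.dirichlet(np.ones(9), size=9)
    m[-1] = 0.0
    m[-1, -1] = 1.0
    # renormalize defensively to the engine's strict row-sum tolerance
    m /= m.sum(axis=1, keepdims=True)
    return m
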
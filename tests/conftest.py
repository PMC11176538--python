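import numpy as np
import pytest

from mmcsim import ModelParameters
from mmcsim.params import PARAMETER_RANGES


@pytest.fixture
def params() -> ModelParameters:
    """Package default parameter set (point estimates + range midpoints)."""
    return ModelParameters()


@pytest.fixture
def worked_params() -> ModelParameters:
    """Parameter set of the worked dose-determination example.

    Upper-range immune kill (p2) and drug kill (p1) rates; all other
    constants at their defaults.
    """
    return ModelParameters(p1=0.2, p2=5.5e-6)


def random_admissible_params(rng: np.random.Generator) -> ModelParameters:
    """Draw a parameter set with ranged constants uniform in their ranges."""
    draws = {name: float(rng.uniform(*bounds)) for name, bounds in PARAMETER_RANGES.items()}
    return ModelParameters(**draws)


def random_admissible_state(rng: np.random.Generator, params: ModelParameters) -> np.ndarray:
    """Random nonnegative state within the biological range of interest."""
    return np.array(
        [
            rng.uniform(0.0, 10.0),            # M [uM]
            rng.uniform(0.0, params.k),        # T [cells]
            rng.uniform(0.0, 1e6),             # E [cells]
        ]
    )
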
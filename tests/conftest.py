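import numpy as np
import pytest

from nephrokit.petkinetics import DEFAULT_FRAME_SCHEDULE, InputFunction
from nephrokit.synth import gen_aif


@pytest.fixture(scope="session")
def schedule():
    return DEFAULT_FRAME_SCHEDULE


@pytest.fixture(scope="session")
def aif():
    """Default gamma-variate arterial input."""
    input_fn, _ = gen_aif()
    return input_fn


@pytest.fixture(scope="session")
def constant_input():
    """Unit-amplitude constant input for closed-form comparisons."""
    return InputFunction(np.array([0.0, 60.0]), np.array([1.0, 1.0]))
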
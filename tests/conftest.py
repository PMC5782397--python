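import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_similarity():
    """Worked 3-object example: objects 0 and 1 identical, object 2 apart."""
    return np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])


@pytest.fixture
def balanced_sizes():
    """Unequal but same-magnitude block sizes of the 100-object experiments."""
    return [15, 17, 20, 24, 24]


@pytest.fixture
def imbalanced_sizes():
    """Strongly imbalanced block sizes of the 100-object experiments."""
    return [2, 3, 10, 35, 50]
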
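import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


MS_EXAMPLE = """\
ms 4 1 -t 5
1234 5678 9012

//
segsites: 3
positions: 0.1 0.5 0.9
010
110
001
111
"""


@pytest.fixture
def ms_example_text():
    """One ms replicate: 4 chromosomes, 3 segregating sites."""
    return MS_EXAMPLE


@pytest.fixture
def small_matrix():
    """The parsed 4x3 example matrix, built directly."""
    from phenosim import HaplotypeMatrix

    return HaplotypeMatrix(
        np.array([[0, 1, 0], [1, 1, 0], [0, 0, 1], [1, 1, 1]]),
        np.array([0.1, 0.5, 0.9]),
    )
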
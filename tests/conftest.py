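import numpy as np
import pytest

import ecotransport as et


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def uniform_2x2():
    """Uniform 2x2 coupling with its marginals."""
    return et.Coupling(np.full((2, 2), 0.25))


@pytest.fixture
def small_counts():
    return et.InteractionCounts(
        np.array([[3, 1], [0, 4]]), ["hostA", "hostB"], ["parX", "parY"]
    )
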